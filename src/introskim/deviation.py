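"""Per-window coverage-deviation statistic.

Skim-sequencing at ~0.05x yields a Poisson-like read count per 1 Mb window.
Copy-number state is read off a normalized coverage ratio:

* **Wheat windows** are normalized against a sequenced wheat parent. With
  ``M_x`` the genome-wide median of wheat-window counts of sample ``x``,

      dev(i) = (c_line(i) / M_line) / (c_parent(i) / M_parent)

  so an unaffected diploid window sits at 1, a heterozygous loss near 0.5
  and a homozygous loss near 0. Of the two parents the one with the most
  similar per-window baseline is used (median absolute difference of
  median-normalized profiles; ties go to the first parent). Windows where
  the parent's normalized coverage falls below ``mask_floor`` are masked —
  the ratio is meaningless where the reference itself has no mappable
  coverage.

* **Alien (T-genome) windows** have no sequenced diploid reference at
  matched depth, so the baseline is dynamic and internal to the line: the
  mean count of the top decile (by count) of the line's non-zero alien
  windows. Introgressed windows then sit near 1 while residual cross-mapped
  background stays near 0.

Deviation values are computed unclipped; ``display_values`` clips at
``clip_at`` (default 2) purely as the plotting convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, WindowCounts, WindowGrid, ensure_same_grid

DEFAULT_MASK_FLOOR = 0.25
DEFAULT_UPPER_DECILE = 0.10
DEFAULT_CLIP_AT = 2.0


@dataclass
class DeviationProfile:
    """Per-window deviation values for one sample on one grid.

    ``values`` is NaN on masked windows (and on windows not yet computed);
    ``masked`` marks wheat windows suppressed by the mask floor. Alien
    windows are never masked.
    """

    sample_id: str
    grid: WindowGrid
    values: np.ndarray
    masked: np.ndarray
    chosen_parent: str | None = None
    alien_baseline: float | None = None
    clip_at: float = DEFAULT_CLIP_AT

    @property
    def display_values(self) -> np.ndarray:
        return np.minimum(self.values, self.clip_at)

    @staticmethod
    def empty(sample_id: str, grid: WindowGrid, clip_at: float = DEFAULT_CLIP_AT):
        return DeviationProfile(
            sample_id=sample_id,
            grid=grid,
            values=np.full(grid.n, np.nan),
            masked=np.zeros(grid.n, dtype=bool),
            clip_at=clip_at,
        )


def _wheat_median(sample: WindowCounts, wheat: np.ndarray) -> float:
    return float(np.median(sample.counts[wheat]))


def select_parent(
    line: WindowCounts,
    parents: list[WindowCounts],
    spec: GenomeSpec,
    grid: WindowGrid,
    mask_floor: float = DEFAULT_MASK_FLOOR,
) -> str:
    """Pick the parent with the most similar wheat-genome baseline.

    Distance is the median over jointly unmasked wheat windows of
    ``|c_line/M_line - c_parent/M_parent|``; the first parent wins ties.
    """
    ensure_same_grid(line, *parents)
    wheat = grid.wheat_mask(spec)
    m_line = _wheat_median(line, wheat)
    if m_line <= 0:
        raise ValueError(f"line {line.sample_id!r}: wheat-window median is 0")
    norm_parents = []
    for p in parents:
        m_p = _wheat_median(p, wheat)
        if m_p <= 0:
            raise ValueError(f"parent {p.sample_id!r}: wheat-window median is 0")
        norm_parents.append(p.counts[wheat] / m_p)
    usable = np.ones(int(wheat.sum()), dtype=bool)
    for np_ in norm_parents:
        usable &= np_ >= mask_floor
    line_norm = line.counts[wheat] / m_line
    dists = [float(np.median(np.abs(line_norm[usable] - np_[usable]))) for np_ in norm_parents]
    best = int(np.argmin(dists))  # argmin takes the first minimum: deterministic tie-break
    return parents[best].sample_id


def wheat_deviation(
    line: WindowCounts,
    parent: WindowCounts,
    spec: GenomeSpec,
    grid: WindowGrid,
    mask_floor: float = DEFAULT_MASK_FLOOR,
    profile: DeviationProfile | None = None,
) -> DeviationProfile:
    """Fill the wheat part of a deviation profile from a chosen parent."""
    ensure_same_grid(line, parent)
    if profile is None:
        profile = DeviationProfile.empty(line.sample_id, grid)
    wheat = grid.wheat_mask(spec)
    m_line = _wheat_median(line, wheat)
    m_parent = _wheat_median(parent, wheat)
    if m_line <= 0 or m_parent <= 0:
        raise ValueError(
            f"zero wheat-window median (line {line.sample_id!r}: {m_line}, "
            f"parent {parent.sample_id!r}: {m_parent})"
        )
    parent_norm = parent.counts[wheat] / m_parent
    masked = parent_norm < mask_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (line.counts[wheat] / m_line) / parent_norm
    dev[masked] = np.nan
    profile.values[wheat] = dev
    profile.masked[wheat] = masked
    profile.chosen_parent = parent.sample_id
    return profile


def alien_baseline(
    line: WindowCounts, spec: GenomeSpec, grid: WindowGrid, decile: float = DEFAULT_UPPER_DECILE
) -> float:
    """Mean count of the top ``decile`` (by count) of the line's non-zero alien bins.

    Returns 0.0 when every alien window is zero.
    """
    alien = grid.alien_mask(spec)
    counts = line.counts[alien]
    nonzero = counts[counts > 0]
    if len(nonzero) == 0:
        return 0.0
    k = math.ceil(decile * len(nonzero))
    top = np.sort(nonzero)[::-1][:k]
    return float(top.mean())


def alien_deviation(
    line: WindowCounts,
    spec: GenomeSpec,
    grid: WindowGrid,
    decile: float = DEFAULT_UPPER_DECILE,
    profile: DeviationProfile | None = None,
) -> DeviationProfile:
    """Fill the alien part of a deviation profile from the dynamic baseline."""
    ensure_same_grid(line)
    if profile is None:
        profile = DeviationProfile.empty(line.sample_id, grid)
    alien = grid.alien_mask(spec)
    b = alien_baseline(line, spec, grid, decile)
    if b > 0:
        profile.values[alien] = line.counts[alien] / b
    else:
        profile.values[alien] = 0.0
    profile.alien_baseline = b
    return profile


def compute_profile(
    line: WindowCounts,
    parents: list[WindowCounts],
    spec: GenomeSpec,
    grid: WindowGrid,
    mask_floor: float = DEFAULT_MASK_FLOOR,
    decile: float = DEFAULT_UPPER_DECILE,
    clip_at: float = DEFAULT_CLIP_AT,
) -> DeviationProfile:
    """Full per-line profile: parent choice, wheat part, alien part."""
    chosen = select_parent(line, parents, spec, grid, mask_floor)
    parent = next(p for p in parents if p.sample_id == chosen)
    profile = DeviationProfile.empty(line.sample_id, grid, clip_at=clip_at)
    wheat_deviation(line, parent, spec, grid, mask_floor, profile=profile)
    alien_deviation(line, spec, grid, decile, profile=profile)
    return profile


def profile_frame(profile: DeviationProfile) -> pd.DataFrame:
    df = profile.grid.to_frame()
    df.insert(0, "sample", profile.sample_id)
    df["deviation"] = profile.values
    df["masked"] = profile.masked.astype(int)
    df["display_value"] = profile.display_values
    return df


def write_profile(profile: DeviationProfile, path) -> None:
    profile_frame(profile).to_csv(path, sep="\t", index=False, na_rep="NA")
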