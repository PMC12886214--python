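"""Segment calling and structural interpretation of deviation profiles.

Calling is run-based at the native 1 Mb window resolution. Three segment
kinds are detected as maximal window runs:

* ``wheat_loss`` — wheat windows with deviation below the upper edge of the
  heterozygous band (0.75), sustained over >= 6 windows. Zygosity is then
  read off the run mean: < 0.25 homozygous, otherwise heterozygous (a loss
  at copy number 1 sits near 0.5, at copy number 0 near 0).
* ``alien_gain`` — T-genome windows with deviation above 0.2 over >= 5
  windows; presence of alien chromatin.
* ``wheat_duplication`` — wheat windows with deviation above 1.5 over >= 5
  windows (a duplicated segment at copy number 4 sits near 2).

A single interrupting window (masked or outlying; ``bridge_gap``) does not
split a run — 1 Mb bins at 0.05x are noisy. Segment coordinates snap to
window boundaries; no sub-window refinement is attempted.

Structural classes are assigned by pairing segments within a line. A drop
on a wheat chromosome alone is not evidence of introgression; the cascade
demands the corresponding alien gain:

1. alien gain + wheat loss in the same homoeologous group
   -> ``homoeologous_substitution``;
2. otherwise a gain spanning >= 95% of its chromosome
   -> ``whole_chromosome_addition``;
3. otherwise, if a wheat duplication exists, the gain has translocated to
   the duplicated (non-homoeologous) region -> ``non_homoeologous_translocation``;
4. otherwise ``unresolved``.

Remaining wheat losses paired with a duplication on a homoeologous wheat
chromosome are ``wheat_wheat_translocation`` (intra-wheat homoeologous
recombination); fully unpaired losses stay plain losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deviation import DeviationProfile
from .genome import ALIEN_SUBGENOME, GenomeSpec, WHEAT_SUBGENOMES

SEGMENT_KINDS = ("wheat_loss", "alien_gain", "wheat_duplication")

EVENT_CLASSES = (
    "homoeologous_substitution",
    "non_homoeologous_translocation",
    "whole_chromosome_addition",
    "wheat_wheat_translocation",
    "unresolved",
)


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds; defaults follow the published run rules."""

    loss_max: float = 0.1          # homozygous-loss evidence level (plot highlighting)
    loss_min_run: int = 6
    gain_min: float = 0.2
    gain_min_run: int = 5
    dup_min: float = 1.5
    dup_min_run: int = 5
    het_band: tuple[float, float] = (0.25, 0.75)
    bridge_gap: int = 1
    addition_span: float = 0.95    # min chromosome fraction for a whole-chromosome addition

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not 0 <= self.loss_max < lo < hi < self.dup_min:
            raise ValueError(
                f"inconsistent thresholds: need 0 <= loss_max < het_band.low < "
                f"het_band.high < dup_min, got {self.loss_max}, {lo}, {hi}, {self.dup_min}"
            )
        for name in ("loss_min_run", "gain_min_run", "dup_min_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bridge_gap < 0:
            raise ValueError("bridge_gap must be >= 0")

    def predicate(self, kind: str):
        if kind == "wheat_loss":
            return lambda v: v < self.het_band[1]
        if kind == "alien_gain":
            return lambda v: v > self.gain_min
        if kind == "wheat_duplication":
            return lambda v: v > self.dup_min
        raise ValueError(f"unknown segment kind {kind!r}")

    def min_run(self, kind: str) -> int:
        return {
            "wheat_loss": self.loss_min_run,
            "alien_gain": self.gain_min_run,
            "wheat_duplication": self.dup_min_run,
        }[kind]


@dataclass
class SegmentCall:
    """A contiguous aberrant-coverage run, window-aligned and half-open."""

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: str
    mean_deviation: float
    n_windows: int
    zygosity: str = "na"
    i0: int = -1                   # grid index of first satisfying window
    i1: int = -1                   # grid index past the last satisfying window

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class Junction:
    """A recombination junction: an internal boundary of an aberrant run."""

    chrom: str
    position: int
    side: str                      # proximal = lower-coordinate edge, distal = upper


@dataclass
class IntrogressionEvent:
    sample_id: str
    event_class: str
    alien_segment: SegmentCall | None = None
    wheat_partner: SegmentCall | None = None
    supporting_duplication: SegmentCall | None = None
    zygosity: str = "na"
    junctions: list[Junction] = field(default_factory=list)
    centric_candidate: bool = False


def find_runs(
    profile: DeviationProfile,
    kind: str,
    th: Thresholds,
    spec: GenomeSpec,
) -> list[SegmentCall]:
    """Maximal runs of windows satisfying ``kind``'s predicate.

    Runs are scanned per chromosome; consecutive satisfying windows whose
    separation is at most ``bridge_gap`` interrupting windows (masked or
    not) belong to one run. A run is reported when it holds at least the
    kind's minimum number of satisfying windows; its coordinates span the
    first to last satisfying window, and its mean deviation is taken over
    satisfying windows only.
    """
    pred = th.predicate(kind)
    min_run = th.min_run(kind)
    grid = profile.grid
    subgenomes = (ALIEN_SUBGENOME,) if kind == "alien_gain" else WHEAT_SUBGENOMES
    calls: list[SegmentCall] = []
    for c in spec:
        if c.subgenome not in subgenomes:
            continue
        sl = grid.windows_for(c.name)
        vals = profile.values[sl]
        sat = np.where(~np.isnan(vals) & pred(vals))[0]
        if len(sat) == 0:
            continue
        run: list[int] = [int(sat[0])]
        groups: list[list[int]] = [run]
        for j in sat[1:]:
            if int(j) - run[-1] - 1 <= th.bridge_gap:
                run.append(int(j))
            else:
                run = [int(j)]
                groups.append(run)
        for g in groups:
            if len(g) < min_run:
                continue
            lo, hi = g[0] + sl.start, g[-1] + sl.start
            calls.append(
                SegmentCall(
                    sample_id=profile.sample_id,
                    chrom=c.name,
                    start=int(grid.starts[lo]),
                    end=int(grid.ends[hi]),
                    kind=kind,
                    mean_deviation=float(np.mean([vals[j] for j in g])),
                    n_windows=len(g),
                    i0=lo,
                    i1=hi + 1,
                )
            )
    return calls


def classify_zygosity(seg: SegmentCall, th: Thresholds = Thresholds()) -> str:
    """hom below the het band, het within it; above the band is not a loss."""
    lo, hi = th.het_band
    if seg.mean_deviation < lo:
        return "hom"
    if seg.mean_deviation <= hi:
        return "het"
    raise ValueError(
        f"segment {seg.chrom}:{seg.start}-{seg.end} mean deviation "
        f"{seg.mean_deviation:.3f} exceeds the heterozygous band ({hi}); not a loss"
    )


def detect_duplications(
    profile: DeviationProfile, th: Thresholds, spec: GenomeSpec
) -> list[SegmentCall]:
    return find_runs(profile, "wheat_duplication", th, spec)


def call_segments(
    profile: DeviationProfile, spec: GenomeSpec, th: Thresholds = Thresholds()
) -> dict[str, list[SegmentCall]]:
    """All three segment kinds for one line, losses carrying zygosity."""
    losses = find_runs(profile, "wheat_loss", th, spec)
    for seg in losses:
        seg.zygosity = classify_zygosity(seg, th)
    return {
        "losses": losses,
        "gains": find_runs(profile, "alien_gain", th, spec),
        "duplications": detect_duplications(profile, th, spec),
    }


def _is_centric(seg: SegmentCall, spec: GenomeSpec, window_size: int) -> bool:
    cen = spec.chrom(seg.chrom).centromere
    if cen is None:
        return False
    return (
        abs(seg.start - cen) <= window_size or abs(seg.end - cen) <= window_size
    )


def pair_events(
    losses: list[SegmentCall],
    gains: list[SegmentCall],
    dups: list[SegmentCall],
    spec: GenomeSpec,
    th: Thresholds = Thresholds(),
) -> list[IntrogressionEvent]:
    """Pair one line's segment calls into structural events (see module doc).

    Each wheat loss and each duplication supports at most one event. Among
    several homoeologous losses the largest is paired; among several
    duplications the largest (ties: lowest chromosome index in the genome
    spec) is the designated translocation partner.
    """

    order = {name: i for i, name in enumerate(spec.names)}
    events: list[IntrogressionEvent] = []
    free_losses = sorted(losses, key=lambda s: (order[s.chrom], s.start))
    free_dups = sorted(dups, key=lambda s: (-s.length, order[s.chrom], s.start))

    for gain in sorted(gains, key=lambda s: (order[s.chrom], s.start)):
        group_chroms = spec.homoeologs(gain.chrom)
        partners = [l for l in free_losses if l.chrom in group_chroms]
        if partners:
            loss = max(partners, key=lambda s: (s.length, -order[s.chrom], -s.start))
            free_losses.remove(loss)
            ev = IntrogressionEvent(
                sample_id=gain.sample_id,
                event_class="homoeologous_substitution",
                alien_segment=gain,
                wheat_partner=loss,
                zygosity=loss.zygosity,
            )
        elif gain.length >= th.addition_span * spec.chrom(gain.chrom).length:
            ev = IntrogressionEvent(
                sample_id=gain.sample_id,
                event_class="whole_chromosome_addition",
                alien_segment=gain,
            )
        elif free_dups:
            dup = free_dups.pop(0)
            ev = IntrogressionEvent(
                sample_id=gain.sample_id,
                event_class="non_homoeologous_translocation",
                alien_segment=gain,
                supporting_duplication=dup,
            )
        else:
            ev = IntrogressionEvent(
                sample_id=gain.sample_id, event_class="unresolved", alien_segment=gain
            )
        events.append(ev)

    # remaining losses: wheat-wheat translocation when a homoeologous duplication exists
    for loss in list(free_losses):
        group_chroms = spec.homoeologs(loss.chrom)
        partners = [d for d in free_dups if d.chrom in group_chroms]
        if partners:
            dup = partners[0]  # free_dups is sorted largest-first
            free_dups.remove(dup)
            free_losses.remove(loss)
            events.append(
                IntrogressionEvent(
                    sample_id=loss.sample_id,
                    event_class="wheat_wheat_translocation",
                    wheat_partner=loss,
                    supporting_duplication=dup,
                    zygosity=loss.zygosity,
                )
            )

    for ev in events:
        seg = ev.alien_segment
        if seg is not None:
            ws = (seg.end - seg.start) // max(seg.n_windows, 1)
            ev.centric_candidate = _is_centric(seg, spec, max(ws, 1))
        ev.junctions = extract_junctions(ev, spec)
    return events


def unpaired_losses(
    losses: list[SegmentCall], events: list[IntrogressionEvent]
) -> list[SegmentCall]:
    used = {id(ev.wheat_partner) for ev in events if ev.wheat_partner is not None}
    return [l for l in losses if id(l) not in used]


def extract_junctions(event: IntrogressionEvent, spec: GenomeSpec) -> list[Junction]:
    """Internal run boundaries of an event's segments, on both genomes.

    A boundary coincident with a chromosome end is not a recombination
    junction; the lower-coordinate edge is reported as ``proximal``, the
    upper as ``distal``. Positional uncertainty is one window.
    """
    junctions: list[Junction] = []
    for seg in (event.alien_segment, event.wheat_partner, event.supporting_duplication):
        if seg is None:
            continue
        length = spec.chrom(seg.chrom).length
        if seg.start > 0:
            junctions.append(Junction(chrom=seg.chrom, position=seg.start, side="proximal"))
        if seg.end < length:
            junctions.append(Junction(chrom=seg.chrom, position=seg.end, side="distal"))
    return junctions


# ---------------------------------------------------------------------------
# tabular output


def segments_frame(segments: list[SegmentCall]) -> pd.DataFrame:
    """BED6+ layout: chrom start end name score strand sample zygosity n_windows."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "name": s.kind,
                "score": round(s.mean_deviation, 4),
                "strand": ".",
                "sample": s.sample_id,
                "zygosity": s.zygosity,
                "n_windows": s.n_windows,
            }
            for s in segments
        ],
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "sample", "zygosity", "n_windows",
        ],
    )


def _seg_dict(seg: SegmentCall | None):
    if seg is None:
        return None
    return {
        "chrom": seg.chrom,
        "start": seg.start,
        "end": seg.end,
        "kind": seg.kind,
        "mean_deviation": round(seg.mean_deviation, 4),
        "n_windows": seg.n_windows,
        "zygosity": seg.zygosity,
    }


def event_record(ev: IntrogressionEvent) -> dict:
    return {
        "sample_id": ev.sample_id,
        "event_class": ev.event_class,
        "zygosity": ev.zygosity,
        "alien_segment": _seg_dict(ev.alien_segment),
        "wheat_partner": _seg_dict(ev.wheat_partner),
        "supporting_duplication": _seg_dict(ev.supporting_duplication),
        "centric_candidate": ev.centric_candidate,
        "junctions": [
            {"chrom": j.chrom, "position": j.position, "side": j.side} for j in ev.junctions
        ],
    }


def events_frame(events: list[IntrogressionEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        a, w, d = ev.alien_segment, ev.wheat_partner, ev.supporting_duplication
        rows.append(
            {
                "sample": ev.sample_id,
                "event_class": ev.event_class,
                "zygosity": ev.zygosity,
                "alien_chrom": a.chrom if a else "",
                "alien_start": a.start if a else "",
                "alien_end": a.end if a else "",
                "wheat_chrom": w.chrom if w else "",
                "wheat_start": w.start if w else "",
                "wheat_end": w.end if w else "",
                "dup_chrom": d.chrom if d else "",
                "centric_candidate": int(ev.centric_candidate),
                "n_junctions": len(ev.junctions),
            }
        )
    return pd.DataFrame(rows)
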