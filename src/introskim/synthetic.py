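"""Seeded skim-sequencing panel simulator with planted truth.

The generator emulates the data regime the caller consumes: ~0.05x
coverage, 1 Mb windows, two sequenced wheat parents and a panel of
introgression lines on a concatenated wheat+alien reference. Counts are
simulated directly at window level — the analysis never sees reads — with
the same statistical structure real windowed counts have:

* expected count per diploid window ``lambda = depth * window_len /
  read_footprint`` (~166.7 at defaults);
* a per-window mappability factor ``m(i)`` (lognormal, mean 1) drawn once
  per panel and shared by every sample — the component the parental-ratio
  normalization exists to cancel; a small fraction of windows is fully
  unmappable (``m = 0``), placed as isolated bins (fully dead 1 Mb bins
  are rare and dispersed outside pericentromeres at this resolution);
* each parent carries its own small lognormal jitter on top of ``m``, and
  every line inherits the jitter of one parent, so parent selection has a
  right answer;
* counts are Poisson(``lambda * m_eff * cn / 2``) given the local copy
  number ``cn`` implied by the planted events;
* wheat reads cross-mapping onto the alien genome are concentrated in a
  small set of conserved/repeat "hot" alien windows (shared across the
  panel), with an average cross-mapped mass of ``cross_map_rate * lambda``
  per alien window and a per-hot-window intensity of
  ``cross_map_rate / cross_map_hot_frac * lambda`` (~0.05 lambda, ~8
  reads, at defaults — well below the single-copy introgression signal,
  so background never mimics nor extends a gain). Concentration in a
  handful of bins is what keeps alien deviation near zero in lines
  without alien content, as observed in real profiles, while still
  exercising the non-zero-bin logic of the dynamic baseline;
  mapping-quality filtering leaves genuinely cross-mapped reads rare and
  clumped in conserved regions.

The default panel is a 28-chromosome miniature genome (21 wheat + 7 alien,
100 windows each), 20 lines and 30 planted events covering every event
class. Identical config + seed reproduces counts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import IntrogressionEvent, SegmentCall
from .genome import (
    ALIEN_SUBGENOME,
    Chromosome,
    GenomeSpec,
    Pedigree,
    PedigreeEntry,
    WindowCounts,
    WindowGrid,
    make_windows,
)

TRUTH_CLASSES = (
    "substitution_hom",
    "substitution_het",
    "addition",
    "non_homoeologous_translocation",
    "duplication",
    "wheat_wheat_translocation",
)

#: copy numbers (wheat_cn, alien_cn) implied by each class
CLASS_COPY_NUMBERS = {
    "substitution_hom": (0, 2),
    "substitution_het": (1, 1),
    "addition": (2, 2),
    "non_homoeologous_translocation": (2, 2),
    "duplication": (4, 0),
    "wheat_wheat_translocation": (0, 0),
}

ACCESSIONS = ("2130004", "2130008", "2130012")
ACCESSION_WEIGHTS = (0.45, 0.10, 0.45)


@dataclass(frozen=True)
class TruthEvent:
    """One planted structural event.

    ``wheat_chrom``/``wheat_interval`` hold the primary wheat-side change
    (the replaced interval for substitutions, the lost interval for a
    wheat-wheat translocation, the duplicated interval for a plain
    duplication); ``partner_*`` hold the secondary duplicated interval of
    translocation classes. Intervals are bp, window-aligned, half-open.
    """

    line_id: str
    event_class: str
    alien_chrom: str | None = None
    alien_interval: tuple[int, int] | None = None
    wheat_chrom: str | None = None
    wheat_interval: tuple[int, int] | None = None
    wheat_cn: int = 2
    alien_cn: int = 0
    partner_chrom: str | None = None
    partner_interval: tuple[int, int] | None = None
    partner_cn: int = 2


@dataclass
class TruthSet:
    events: list[TruthEvent]
    pedigree: Pedigree
    line_ids: list[str]


@dataclass
class SimConfig:
    spec: GenomeSpec
    window_size: int = 1_000_000
    depth: float = 0.05
    read_footprint: int = 300
    map_sigma: float = 0.2
    zero_fraction: float = 0.02
    cross_map_rate: float = 0.00025
    cross_map_hot_frac: float = 0.005
    parent_jitter_sigma: float = 0.05
    parent_ids: tuple[str, str] = ("ParentA", "ParentB")
    events: list[TruthEvent] = field(default_factory=list)
    line_parent: dict[str, int] = field(default_factory=dict)
    pedigree: Pedigree | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        if not 0 <= self.cross_map_rate < 0.2:
            raise ValueError("cross_map_rate must be in [0, 0.2)")
        if not 0 < self.cross_map_hot_frac <= 1:
            raise ValueError("cross_map_hot_frac must be in (0, 1]")
        for ev in self.events:
            if ev.event_class not in TRUTH_CLASSES:
                raise ValueError(f"unknown truth class {ev.event_class!r}")

    @property
    def line_ids(self) -> list[str]:
        return sorted(self.line_parent)


def default_genome(n_windows_per_chrom: int = 100, window_size: int = 1_000_000) -> GenomeSpec:
    """Miniature 28-chromosome genome: groups 1-7 x subgenomes A, B, D, T."""
    length = n_windows_per_chrom * window_size
    chroms = [
        Chromosome(
            name=f"{g}{sg}",
            length=length,
            subgenome=sg,
            group=g,
            centromere=length // 2,
        )
        for sg in ("A", "B", "D", "T")
        for g in range(1, 8)
    ]
    return GenomeSpec(chroms)


# ---------------------------------------------------------------------------
# default panel construction


#: default class mix of the 30 planted events
DEFAULT_CLASS_MIX = (
    ("substitution_hom", 12),
    ("substitution_het", 6),
    ("addition", 2),
    ("non_homoeologous_translocation", 3),
    ("duplication", 3),
    ("wheat_wheat_translocation", 4),
)

_DUP_BEARING = {"non_homoeologous_translocation", "duplication", "wheat_wheat_translocation"}


def _sample_interval(rng, n_win: int, window: int, k: int) -> tuple[int, int]:
    """A k-window interval; mostly terminal, as real recombination is distal."""
    u = rng.random()
    if u < 0.35:
        return 0, k * window
    if u < 0.70:
        return (n_win - k) * window, n_win * window
    s = int(rng.integers(1, n_win - k))
    return s * window, (s + k) * window


def default_panel(
    seed: int,
    n_lines: int = 20,
    class_mix=DEFAULT_CLASS_MIX,
    n_windows_per_chrom: int = 100,
    window_size: int = 1_000_000,
) -> SimConfig:
    """The default study panel: 20 lines, 30 events across all classes.

    Two deliberate structures mirror the crossing design: lines Sim01 and
    Sim02 share a BC1 ancestor and carry the identical substitution (they
    must collapse to one unique introgression), and Sim03/Sim04 carry
    substitutions from different BC1 plants with a shared alien junction
    (a recombination hotspot).
    """
    rng = np.random.default_rng(seed)
    spec = default_genome(n_windows_per_chrom, window_size)
    n_win = n_windows_per_chrom
    w = window_size

    line_ids = [f"Sim{i:02d}" for i in range(1, n_lines + 1)]
    line_parent = {lid: i % 2 for i, lid in enumerate(line_ids)}

    # pedigree: Sim01/Sim02 share BC01; Sim03/Sim04 fixed to distinct BC1s
    bc1_pool = [f"BC{i:02d}" for i in range(2, 15)]
    bc1_of: dict[str, str] = {}
    for i, lid in enumerate(line_ids):
        if lid in ("Sim01", "Sim02"):
            bc1_of[lid] = "BC01"
        elif lid == "Sim03":
            bc1_of[lid] = "BC02"
        elif lid == "Sim04":
            bc1_of[lid] = "BC03"
        else:
            bc1_of[lid] = str(rng.choice(bc1_pool))
    acc_of_bc1 = {
        b: str(rng.choice(ACCESSIONS, p=ACCESSION_WEIGHTS))
        for b in sorted(set(bc1_of.values()))
    }
    pedigree = Pedigree(
        {
            lid: PedigreeEntry(line_id=lid, bc1_id=b, accession=acc_of_bc1[b])
            for lid, b in bc1_of.items()
        }
    )

    used_groups: dict[str, set[int]] = {lid: set() for lid in line_ids}
    has_dup_event: dict[str, bool] = {lid: False for lid in line_ids}
    n_events_of: dict[str, int] = {lid: 0 for lid in line_ids}
    events: list[TruthEvent] = []

    def pick_letter() -> str:
        return str(rng.choice(["A", "B", "D"], p=[0.18, 0.07, 0.75]))

    def make_substitution(line_id: str, group: int, zyg: str, interval: tuple[int, int],
                          letter: str) -> TruthEvent:
        wheat_cn, alien_cn = CLASS_COPY_NUMBERS[f"substitution_{zyg}"]
        return TruthEvent(
            line_id=line_id,
            event_class=f"substitution_{zyg}",
            alien_chrom=f"{group}{ALIEN_SUBGENOME}",
            alien_interval=interval,
            wheat_chrom=f"{group}{letter}",
            wheat_interval=interval,       # collinear replacement
            wheat_cn=wheat_cn,
            alien_cn=alien_cn,
        )

    # --- deliberate structures (need the first four lines to exist) ----------
    n_specials = 0
    k = int(rng.integers(12, 30))
    shared_iv = _sample_interval(rng, n_win, w, k)
    shared_letter = pick_letter()
    g_shared = int(rng.integers(1, 8))
    g_hot = int(rng.integers(1, 8))
    k_hot = int(rng.integers(15, 35))
    hot_iv = ((n_win - k_hot) * w, n_win * w)  # terminal: one shared proximal junction
    if n_lines >= 4:
        for lid in ("Sim01", "Sim02"):
            events.append(make_substitution(lid, g_shared, "hom", shared_iv, shared_letter))
            used_groups[lid].add(g_shared)
            n_events_of[lid] += 1
        for lid, letter in (("Sim03", "D"), ("Sim04", "A")):
            events.append(make_substitution(lid, g_hot, "hom", hot_iv, letter))
            used_groups[lid].add(g_hot)
            n_events_of[lid] += 1
        n_specials = 4

    # --- remaining events -----------------------------------------------------
    remaining = []
    for cls, n in class_mix:
        n_left = n - (n_specials if cls == "substitution_hom" else 0)
        remaining.extend([cls] * max(n_left, 0))
    remaining = [remaining[i] for i in rng.permutation(len(remaining))]

    def eligible(lid: str, cls: str, groups_needed: int) -> bool:
        if n_events_of[lid] >= 3:
            return False
        if cls in _DUP_BEARING and has_dup_event[lid]:
            return False
        return len(used_groups[lid]) + groups_needed <= 7

    for cls in remaining:
        groups_needed = 2 if cls == "non_homoeologous_translocation" else 1
        order = sorted(line_ids, key=lambda l: (n_events_of[l], l))
        lid = next((l for l in order if eligible(l, cls, groups_needed)), None)
        if lid is None:
            continue  # small panels: plant as many of the mix as capacity allows
        free = [g for g in range(1, 8) if g not in used_groups[lid]]
        g = int(free[rng.integers(len(free))])
        used_groups[lid].add(g)
        k = int(rng.integers(8, 41))
        iv = _sample_interval(rng, n_win, w, k)
        if cls in ("substitution_hom", "substitution_het"):
            zyg = cls.split("_")[1]
            events.append(make_substitution(lid, g, zyg, iv, pick_letter()))
        elif cls == "addition":
            events.append(
                TruthEvent(
                    line_id=lid,
                    event_class=cls,
                    alien_chrom=f"{g}{ALIEN_SUBGENOME}",
                    alien_interval=(0, n_win * w),
                    alien_cn=2,
                )
            )
        elif cls == "non_homoeologous_translocation":
            free2 = [x for x in range(1, 8) if x not in used_groups[lid]]
            g2 = int(free2[rng.integers(len(free2))])
            used_groups[lid].add(g2)
            dup_iv = _sample_interval(rng, n_win, w, k)
            events.append(
                TruthEvent(
                    line_id=lid,
                    event_class=cls,
                    alien_chrom=f"{g}{ALIEN_SUBGENOME}",
                    alien_interval=iv,
                    alien_cn=2,
                    partner_chrom=f"{g2}{pick_letter()}",
                    partner_interval=dup_iv,
                    partner_cn=4,
                )
            )
            has_dup_event[lid] = True
        elif cls == "duplication":
            events.append(
                TruthEvent(
                    line_id=lid,
                    event_class=cls,
                    wheat_chrom=f"{g}{pick_letter()}",
                    wheat_interval=iv,
                    wheat_cn=4,
                )
            )
            has_dup_event[lid] = True
        elif cls == "wheat_wheat_translocation":
            la = pick_letter()
            lb = str(rng.choice([x for x in ("A", "B", "D") if x != la]))
            events.append(
                TruthEvent(
                    line_id=lid,
                    event_class=cls,
                    wheat_chrom=f"{g}{la}",
                    wheat_interval=iv,
                    wheat_cn=0,
                    partner_chrom=f"{g}{lb}",
                    partner_interval=iv,   # collinear donor segment
                    partner_cn=4,
                )
            )
            has_dup_event[lid] = True
        n_events_of[lid] += 1

    return SimConfig(
        spec=spec,
        window_size=window_size,
        events=events,
        line_parent=line_parent,
        pedigree=pedigree,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation


def expected_lambda(cfg: SimConfig) -> float:
    """Expected read pairs per full diploid window."""
    return cfg.depth * cfg.window_size / cfg.read_footprint


def _copy_numbers(cfg: SimConfig, grid: WindowGrid, line_id: str):
    """(wheat-side cn, alien-side cn) arrays over the grid for one line."""
    wheat_cn = np.full(grid.n, 2.0)
    alien_cn = np.zeros(grid.n)
    alien_names = {c.name for c in cfg.spec.alien_chromosomes}
    for c in cfg.spec.alien_chromosomes:
        wheat_cn[grid.windows_for(c.name)] = 0.0

    def apply(chrom, interval, value):
        if chrom is None or interval is None:
            return
        sl = grid.windows_for(chrom)
        lo = sl.start + interval[0] // cfg.window_size
        hi = sl.start + -(-interval[1] // cfg.window_size)
        if chrom in alien_names:
            alien_cn[lo:hi] = value
        else:
            wheat_cn[lo:hi] = value

    for ev in cfg.events:
        if ev.line_id != line_id:
            continue
        apply(ev.alien_chrom, ev.alien_interval, ev.alien_cn)
        apply(ev.wheat_chrom, ev.wheat_interval, ev.wheat_cn)
        apply(ev.partner_chrom, ev.partner_interval, ev.partner_cn)
    return wheat_cn, alien_cn


def simulate_panel(cfg: SimConfig):
    """Simulate parent and line counts with planted truth.

    Returns ``(parents, lines, grid, truth)`` where ``parents`` and
    ``lines`` are lists of :class:`WindowCounts` and ``truth`` a
    :class:`TruthSet`. Identical config and seed give identical counts.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = make_windows(cfg.spec, cfg.window_size)
    n = grid.n
    lam = expected_lambda(cfg) * (grid.ends - grid.starts) / cfg.window_size

    # shared per-window mappability, unmappable bins isolated
    mu = -0.5 * cfg.map_sigma**2
    m = rng.lognormal(mean=mu, sigma=cfg.map_sigma, size=n)
    n_zero = int(cfg.zero_fraction * n)
    dead: list[int] = []
    for i in rng.permutation(n):
        if len(dead) >= n_zero:
            break
        if (i - 1 not in dead) and (i + 1 not in dead):
            dead.append(int(i))
    m[dead] = 0.0

    alien_mask = grid.alien_mask(cfg.spec)
    hot = alien_mask & (rng.random(n) < cfg.cross_map_hot_frac)
    bg = np.zeros(n)
    bg[hot] = cfg.cross_map_rate / cfg.cross_map_hot_frac * lam[hot] * m[hot]

    jitter = [
        rng.lognormal(mean=-0.5 * cfg.parent_jitter_sigma**2,
                      sigma=cfg.parent_jitter_sigma, size=n)
        for _ in cfg.parent_ids
    ]

    def draw(sample_id: str, parent_idx: int, wheat_cn, alien_cn) -> WindowCounts:
        m_eff = m * jitter[parent_idx]
        rate = lam * m_eff * (wheat_cn + alien_cn) / 2.0 + bg
        return WindowCounts(sample_id=sample_id, counts=rng.poisson(rate), grid=grid)

    base_wheat = np.full(n, 2.0)
    base_wheat[alien_mask] = 0.0
    parents = [
        draw(pid, i, base_wheat, np.zeros(n)) for i, pid in enumerate(cfg.parent_ids)
    ]
    lines = []
    for lid in cfg.line_ids:
        wheat_cn, alien_cn = _copy_numbers(cfg, grid, lid)
        lines.append(draw(lid, cfg.line_parent[lid], wheat_cn, alien_cn))

    pedigree = cfg.pedigree or Pedigree(
        {
            lid: PedigreeEntry(line_id=lid, bc1_id=lid, accession="unknown")
            for lid in cfg.line_ids
        }
    )
    truth = TruthSet(events=list(cfg.events), pedigree=pedigree, line_ids=cfg.line_ids)
    return parents, lines, grid, truth


def default_marker_panel(
    spec: GenomeSpec,
    seed: int,
    spacing: int = 26_000_000,
    jitter: int = 5_000_000,
):
    """A chromosome-specific marker panel at realistic density.

    Markers are laid out on wheat chromosomes at a mean spacing matching
    the published panel (~26 Mb between adjacent markers), with uniform
    positional jitter, so some planted segments fall between flanking
    markers and are invisible to the marker assay.
    """
    from .panels import MarkerPanel

    rng = np.random.default_rng(seed)
    rows = []
    for c in spec.wheat_chromosomes:
        base = np.arange(spacing // 2, c.length, spacing)
        pos = base + rng.integers(-jitter, jitter + 1, size=len(base))
        pos = np.clip(pos, 0, c.length - 1)
        for i, p in enumerate(sorted(set(int(x) for x in pos))):
            rows.append({"marker_id": f"K{c.name}_{i + 1:02d}", "chrom": c.name, "position": p})
    return MarkerPanel(markers=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# evaluation


#: truth class -> called event class (None: matched against leftover segments)
_CLASS_MAP = {
    "substitution_hom": "homoeologous_substitution",
    "substitution_het": "homoeologous_substitution",
    "addition": "whole_chromosome_addition",
    "non_homoeologous_translocation": "non_homoeologous_translocation",
    "wheat_wheat_translocation": "wheat_wheat_translocation",
    "duplication": None,
}


def _truth_primary(ev: TruthEvent) -> tuple[str, int, int]:
    if ev.event_class in ("wheat_wheat_translocation", "duplication"):
        return ev.wheat_chrom, *ev.wheat_interval
    return ev.alien_chrom, *ev.alien_interval


def _call_primary(ev) -> tuple[str, int, int]:
    if isinstance(ev, SegmentCall):
        return ev.chrom, ev.start, ev.end
    seg = ev.alien_segment if ev.alien_segment is not None else ev.wheat_partner
    return seg.chrom, seg.start, seg.end


def _reciprocal(a, b) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


@dataclass
class EvalResult:
    precision: float
    recall: float
    boundary_error_windows: int
    n_truth: int
    n_calls: int
    n_matched: int
    confusion: pd.DataFrame

    def summary(self) -> dict:
        return {
            "precision": round(self.precision, 4),
            "recall": round(self.recall, 4),
            "boundary_error_windows": self.boundary_error_windows,
            "n_truth": self.n_truth,
            "n_calls": self.n_calls,
            "n_matched": self.n_matched,
        }


def evaluate_calls(
    called: dict[str, list[IntrogressionEvent]],
    truth: TruthSet,
    grid: WindowGrid,
    leftover_duplications: dict[str, list[SegmentCall]] | None = None,
    min_overlap: float = 0.5,
) -> EvalResult:
    """Match called events against planted truth.

    A truth event is recovered when a call of the corresponding class (and,
    for substitutions, matching zygosity) in the same line overlaps it
    reciprocally by at least ``min_overlap`` on the primary interval (alien
    side where one exists, wheat side otherwise). Standalone planted
    duplications are matched against duplication segments not consumed as
    translocation evidence. Boundary error is the maximum endpoint
    distance, in windows, over recovered events.
    """
    window = grid.window_size
    leftover_duplications = leftover_duplications or {}
    candidates: list[tuple[str, str, str, object]] = []  # line, class, zygosity, call
    for lid, events in called.items():
        for ev in events:
            candidates.append((lid, ev.event_class, ev.zygosity, ev))
    for lid, dups in leftover_duplications.items():
        for seg in dups:
            candidates.append((lid, "wheat_duplication", "na", seg))

    used = [False] * len(candidates)
    n_matched = 0
    max_boundary = 0
    rows = []
    for tev in truth.events:
        want_class = _CLASS_MAP[tev.event_class] or "wheat_duplication"
        want_zyg = (
            tev.event_class.split("_")[1]
            if tev.event_class.startswith("substitution_")
            else None
        )
        t_chrom, t_start, t_end = _truth_primary(tev)
        best, best_ov = None, 0.0
        for idx, (lid, cls, zyg, call) in enumerate(candidates):
            if used[idx] or lid != tev.line_id or cls != want_class:
                continue
            if want_zyg is not None and zyg != want_zyg:
                continue
            c_chrom, c_start, c_end = _call_primary(call)
            if c_chrom != t_chrom:
                continue
            ov = _reciprocal((t_start, t_end), (c_start, c_end))
            if ov >= min_overlap and ov > best_ov:
                best, best_ov = idx, ov
        recovered = best is not None
        berr = None
        if recovered:
            used[best] = True
            n_matched += 1
            _, c_start, c_end = _call_primary(candidates[best][3])
            berr = max(abs(c_start - t_start), abs(c_end - t_end)) / window
            berr = int(-(-berr // 1))
            max_boundary = max(max_boundary, berr)
        rows.append(
            {
                "line": tev.line_id,
                "truth_class": tev.event_class,
                "recovered": recovered,
                "boundary_error_windows": berr,
            }
        )
    confusion = (
        pd.DataFrame(rows)
        .groupby(["truth_class", "recovered"])
        .size()
        .rename("n")
        .reset_index()
    )
    n_calls = len(candidates)
    return EvalResult(
        precision=n_matched / n_calls if n_calls else 1.0,
        recall=n_matched / len(truth.events) if truth.events else 1.0,
        boundary_error_windows=max_boundary,
        n_truth=len(truth.events),
        n_calls=n_calls,
        n_matched=n_matched,
        confusion=confusion,
    )


def truth_wheat_deviation_means(
    truth: TruthSet, profiles: dict[str, "object"], cfg_window: int
) -> dict[str, list[float]]:
    """Mean wheat-side deviation over each substitution truth interval.

    Returns per-class lists ('substitution_het', 'substitution_hom') used
    to verify the het/hom separation of the deviation statistic.
    """
    out: dict[str, list[float]] = {"substitution_het": [], "substitution_hom": []}
    for ev in truth.events:
        if ev.event_class not in out:
            continue
        prof = profiles[ev.line_id]
        sl = prof.grid.windows_for(ev.wheat_chrom)
        lo = sl.start + ev.wheat_interval[0] // cfg_window
        hi = sl.start + -(-ev.wheat_interval[1] // cfg_window)
        vals = prof.values[lo:hi]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            out[ev.event_class].append(float(np.mean(vals)))
    return out
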