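"""Recombination-junction hotspot clustering and marker-panel detectability.

Junctions are clustered per alien chromosome by single linkage: a junction
joins a cluster when it lies within ``tolerance`` of any member. Clustering
runs on the alien-side coordinate — the alien chromosome is the invariant
axis when the same wild-relative position has recombined into different
wheat subgenomes — and a cluster is a *hotspot* only when its members
descend from at least two distinct BC1 plants (independent meioses).
Non-hotspot clusters are counted as "further recombination sites".

The KASP model is positional: a co-dominant marker panel with a target
density of one marker per 50 Mb detects a replaced wheat interval iff at
least one marker falls inside it; in a whole-chromosome addition every
marker of the group scores heterozygous because all wheat homoeologs are
still present. GISH resolves segments down to ~15 Mb, so a segment smaller
than that floor lying between two flanking markers is invisible to both
assays — these are the segments skim-sequencing uniquely contributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import IntrogressionEvent
from .genome import GenomeSpec, Pedigree

DEFAULT_TARGET_DENSITY = 50_000_000
DEFAULT_GISH_FLOOR = 15_000_000
DEFAULT_HOTSPOT_TOLERANCE = 10_000_000
DEFAULT_WIDE_GAP = 70_000_000


@dataclass
class MarkerPanel:
    """Chromosome-specific marker positions, sorted per chromosome."""

    markers: pd.DataFrame          # columns marker_id, chrom, position
    target_density: int = DEFAULT_TARGET_DENSITY

    def __post_init__(self) -> None:
        need = {"marker_id", "chrom", "position"}
        if not need <= set(self.markers.columns):
            raise ValueError(f"marker table needs columns {sorted(need)}")
        self.markers = (
            self.markers.sort_values(["chrom", "position"]).reset_index(drop=True)
        )

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.markers[self.markers["chrom"] == chrom]
        return sub["position"].to_numpy(dtype=np.int64)

    def validate_against(self, spec: GenomeSpec) -> None:
        for row in self.markers.itertuples(index=False):
            length = spec.chrom(str(row.chrom)).length
            if not 0 <= row.position < length:
                raise ValueError(
                    f"marker {row.marker_id!r} at {row.chrom}:{row.position} outside "
                    f"chromosome bounds [0, {length})"
                )


def load_markers(path, target_density: int = DEFAULT_TARGET_DENSITY) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return MarkerPanel(markers=df, target_density=target_density)


def write_markers(panel: MarkerPanel, path) -> None:
    panel.markers.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class JunctionRecord:
    """One junction observation with its pedigree label and wheat-side context."""

    chrom: str                     # alien chromosome
    position: int
    line_id: str
    bc1_id: str
    wheat_chrom: str = ""
    wheat_position: int = -1


@dataclass
class JunctionCluster:
    chrom: str
    members: list[JunctionRecord]
    center: float = field(init=False)
    span: int = field(init=False)
    n_independent: int = field(init=False)
    is_hotspot: bool = field(init=False)

    def __post_init__(self) -> None:
        pos = [m.position for m in self.members]
        self.center = float(np.mean(pos))
        self.span = max(pos) - min(pos)
        self.n_independent = len({m.bc1_id for m in self.members})
        self.is_hotspot = self.n_independent >= 2

    @property
    def positions(self) -> list[int]:
        return [m.position for m in self.members]


def junction_records(
    events: list[IntrogressionEvent], pedigree: Pedigree, spec: GenomeSpec
) -> list[JunctionRecord]:
    """Alien-side junctions of alien-bearing events, with wheat-side context.

    The wheat partner's junction on the matching side (proximal/proximal,
    distal/distal) is attached where one exists.
    """
    records: list[JunctionRecord] = []
    for ev in events:
        if ev.alien_segment is None:
            continue
        alien_chrom = ev.alien_segment.chrom
        wheat_by_side = {}
        for j in ev.junctions:
            if spec.chrom(j.chrom).is_wheat:
                wheat_by_side[j.side] = j
        for j in ev.junctions:
            if j.chrom != alien_chrom:
                continue
            w = wheat_by_side.get(j.side)
            records.append(
                JunctionRecord(
                    chrom=j.chrom,
                    position=j.position,
                    line_id=ev.sample_id,
                    bc1_id=pedigree.bc1(ev.sample_id),
                    wheat_chrom=w.chrom if w else "",
                    wheat_position=w.position if w else -1,
                )
            )
    return records


def cluster_junctions(
    junctions: list[JunctionRecord],
    spec: GenomeSpec,
    tolerance: int = DEFAULT_HOTSPOT_TOLERANCE,
) -> list[JunctionCluster]:
    """Single-linkage clustering of junctions per chromosome.

    Two junctions on the same chromosome connect when their distance is at
    most ``tolerance``; connectivity is transitive. Output order is by
    chromosome (genome-spec order), then cluster position.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    order = {name: i for i, name in enumerate(spec.names)}
    for j in junctions:
        if j.chrom not in spec:
            raise KeyError(f"junction on unknown chromosome {j.chrom!r}")
    clusters: list[JunctionCluster] = []
    by_chrom: dict[str, list[JunctionRecord]] = {}
    for j in junctions:
        by_chrom.setdefault(j.chrom, []).append(j)
    for chrom in sorted(by_chrom, key=order.__getitem__):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.position, r.line_id))
        current = [recs[0]]
        for r in recs[1:]:
            # sorted 1-D single linkage: adjacent gap within tolerance chains
            if r.position - current[-1].position <= tolerance:
                current.append(r)
            else:
                clusters.append(JunctionCluster(chrom=chrom, members=current))
                current = [r]
        clusters.append(JunctionCluster(chrom=chrom, members=current))
    return clusters


def clusters_frame(clusters: list[JunctionCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "center": int(round(c.center)),
                "span": c.span,
                "n_members": len(c.members),
                "n_independent": c.n_independent,
                "is_hotspot": int(c.is_hotspot),
                "member_lines": ",".join(sorted({m.line_id for m in c.members})),
                "wheat_chroms": ",".join(
                    sorted({m.wheat_chrom for m in c.members if m.wheat_chrom})
                ),
            }
            for c in clusters
        ]
    )


# ---------------------------------------------------------------------------
# marker statistics and detectability


def marker_spacing_stats(
    panel: MarkerPanel,
    spec: GenomeSpec,
    wide_gap: int = DEFAULT_WIDE_GAP,
) -> tuple[float, int, pd.DataFrame]:
    """(mean adjacent gap, number of gaps over ``wide_gap``, per-chromosome table).

    Gaps are measured between adjacent markers on the same chromosome only;
    distances to chromosome ends are not gaps. Chromosomes with fewer than
    two markers contribute none.
    """
    if len(panel.markers) == 0:
        raise ValueError("empty marker panel")
    rows = []
    all_gaps: list[int] = []
    for chrom in panel.markers["chrom"].unique():
        pos = panel.positions(str(chrom))
        gaps = np.diff(pos)
        all_gaps.extend(int(g) for g in gaps)
        rows.append(
            {
                "chrom": chrom,
                "n_markers": len(pos),
                "n_gaps": len(gaps),
                "mean_gap": float(gaps.mean()) if len(gaps) else float("nan"),
                "max_gap": int(gaps.max()) if len(gaps) else 0,
                "n_over": int((gaps > wide_gap).sum()) if len(gaps) else 0,
            }
        )
    table = pd.DataFrame(rows)
    mean_gap = float(np.mean(all_gaps)) if all_gaps else float("nan")
    n_over = int(sum(g > wide_gap for g in all_gaps))
    return mean_gap, n_over, table


def predict_detectability(
    chrom: str,
    start: int,
    end: int,
    panel: MarkerPanel,
    gish_floor: int = DEFAULT_GISH_FLOOR,
) -> tuple[bool, bool]:
    """(kasp_detectable, gish_detectable) for a replaced wheat interval.

    KASP sees the segment iff >= 1 marker position lies in [start, end);
    GISH resolves it iff its length reaches the size floor.
    """
    pos = panel.positions(chrom)
    kasp = bool(np.any((pos >= start) & (pos < end)))
    gish = (end - start) >= gish_floor
    return kasp, gish


def predict_kasp_calls(
    events: list[IntrogressionEvent],
    panel: MarkerPanel,
    spec: GenomeSpec,
) -> pd.DataFrame:
    """Predicted per-marker genotype call for one line's events.

    A marker inside a homozygous substitution's replaced wheat interval
    calls ``alien_hom``; inside a heterozygous one, ``het``. Every marker
    whose group carries a whole-chromosome addition calls ``het`` (all
    wheat homoeologs are still present). All other markers call
    ``wheat_hom``.
    """
    addition_groups = {
        spec.chrom(ev.alien_segment.chrom).group
        for ev in events
        if ev.event_class == "whole_chromosome_addition"
    }
    calls = []
    for row in panel.markers.itertuples(index=False):
        chrom, pos = str(row.chrom), int(row.position)
        call = "wheat_hom"
        if spec.chrom(chrom).group in addition_groups:
            call = "het"
        for ev in events:
            if ev.event_class != "homoeologous_substitution":
                continue
            w = ev.wheat_partner
            if w.chrom == chrom and w.start <= pos < w.end:
                call = "alien_hom" if ev.zygosity == "hom" else "het"
                break
        calls.append({"marker_id": row.marker_id, "chrom": chrom, "position": pos, "call": call})
    return pd.DataFrame(calls)


def propose_markers(
    undetected: list[tuple[str, int, int]],
    panel: MarkerPanel,
    spec: GenomeSpec,
    target_density: int | None = None,
) -> pd.DataFrame:
    """Marker positions closing the panel's blind spots.

    One proposal at the midpoint of every KASP-undetectable segment, plus
    fill-in positions splitting every adjacent gap wider than the target
    density into equal sub-intervals below it.
    """
    density = target_density if target_density is not None else panel.target_density
    rows = []
    for chrom, start, end in undetected:
        rows.append(
            {
                "chrom": chrom,
                "position": (start + end) // 2,
                "reason": f"undetected_segment:{start}-{end}",
            }
        )
    for chrom in panel.markers["chrom"].unique():
        pos = panel.positions(str(chrom))
        for a, b in zip(pos[:-1], pos[1:]):
            gap = int(b - a)
            if gap <= density:
                continue
            k = math.ceil(gap / density) - 1    # minimal equal partition below target
            for i in range(1, k + 1):
                rows.append(
                    {
                        "chrom": str(chrom),
                        "position": int(a + round(i * gap / (k + 1))),
                        "reason": f"gap_fill:{int(a)}-{int(b)}",
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "position", "reason"])
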