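"""Pedigree-aware unique-introgression accounting and resource statistics.

Introgressions descending from distinct BC1 plants arose from independent
recombination events in different F1 gametes, so they are distinct even
when their coordinates coincide. Within one BC1 family, segments on the
same alien chromosome are the same original introgression (possibly
trimmed by later recombination) when they overlap reciprocally by at least
``overlap_min``; the merged record keeps the union interval. Whole-
chromosome additions are listed but excluded from uniqueness counts and
size statistics.

Unique introgressions are coded ``<alienChrom>.<targetGenome><serial>``
(e.g. ``2T.D11``: a 2T segment recombined into the D genome), serials
assigned in descending size order within each alien-chromosome x target
combination. Serials are regenerated here, not matched to historical
numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calling import IntrogressionEvent
from .genome import GenomeSpec, Pedigree


@dataclass
class UniqueIntrogression:
    uid: int
    code: str
    alien_chrom: str
    start: int
    end: int
    wheat_target: str              # subgenome letter + chromosome, or "addition"
    target_genome: str             # A / B / D, or "" for additions/unresolved
    bc1_id: str
    accession: str
    member_lines: list[str]
    zygosity: str = "na"

    @property
    def length(self) -> int:
        return self.end - self.start


def _event_target(ev: IntrogressionEvent, spec: GenomeSpec) -> tuple[str, str]:
    """(target label, target genome letter) of an alien-bearing event."""
    if ev.event_class == "homoeologous_substitution":
        c = ev.wheat_partner.chrom
        return c, spec.chrom(c).subgenome
    if ev.event_class == "non_homoeologous_translocation":
        c = ev.supporting_duplication.chrom
        return c, spec.chrom(c).subgenome
    if ev.event_class == "whole_chromosome_addition":
        return "addition", ""
    return "", ""


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def dedup_unique(
    events: list[IntrogressionEvent],
    pedigree: Pedigree,
    spec: GenomeSpec,
    overlap_min: float = 0.8,
) -> list[UniqueIntrogression]:
    """Collapse per-line events into unique introgressions.

    Only events carrying an alien segment and a wheat target take part
    (substitutions and non-homoeologous translocations); additions and
    unresolved gains are excluded from uniqueness accounting. Merging is
    single-linkage within (alien chromosome, BC1) at reciprocal overlap
    >= ``overlap_min``; output is invariant to input event order.
    """
    candidates = []
    for ev in events:
        if ev.event_class not in (
            "homoeologous_substitution",
            "non_homoeologous_translocation",
        ):
            continue
        if ev.sample_id not in pedigree:
            raise KeyError(f"line {ev.sample_id!r} absent from pedigree")
        target, letter = _event_target(ev, spec)
        seg = ev.alien_segment
        candidates.append(
            {
                "line": ev.sample_id,
                "bc1": pedigree.bc1(ev.sample_id),
                "accession": pedigree.accession(ev.sample_id),
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "target": target,
                "letter": letter,
                "zygosity": ev.zygosity,
            }
        )
    # deterministic processing order regardless of caller ordering
    candidates.sort(key=lambda c: (c["chrom"], c["bc1"], c["start"], c["end"], c["line"]))

    # single-linkage union-find: same alien chromosome, same BC1 family,
    # reciprocal overlap >= overlap_min
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(candidates):
        for j in range(i + 1, len(candidates)):
            b = candidates[j]
            if a["chrom"] != b["chrom"] or a["bc1"] != b["bc1"]:
                continue
            if (
                _reciprocal_overlap((a["start"], a["end"]), (b["start"], b["end"]))
                >= overlap_min
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    grouped: dict[int, list[dict]] = {}
    for i, cand in enumerate(candidates):
        grouped.setdefault(find(i), []).append(cand)
    clusters = [grouped[k] for k in sorted(grouped)]

    uniques: list[UniqueIntrogression] = []
    for cl in clusters:
        start = min(m["start"] for m in cl)
        end = max(m["end"] for m in cl)
        # the largest member defines the wheat target of the merged record
        rep = max(cl, key=lambda m: m["end"] - m["start"])
        uniques.append(
            UniqueIntrogression(
                uid=0,
                code="",
                alien_chrom=cl[0]["chrom"],
                start=start,
                end=end,
                wheat_target=rep["target"],
                target_genome=rep["letter"],
                bc1_id=cl[0]["bc1"],
                accession=cl[0]["accession"],
                member_lines=sorted({m["line"] for m in cl}),
                zygosity=rep["zygosity"],
            )
        )

    # code serials per (alien chromosome, target genome), largest first
    uniques.sort(key=lambda u: (u.alien_chrom, u.target_genome, -u.length, u.start, u.bc1_id))
    serial: dict[tuple[str, str], int] = {}
    for i, u in enumerate(uniques):
        key = (u.alien_chrom, u.target_genome)
        serial[key] = serial.get(key, 0) + 1
        u.uid = i + 1
        u.code = f"{u.alien_chrom}.{u.target_genome or 'X'}{serial[key]}"
    return uniques


# ---------------------------------------------------------------------------
# interval-union coverage


def interval_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class TransferReport:
    scope: str
    covered_bp: int
    total_bp: int
    fraction: float                # percent
    gaps: list[tuple[str, int, int, int]]   # chrom, start, end, length

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "covered_bp": self.covered_bp,
            "total_bp": self.total_bp,
            "fraction_pct": round(self.fraction, 3),
            "gaps": [
                {"chrom": c, "start": s, "end": e, "length": l} for c, s, e, l in self.gaps
            ],
        }


def transfer_fraction(
    uniques: list[UniqueIntrogression],
    spec: GenomeSpec,
    scope: str = "all",
) -> TransferReport:
    """Fraction of the alien genome covered by the union of introgressions.

    ``scope`` is ``"all"``, ``"accession:<id>"`` or ``"chromosome:<name>"``.
    Overlapping segments count once; gaps are the maximal uncovered
    intervals of the in-scope alien chromosomes.
    """
    if scope == "all":
        chroms = [c.name for c in spec.alien_chromosomes]
        pool = uniques
    elif scope.startswith("accession:"):
        acc = scope.split(":", 1)[1]
        chroms = [c.name for c in spec.alien_chromosomes]
        pool = [u for u in uniques if u.accession == acc]
    elif scope.startswith("chromosome:"):
        name = scope.split(":", 1)[1]
        if name not in spec:
            raise KeyError(f"unknown chromosome {name!r}")
        chroms = [name]
        pool = [u for u in uniques if u.alien_chrom == name]
    else:
        raise ValueError(f"unresolvable scope {scope!r}")
    if not chroms:
        raise ValueError(f"scope {scope!r} selects no chromosomes")

    covered = 0
    total = 0
    gaps: list[tuple[str, int, int, int]] = []
    for name in chroms:
        length = spec.chrom(name).length
        total += length
        merged = interval_union(
            [(u.start, min(u.end, length)) for u in pool if u.alien_chrom == name]
        )
        covered += sum(e - s for s, e in merged)
        cursor = 0
        for s, e in merged:
            if s > cursor:
                gaps.append((name, cursor, s, s - cursor))
            cursor = e
        if cursor < length:
            gaps.append((name, cursor, length, length - cursor))
    return TransferReport(
        scope=scope,
        covered_bp=covered,
        total_bp=total,
        fraction=100.0 * covered / total,
        gaps=gaps,
    )


def size_stats(uniques: list[UniqueIntrogression]) -> tuple[float, float, int, int]:
    """(mean, median, min, max) of unique-introgression lengths, additions excluded."""
    lengths = [u.length for u in uniques if u.wheat_target != "addition"]
    if not lengths:
        raise ValueError("no unique introgressions to summarise")
    arr = np.asarray(lengths, dtype=float)
    return float(arr.mean()), float(np.median(arr)), int(arr.min()), int(arr.max())


def genome_share(uniques: list[UniqueIntrogression]) -> dict[str, float]:
    """Percent of targeted uniques recombined into each wheat subgenome."""
    targeted = [u for u in uniques if u.target_genome in ("A", "B", "D")]
    n = len(targeted)
    share = {g: 0.0 for g in ("A", "B", "D")}
    if n == 0:
        return share
    for u in targeted:
        share[u.target_genome] += 1
    return {g: 100.0 * v / n for g, v in share.items()}


def chromosome_summary(
    uniques: list[UniqueIntrogression],
    clusters: list | None,
    spec: GenomeSpec,
) -> pd.DataFrame:
    """Per-alien-chromosome counts by accession, plus hotspot columns.

    ``clusters`` is the output of :func:`introskim.panels.cluster_junctions`
    (may be None when clustering was not run). The totals row equals the
    column sums; the sum of per-chromosome totals equals the number of
    uniques.
    """
    accessions = sorted({u.accession for u in uniques})
    rows = []
    for c in spec.alien_chromosomes:
        on_chrom = [u for u in uniques if u.alien_chrom == c.name]
        row = {"chrom": c.name}
        for acc in accessions:
            row[acc] = sum(1 for u in on_chrom if u.accession == acc)
        row["total"] = len(on_chrom)
        if clusters is not None:
            here = [cl for cl in clusters if cl.chrom == c.name]
            row["hotspots"] = sum(1 for cl in here if cl.is_hotspot)
            row["further_sites"] = sum(1 for cl in here if not cl.is_hotspot)
        rows.append(row)
    df = pd.DataFrame(rows)
    totals = {"chrom": "total"}
    for col in df.columns[1:]:
        totals[col] = int(df[col].sum())
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def uniques_frame(uniques: list[UniqueIntrogression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "uid": u.uid,
                "code": u.code,
                "alien_chrom": u.alien_chrom,
                "start": u.start,
                "end": u.end,
                "target": u.wheat_target,
                "bc1": u.bc1_id,
                "accession": u.accession,
                "n_lines": len(u.member_lines),
                "lines": ",".join(u.member_lines),
            }
            for u in uniques
        ]
    )


# ---------------------------------------------------------------------------
# published line-code table


def load_line_codes() -> pd.DataFrame:
    """The published line -> introgression-code table shipped with the package.

    One row per introgression code; ``skim_only`` marks segments that were
    found by skim-sequencing but missed by both the KASP panel and GISH.
    """
    with resources.files("introskim.data").joinpath("line_codes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    rows = []
    for row in df.itertuples(index=False):
        for code in str(row.codes).split(","):
            rows.append(
                {
                    "line_id": row.line_id,
                    "code": code.rstrip("*"),
                    "skim_only": code.endswith("*"),
                }
            )
    return pd.DataFrame(rows)


def line_code_stats(codes: pd.DataFrame) -> dict[str, int]:
    per_line = codes.groupby("line_id").size()
    return {
        "n_lines": int(codes["line_id"].nunique()),
        "n_introgression_entries": int(len(codes)),
        "max_per_line": int(per_line.max()),
        "n_skim_only": int(codes["skim_only"].sum()),
    }
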