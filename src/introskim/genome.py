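"""Genome catalogue, window grid, homoeology relations and windowed-count I/O.

The analysis runs on a concatenated reference: the three wheat subgenomes
(A, B, D) plus the T genome of the wild relative. Chromosomes carry a
homoeologous group number (1-7); homoeology is inferred from shared group
numbers (e.g. 5A, 5B, 5D and 5T form one group). All coordinates are
0-based, half-open, both internally and in the BED-like files; windows tile
each chromosome without gaps, the last window of a chromosome being allowed
to run short.

File formats (UTF-8, tab-delimited, ``#`` comment lines ignored, gzip
accepted wherever pandas accepts it):

* genome spec: columns ``chrom  length  subgenome  group  [centromere]``
* per-sample counts: BED-like ``chrom  start  end  count``
* wide counts: ``chrom  start  end  <sample1>  <sample2> ...``
* pedigree: ``line_id  bc1_id  accession  [notes]``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WHEAT_SUBGENOMES = ("A", "B", "D")
ALIEN_SUBGENOME = "T"
VALID_SUBGENOMES = WHEAT_SUBGENOMES + (ALIEN_SUBGENOME,)

DEFAULT_WINDOW_SIZE = 1_000_000


class GenomeSpecError(ValueError):
    """Invalid genome-spec content."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    subgenome: str
    group: int
    centromere: int | None = None

    @property
    def is_wheat(self) -> bool:
        return self.subgenome in WHEAT_SUBGENOMES

    @property
    def is_alien(self) -> bool:
        return self.subgenome == ALIEN_SUBGENOME


@dataclass
class GenomeSpec:
    """Ordered chromosome catalogue with subgenome labels and group numbers."""

    chromosomes: list[Chromosome]
    _by_name: dict[str, Chromosome] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, Chromosome] = {}
        for i, c in enumerate(self.chromosomes):
            if c.name in seen:
                raise GenomeSpecError(f"duplicate chromosome name {c.name!r} (row {i})")
            if c.length <= 0:
                raise GenomeSpecError(f"chromosome {c.name!r}: non-positive length {c.length}")
            if c.subgenome not in VALID_SUBGENOMES:
                raise GenomeSpecError(
                    f"chromosome {c.name!r}: unknown subgenome {c.subgenome!r} "
                    f"(expected one of {'/'.join(VALID_SUBGENOMES)})"
                )
            if not 1 <= c.group <= 7:
                raise GenomeSpecError(f"chromosome {c.name!r}: group {c.group} outside 1-7")
            if c.centromere is not None and not 0 < c.centromere < c.length:
                raise GenomeSpecError(
                    f"chromosome {c.name!r}: centromere {c.centromere} outside (0, {c.length})"
                )
            seen[c.name] = c
        object.__setattr__(self, "_by_name", seen)

    def __iter__(self):
        return iter(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def wheat_chromosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.is_wheat]

    @property
    def alien_chromosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.is_alien]

    def homoeologs(self, name: str) -> set[str]:
        """All other chromosomes sharing this chromosome's group number."""
        c = self.chrom(name)
        return {o.name for o in self.chromosomes if o.group == c.group and o.name != c.name}


def homoeologs(spec: GenomeSpec, chrom: str) -> set[str]:
    return spec.homoeologs(chrom)


@dataclass
class WindowGrid:
    """Non-overlapping window tiling of every chromosome of a genome spec."""

    window_size: int
    chroms: np.ndarray          # window chromosome names, object dtype
    starts: np.ndarray          # int64, 0-based
    ends: np.ndarray            # int64, half-open
    chrom_slices: dict[str, slice]

    @property
    def n(self) -> int:
        return len(self.starts)

    def windows_for(self, chrom: str) -> slice:
        return self.chrom_slices[chrom]

    def subgenome_mask(self, spec: GenomeSpec, subgenomes) -> np.ndarray:
        wanted = {c.name for c in spec if c.subgenome in set(subgenomes)}
        return np.fromiter((c in wanted for c in self.chroms), bool, self.n)

    def wheat_mask(self, spec: GenomeSpec) -> np.ndarray:
        return self.subgenome_mask(spec, WHEAT_SUBGENOMES)

    def alien_mask(self, spec: GenomeSpec) -> np.ndarray:
        return self.subgenome_mask(spec, (ALIEN_SUBGENOME,))

    def same_grid(self, other: "WindowGrid") -> bool:
        return (
            self.window_size == other.window_size
            and self.n == other.n
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})


def make_windows(spec: GenomeSpec, window_size: int = DEFAULT_WINDOW_SIZE) -> WindowGrid:
    """Tile each chromosome with half-open windows of ``window_size`` bp.

    Per chromosome, ceil(length / window_size) windows; the last window may
    be shorter.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    slices: dict[str, slice] = {}
    for c in spec:
        n = math.ceil(c.length / window_size)
        lo = len(starts)
        for i in range(n):
            chroms.append(c.name)
            starts.append(i * window_size)
            ends.append(min((i + 1) * window_size, c.length))
        slices[c.name] = slice(lo, len(starts))
    return WindowGrid(
        window_size=window_size,
        chroms=np.array(chroms, dtype=object),
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        chrom_slices=slices,
    )


@dataclass
class WindowCounts:
    """Per-window read counts of one sample, aligned to a WindowGrid."""

    sample_id: str
    counts: np.ndarray
    grid: WindowGrid

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) != self.grid.n:
            raise ValueError(
                f"sample {self.sample_id!r}: count vector length {len(self.counts)} "
                f"does not match grid ({self.grid.n} windows)"
            )
        if (self.counts < 0).any():
            i = int(np.argmax(self.counts < 0))
            raise ValueError(
                f"sample {self.sample_id!r}: negative count at "
                f"{self.grid.chroms[i]}:{self.grid.starts[i]}-{self.grid.ends[i]}"
            )


def ensure_same_grid(*samples: WindowCounts) -> WindowGrid:
    grid = samples[0].grid
    for s in samples[1:]:
        if s.grid is not grid and not grid.same_grid(s.grid):
            raise ValueError(
                f"samples {samples[0].sample_id!r} and {s.sample_id!r} are on different "
                "window grids; re-binning is not implicit"
            )
    return grid


@dataclass(frozen=True)
class PedigreeEntry:
    line_id: str
    bc1_id: str
    accession: str
    notes: str = ""


@dataclass
class Pedigree:
    """Line -> (BC1 ancestor, source accession) mapping.

    Lines descending from distinct BC1 plants carry independently generated
    recombination events; this drives unique-introgression accounting and
    hotspot independence.
    """

    entries: dict[str, PedigreeEntry]

    def __contains__(self, line_id: str) -> bool:
        return line_id in self.entries

    def __getitem__(self, line_id: str) -> PedigreeEntry:
        try:
            return self.entries[line_id]
        except KeyError:
            raise KeyError(f"line {line_id!r} absent from pedigree") from None

    def bc1(self, line_id: str) -> str:
        return self[line_id].bc1_id

    def accession(self, line_id: str) -> str:
        return self[line_id].accession


# ---------------------------------------------------------------------------
# I/O


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def load_genome_spec(path) -> GenomeSpec:
    df = _read_tsv(path)
    required = {"chrom", "length", "subgenome", "group"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeSpecError(f"genome spec {path}: missing columns {sorted(missing)}")
    chroms = []
    for row in df.itertuples(index=False):
        cen = getattr(row, "centromere", None)
        if cen is not None and pd.isna(cen):
            cen = None
        chroms.append(
            Chromosome(
                name=str(row.chrom),
                length=int(row.length),
                subgenome=str(row.subgenome),
                group=int(row.group),
                centromere=None if cen is None else int(cen),
            )
        )
    return GenomeSpec(chroms)


def write_genome_spec(spec: GenomeSpec, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [c.name for c in spec],
            "length": [c.length for c in spec],
            "subgenome": [c.subgenome for c in spec],
            "group": [c.group for c in spec],
            "centromere": [c.centromere if c.centromere is not None else "" for c in spec],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_counts(path, grid: WindowGrid, sample_id: str | None = None) -> WindowCounts:
    """Read a 4-column BED-like counts file and align it to ``grid``.

    Every grid window must be present exactly once; missing windows are an
    error, not an implicit zero.
    """
    df = _read_tsv(path)
    cols = list(df.columns[:4])
    df = df.rename(columns=dict(zip(cols, ["chrom", "start", "end", "count"])))
    known = set(grid.chrom_slices)
    bad = set(df["chrom"]) - known
    if bad:
        raise ValueError(f"counts file {path}: unknown chromosome(s) {sorted(bad)}")
    table = {
        (c, int(s), int(e)): int(v)
        for c, s, e, v in zip(df["chrom"], df["start"], df["end"], df["count"])
    }
    counts = np.empty(grid.n, dtype=np.int64)
    missing = []
    for i in range(grid.n):
        key = (grid.chroms[i], int(grid.starts[i]), int(grid.ends[i]))
        if key not in table:
            missing.append(f"{key[0]}:{key[1]}-{key[2]}")
            continue
        counts[i] = table[key]
    if missing:
        shown = ", ".join(missing[:5]) + ("..." if len(missing) > 5 else "")
        raise ValueError(f"counts file {path}: missing window(s) {shown}")
    if sample_id is None:
        sample_id = Path(str(path)).name.split(".")[0]
    return WindowCounts(sample_id=sample_id, counts=counts, grid=grid)


def write_counts(sample: WindowCounts, path) -> None:
    df = sample.grid.to_frame()
    df["count"] = sample.counts
    df.to_csv(path, sep="\t", index=False)


def load_counts_wide(path, grid: WindowGrid) -> list[WindowCounts]:
    """Read a wide counts table (one column per sample) against ``grid``."""
    df = _read_tsv(path)
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    out = []
    for s in samples:
        sub = df[["chrom", "start", "end", s]]
        key = {
            (c, int(a), int(b)): int(v)
            for c, a, b, v in zip(sub["chrom"], sub["start"], sub["end"], sub[s])
        }
        counts = np.empty(grid.n, dtype=np.int64)
        for i in range(grid.n):
            k = (grid.chroms[i], int(grid.starts[i]), int(grid.ends[i]))
            if k not in key:
                raise ValueError(f"wide counts {path}: sample {s!r} missing window {k}")
            counts[i] = key[k]
        out.append(WindowCounts(sample_id=s, counts=counts, grid=grid))
    return out


def load_pedigree(path) -> Pedigree:
    df = _read_tsv(path)
    entries: dict[str, PedigreeEntry] = {}
    for row in df.itertuples(index=False):
        lid = str(row.line_id)
        if lid in entries:
            raise ValueError(f"pedigree {path}: duplicate line {lid!r}")
        entries[lid] = PedigreeEntry(
            line_id=lid,
            bc1_id=str(row.bc1_id),
            accession=str(row.accession),
            notes=str(getattr(row, "notes", "") or ""),
        )
    return Pedigree(entries)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        [
            {"line_id": e.line_id, "bc1_id": e.bc1_id, "accession": e.accession, "notes": e.notes}
            for e in ped.entries.values()
        ]
    )
    df.to_csv(path, sep="\t", index=False)
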