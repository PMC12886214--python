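"""End-to-end orchestration: counts in, characterised introgressions out.

``analyse_panel`` is the in-memory pipeline (deviation -> segment calling
-> event pairing) used by the CLI, the tests and the acceptance script;
``run_pipeline`` wraps it with file I/O, producing one artefact per
analysis stage plus a structured log of every threshold used. Runs are
deterministic: identical inputs and config give byte-identical non-log
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import calling, deviation, panels, summarise
from .calling import Thresholds
from .genome import (
    GenomeSpec,
    Pedigree,
    WindowCounts,
    WindowGrid,
    load_counts,
    load_genome_spec,
    load_pedigree,
    make_windows,
)


@dataclass
class RunConfig:
    genome: str
    counts_dir: str
    parents: list[str]
    pedigree: str
    markers: str
    outdir: str
    window_size: int = 1_000_000
    mask_floor: float = deviation.DEFAULT_MASK_FLOOR
    upper_decile: float = deviation.DEFAULT_UPPER_DECILE
    clip_at: float = deviation.DEFAULT_CLIP_AT
    calling: dict = field(default_factory=dict)
    overlap_min: float = 0.8
    hotspot_tolerance: int = panels.DEFAULT_HOTSPOT_TOLERANCE
    gish_floor: int = panels.DEFAULT_GISH_FLOOR
    plot: bool = False

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return RunConfig(**data)

    def thresholds(self) -> Thresholds:
        kw = dict(self.calling)
        if "het_band" in kw:
            kw["het_band"] = tuple(kw["het_band"])
        return Thresholds(**kw)


@dataclass
class PanelAnalysis:
    profiles: dict
    segments: dict                 # line -> {losses, gains, duplications}
    events: dict                   # line -> list[IntrogressionEvent]
    leftover_duplications: dict
    unpaired_losses: dict

    @property
    def all_events(self) -> list:
        return [ev for evs in self.events.values() for ev in evs]


def analyse_panel(
    parents: list[WindowCounts],
    lines: list[WindowCounts],
    spec: GenomeSpec,
    grid: WindowGrid,
    th: Thresholds = Thresholds(),
    mask_floor: float = deviation.DEFAULT_MASK_FLOOR,
    upper_decile: float = deviation.DEFAULT_UPPER_DECILE,
    clip_at: float = deviation.DEFAULT_CLIP_AT,
) -> PanelAnalysis:
    """Deviation, segment calling and event pairing for every line."""
    profiles, segments, events = {}, {}, {}
    leftover, unpaired = {}, {}
    for line in lines:
        prof = deviation.compute_profile(
            line, parents, spec, grid, mask_floor, upper_decile, clip_at
        )
        segs = calling.call_segments(prof, spec, th)
        evs = calling.pair_events(
            segs["losses"], segs["gains"], segs["duplications"], spec, th
        )
        used_dups = {id(ev.supporting_duplication) for ev in evs}
        profiles[line.sample_id] = prof
        segments[line.sample_id] = segs
        events[line.sample_id] = evs
        leftover[line.sample_id] = [
            d for d in segs["duplications"] if id(d) not in used_dups
        ]
        unpaired[line.sample_id] = calling.unpaired_losses(segs["losses"], evs)
    return PanelAnalysis(
        profiles=profiles,
        segments=segments,
        events=events,
        leftover_duplications=leftover,
        unpaired_losses=unpaired,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis from files; returns the artefact manifest."""
    for name in ("genome", "pedigree", "markers"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    counts_dir = Path(cfg.counts_dir)
    if not counts_dir.is_dir():
        raise FileNotFoundError(f"counts directory not found: {counts_dir}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spec = load_genome_spec(cfg.genome)
    grid = make_windows(spec, cfg.window_size)
    pedigree = load_pedigree(cfg.pedigree)
    panel = panels.load_markers(cfg.markers)
    panel.validate_against(spec)
    th = cfg.thresholds()

    parent_files = {Path(p).name.split(".")[0]: p for p in cfg.parents}
    parents = [load_counts(p, grid) for p in cfg.parents]
    line_files = sorted(
        f for f in counts_dir.glob("*.tsv") if f.name.split(".")[0] not in parent_files
    )
    if not line_files:
        raise FileNotFoundError(f"no line counts files under {counts_dir}")
    lines = [load_counts(f, grid) for f in line_files]

    result = analyse_panel(
        parents, lines, spec, grid, th, cfg.mask_floor, cfg.upper_decile, cfg.clip_at
    )

    manifest: dict[str, object] = {}

    # 1. deviation profiles
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for lid, prof in sorted(result.profiles.items()):
        deviation.write_profile(prof, prof_dir / f"{lid}.deviation.tsv")
    manifest["profiles"] = sorted(str(p.relative_to(outdir)) for p in prof_dir.glob("*.tsv"))

    # 2. segment calls
    all_segs = [
        s
        for lid in sorted(result.segments)
        for kind in ("losses", "gains", "duplications")
        for s in result.segments[lid][kind]
    ]
    seg_path = outdir / "segments.bed"
    calling.segments_frame(all_segs).to_csv(seg_path, sep="\t", index=False)
    manifest["segments"] = str(seg_path.relative_to(outdir))

    # 3. events
    ev_path = outdir / "events.json"
    with open(ev_path, "w") as fh:
        json.dump(
            [calling.event_record(ev) for lid in sorted(result.events) for ev in result.events[lid]],
            fh,
            indent=2,
        )
    calling.events_frame(result.all_events).to_csv(
        outdir / "events.tsv", sep="\t", index=False
    )
    manifest["events"] = str(ev_path.relative_to(outdir))

    # 4. unique introgressions
    uniques = summarise.dedup_unique(result.all_events, pedigree, spec, cfg.overlap_min)
    uniq_path = outdir / "unique_introgressions.tsv"
    summarise.uniques_frame(uniques).to_csv(uniq_path, sep="\t", index=False)
    manifest["unique_introgressions"] = str(uniq_path.relative_to(outdir))

    # 5. transfer report
    report = summarise.transfer_fraction(uniques, spec, "all")
    per_acc = {
        acc: summarise.transfer_fraction(uniques, spec, f"accession:{acc}").fraction
        for acc in sorted({u.accession for u in uniques})
    }
    transfer_path = outdir / "transfer.json"
    with open(transfer_path, "w") as fh:
        json.dump({**report.to_dict(), "per_accession_pct": per_acc}, fh, indent=2)
    manifest["transfer"] = str(transfer_path.relative_to(outdir))

    # 6. junction clusters / hotspots
    junctions = panels.junction_records(result.all_events, pedigree, spec)
    clusters = panels.cluster_junctions(junctions, spec, cfg.hotspot_tolerance)
    hot_path = outdir / "hotspots.tsv"
    panels.clusters_frame(clusters).to_csv(hot_path, sep="\t", index=False)
    manifest["hotspots"] = str(hot_path.relative_to(outdir))

    # 7. marker-panel report
    mean_gap, n_over, spacing_table = panels.marker_spacing_stats(panel, spec)
    detect_rows = []
    undetected = []
    for ev in result.all_events:
        if ev.wheat_partner is None or ev.event_class != "homoeologous_substitution":
            continue
        w = ev.wheat_partner
        kasp, gish = panels.predict_detectability(
            w.chrom, w.start, w.end, panel, cfg.gish_floor
        )
        detect_rows.append(
            {
                "sample": ev.sample_id,
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "kasp_detectable": kasp,
                "gish_detectable": gish,
            }
        )
        if not kasp:
            undetected.append((w.chrom, w.start, w.end))
    proposals = panels.propose_markers(undetected, panel, spec)
    proposals.to_csv(outdir / "marker_proposals.tsv", sep="\t", index=False)
    panel_path = outdir / "panel_report.json"
    with open(panel_path, "w") as fh:
        json.dump(
            {
                "mean_adjacent_gap_bp": round(mean_gap, 1),
                "n_gaps_over_70Mb": n_over,
                "n_hotspots": sum(1 for c in clusters if c.is_hotspot),
                "n_further_sites": sum(1 for c in clusters if not c.is_hotspot),
                "segments": detect_rows,
                "n_kasp_silent": sum(1 for r in detect_rows if not r["kasp_detectable"]),
            },
            fh,
            indent=2,
        )
    manifest["panel_report"] = str(panel_path.relative_to(outdir))
    manifest["summary_table"] = "chromosome_summary.tsv"
    summarise.chromosome_summary(uniques, clusters, spec).to_csv(
        outdir / "chromosome_summary.tsv", sep="\t", index=False
    )

    # 8. run log: every threshold plus per-line hidden quantities
    log = {
        "thresholds": dataclasses.asdict(th),
        "mask_floor": cfg.mask_floor,
        "upper_decile": cfg.upper_decile,
        "clip_at": cfg.clip_at,
        "overlap_min": cfg.overlap_min,
        "hotspot_tolerance": cfg.hotspot_tolerance,
        "gish_floor": cfg.gish_floor,
        "lines": {
            lid: {
                "chosen_parent": prof.chosen_parent,
                "alien_baseline": prof.alien_baseline,
            }
            for lid, prof in sorted(result.profiles.items())
        },
    }
    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2)
    manifest["run_log"] = str(log_path.relative_to(outdir))

    if cfg.plot:
        plot_dir = outdir / "plots"
        plot_dir.mkdir(exist_ok=True)
        for lid, prof in sorted(result.profiles.items()):
            plot_profile(
                prof, spec, result.events[lid], plot_dir / f"{lid}.png"
            )
        manifest["plots"] = sorted(str(p.relative_to(outdir)) for p in plot_dir.glob("*.png"))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def plot_profile(profile, spec: GenomeSpec, events, path) -> None:
    """Per-line deviation plot, one facet row per subgenome, y clipped at 2.

    Aberrant windows are highlighted in red only when the paired-evidence
    rule holds, i.e. the segment belongs to an event that includes an
    alien-coverage gain; wheat-wheat rearrangement segments are drawn in
    green.
    """
    grid = profile.grid
    supported = np.zeros(grid.n, dtype=bool)
    intra_wheat = np.zeros(grid.n, dtype=bool)
    for ev in events:
        segs = [ev.alien_segment, ev.wheat_partner, ev.supporting_duplication]
        target = supported if ev.alien_segment is not None else intra_wheat
        for seg in segs:
            if seg is not None and seg.i0 >= 0:
                target[seg.i0 : seg.i1] = True

    subgenomes = ("A", "B", "D", "T")
    fig, axes = plt.subplots(4, 1, figsize=(12, 9), sharey=True)
    disp = profile.display_values
    for ax, sg in zip(axes, subgenomes):
        offset = 0
        ticks, labels = [], []
        for c in spec:
            if c.subgenome != sg:
                continue
            sl = grid.windows_for(c.name)
            x = offset + (grid.starts[sl] + grid.ends[sl]) / 2
            y = disp[sl]
            base = ~(supported[sl] | intra_wheat[sl])
            ax.plot(x[base], y[base], ".", color="0.55", ms=3)
            if supported[sl].any():
                ax.plot(x[supported[sl]], y[supported[sl]], ".", color="crimson", ms=4)
            if intra_wheat[sl].any():
                ax.plot(x[intra_wheat[sl]], y[intra_wheat[sl]], ".", color="seagreen", ms=4)
            ticks.append(offset + c.length / 2)
            labels.append(c.name)
            offset += c.length
            ax.axvline(offset, color="0.85", lw=0.5)
        ax.set_xticks(ticks)
        ax.set_xticklabels(labels, fontsize=8)
        ax.set_ylim(-0.05, profile.clip_at + 0.1)
        ax.set_ylabel(f"{sg} deviation")
    axes[0].set_title(f"{profile.sample_id} (parent: {profile.chosen_parent})")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
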