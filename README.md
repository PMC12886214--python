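# introskim

Detection and characterisation of wild-relative introgressions in hexaploid
wheat from skim-sequencing window coverage.

## The problem

Breeding programmes transfer chromosome segments ("introgressions") from
wild relatives such as *Aegilops mutica* (genome TT) into bread wheat
(*Triticum aestivum*, AABBDD) by homoeologous recombination. Verifying what
each derived line actually carries — which alien segment, recombined into
which wheat chromosome, homozygous or heterozygous, plus any collateral
losses, duplications or wheat–wheat rearrangements — is done cheaply with
very low coverage ("skim") whole-genome sequencing: reads from each line
and its two wheat parents are aligned to a concatenated wheat+alien
reference, counted in 1 Mb windows, and interpreted as window-level copy
number. `introskim` implements that interpretation end to end, for anyone
running a wild-relative introgression programme off windowed read counts.

## The statistic and the calling model

For wheat windows, with `M_x` the genome-wide median of wheat-window counts
of sample *x*, the coverage deviation of line vs. chosen parent is

```
dev(i) = (c_line(i) / M_line) / (c_parent(i) / M_parent)
```

so unaffected windows sit near 1, heterozygous losses near 0.5, homozygous
losses near 0, and duplicated segments near 2. The parent with the most
similar per-window baseline is chosen per line; windows where the parent
itself has almost no coverage are masked. Alien (T-genome) windows are
normalized by a dynamic within-line baseline — the mean of the top decile
of the line's non-zero alien bins — putting introgressed windows near 1
and residual cross-mapping near 0.

Calls are run-based at window resolution: sustained wheat drops
(≥ 6 consecutive windows) and alien gains (deviation > 0.2 over ≥ 5
windows), with a single interrupting window bridged. A wheat drop counts
as an introgression only when a homoeologous alien gain backs it
(substitution); gains spanning ≥ 95% of their chromosome are additions;
gains with no homoeologous loss but a wheat duplication elsewhere are
non-homoeologous translocations; losses paired with a homoeologous wheat
duplication are wheat–wheat translocations. Downstream modules handle
pedigree-aware unique-introgression accounting (segments from distinct BC₁
plants are independent events), genome-transfer fractions, recombination
hotspot clustering, and KASP-marker / GISH detectability modelling.

A seeded synthetic-panel generator reproduces the data regime (Poisson
window counts at 0.05×-equivalent depth, shared mappability, parent-specific
jitter, concentrated alien cross-mapping background) with planted truth,
so the whole pipeline is testable for parameter recovery.

## Worked example

Simulate a panel (two parents + 20 lines, 30 planted events) and analyse it:

```
$ introskim simulate --seed 7 --outdir demo
wrote 2 parents, 20 lines, 30 planted events under demo
$ introskim all --indir demo --outdir demo/out
wrote 9 artefact kinds under demo/out
```

`demo/out/unique_introgressions.tsv` starts:

```
uid  code   alien_chrom  start     end        target  bc1   accession  n_lines  lines
1    1T.D1  1T           71000000  100000000  1D      BC02  2130008    1        Sim03
2    1T.D2  1T           72000000  100000000  1D      BC10  2130012    1        Sim07
3    1T.D3  1T           13000000  28000000   1D      BC09  2130008    1        Sim09
```

Each row is one unique introgression: code `1T.D1` means the largest 1T
segment recombined into the D genome; lines descending from the same BC₁
plant with overlapping segments collapse into one row. For this seed,
`transfer.json` reports 54.0% of the miniature alien genome transferred
(8 uncovered gaps), `panel_report.json` reports 5 recombination hotspots,
10 further recombination sites, a mean adjacent marker gap of 25.5 Mb and
1 substitution invisible to the marker panel, and `run_log.json` records
per-line analysis-critical hidden state, e.g. Sim01: chosen parent
`ParentA`, alien baseline 230.5 counts/window.

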