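# Methods

## Scope and upstream contract

`introskim` consumes per-window read counts, not reads. The documented
upstream contract is: adapter/quality trimming, alignment of 150 bp
paired-end skim reads (~0.05× per library) to a concatenated reference
(the three wheat subgenomes plus the wild-relative T genome), retention of
properly paired, uniquely mapped reads at mapping quality ≥ 10, duplicate
removal, and counting in 1 Mb non-overlapping windows. Everything from the
counts onward — normalization, calling, structural interpretation,
resource accounting, detectability modelling — is this package.

Coordinates are 0-based half-open everywhere, including the BED-like
files; windows tile each chromosome with `ceil(length / window_size)`
windows, the last one allowed to run short. Every chromosome must carry a
homoeologous group number (1–7); homoeology is shared group membership
(5A–5B–5D–5T). Unplaced scaffolds are not supported: the pairing logic is
group-driven. All samples of an analysis share one window grid; counts on
a different grid are an error, never an implicit re-bin.

## The deviation statistic

**Wheat windows.** With `M_x` the genome-wide median of wheat-window
counts of sample `x`,

    dev(i) = (c_line(i) / M_line) / (c_parent(i) / M_parent).

The median normalization makes the statistic invariant to sequencing
depth, and the parental ratio cancels per-window mappability shared
between line and parent. In the noiseless limit this puts copy-number
2/1/0 windows at exactly 1/0.5/0, which is what the zygosity bands read
off. Windows where the parent's median-normalized coverage falls below
`mask_floor` (default 0.25, exposed in config) are masked: a ratio against
a near-empty reference window is noise. The floor is a package choice made
to prevent ratio blow-ups in low-mappability windows.

**Parent choice.** Two parents are supplied; the one minimizing the median
over jointly unmasked wheat windows of `|c_line/M_line − c_p/M_p|` is used,
first parent on ties. The median absolute difference is deliberately
robust: a line's own segmental events should not sway the choice. Parent
choice is per line and global; per-chromosome choice was considered and
rejected as an extra degree of freedom with no support in the data regime.

**Alien windows.** No alien diploid reference at matched depth exists, so
the baseline is dynamic and internal: `B` = mean count of the top decile
(by count) of the line's non-zero alien bins, computed across the whole
alien subgenome ("top decile" = top 10% of non-zero bins; mean rather
than median purely for determinism — they are near-equivalent). Then
`dev(i) = c(i)/B`. In a line carrying alien chromatin, `B` is dominated by
the introgressed windows, putting them near 1 and cross-mapped background
near 0. If every alien bin is zero, deviation is identically 0 and `B` is
recorded as 0. Note the self-normalization implies a line with *no* alien
content has its few background bins near 1 — isolated single windows that
the run rules below can never call.

Deviation values are used unclipped by all calling; `display_value =
min(dev, 2)` exists only for plotting, matching the figure convention of
plotting out-of-bound values at 2.

## Segment calling

Calls are maximal window runs per chromosome:

| kind              | predicate             | min run | note                          |
|-------------------|------------------------|---------|-------------------------------|
| wheat_loss        | dev < 0.75             | 6       | zygosity read off run mean    |
| alien_gain        | dev > 0.2              | 5       | presence of alien chromatin   |
| wheat_duplication | dev > 1.5              | 5       | copy number 4 sits near 2     |

Up to `bridge_gap` (default 1) consecutive interrupting windows — masked
or out-of-band — neither extend nor break a run; 1 Mb bins at 0.05× are
noisy and the sustained-run semantics should tolerate a single bad bin.
Run coordinates snap to the first/last satisfying window; the method's
native resolution is the bin, and no sub-window refinement is attempted.
Mean deviation is taken over satisfying windows only.

The published run rule is stated for homozygous drops (< 0.1 over ≥ 6
windows). Heterozygous losses sit near 0.5 and would never satisfy it, so
loss runs are detected with the permissive predicate `dev <
het_band.high` (0.75) and zygosity is then classified from the run mean:
hom below 0.25, het in [0.25, 0.75] (the band boundary belongs to het;
a "loss" with mean above the band is an error). `loss_max = 0.1` is kept
as the homozygous-evidence level used in plot highlighting. The het band
is a package extension and is documented as such.

## Structural interpretation

A wheat drop alone is not introgression evidence; the cascade demands the
paired alien gain. Per alien gain, in order:

1. a wheat loss on a homoeologous chromosome exists → **homoeologous
   substitution** (largest homoeologous loss paired; the event inherits
   its zygosity);
2. the gain spans ≥ 95% of its chromosome → **whole-chromosome addition**
   (the span floor distinguishes additions from large terminal segments
   and is configurable);
3. a wheat duplication exists anywhere → **non-homoeologous
   translocation**, the largest duplication (ties: lowest chromosome
   index) designated as the receiving region;
4. otherwise **unresolved**.

Remaining losses paired with a homoeologous wheat duplication become
**wheat–wheat translocations**; fully unpaired losses are reported as
plain losses, never as introgressions. Each loss and each duplication
supports at most one event. Events whose alien-segment boundary falls
within one window of the recorded centromere are tagged
`centric_candidate` but never auto-classified as centric fusions: no
calling rule for centric fusion is defensible at window resolution.

Junctions are the internal run boundaries (boundaries coincident with a
chromosome end are not recombination junctions), reported on both the
alien and the wheat side, lower-coordinate edge as `proximal`, with one
window of positional uncertainty.

## Unique introgressions and resource statistics

Introgressions in lines descending from distinct BC₁ plants arose from
independent F₁ meioses and are distinct by construction, whatever their
coordinates. Within a BC₁ family, segments on one alien chromosome merge
by single linkage at reciprocal overlap ≥ 0.8 (union interval kept). The
0.8 was chosen so that a documented same-family nested trio trimmed by
later recombination (450 → 116 → 30 Mb) stays distinct while
measurement-level jitter merges; it is config-exposed. Codes follow
`<alienChrom>.<targetGenome><serial>` with serials assigned in descending
size order per alien-chromosome × target combination; serials are
regenerated, not reconciled with historical numbering, since prior lines'
codes are not among the inputs. Whole-chromosome additions and unresolved
gains are listed but excluded from uniqueness counts and size statistics.

Transfer fractions are interval-union coverage of the alien chromosomes in
scope (all / per accession / per chromosome), overlaps counted once, gaps
reported as maximal uncovered intervals, at window resolution.

## Hotspots

Junctions are clustered per alien chromosome by single linkage at a
tolerance of 10 Mb (10 windows) — the data identify "very similar"
positions only up to skim resolution, and the knob is config-exposed and
echoed in output. Clustering runs on the alien coordinate because the
alien chromosome is the invariant axis when one wild-relative site has
recombined into different wheat subgenomes; member wheat-side coordinates
are carried along. A cluster is a hotspot iff its members span ≥ 2
distinct BC₁ plants; everything else is a "further recombination site".
Under chaining the cluster span can in principle exceed twice the
tolerance; on junction sets as sparse as these panels produce it does not.

## Marker and GISH detectability

The KASP model is purely positional: a segment's replaced wheat interval
is detectable iff ≥ 1 marker position falls inside it. Zygosity
prediction: markers inside a homozygous substitution call `alien_hom`,
inside a heterozygous one `het`, and every marker whose group carries a
whole-chromosome addition calls `het` (all wheat homoeologs are still
present — the classic reason additions score heterozygous). GISH
resolves segments at or above a 15 Mb floor. Proposed markers are the
midpoints of undetectable segments plus minimal equal partitions of every
adjacent gap above the 50 Mb target density. Primer design and GISH
signal modelling beyond the size floor are out of scope.

## Synthetic panels

The generator emulates the consumed data regime directly at window level;
read-level simulation would add nothing the analysis can see. Defaults
define the study conditions:

* miniature genome: 28 chromosomes (7 groups × A/B/D/T), 100 × 1 Mb
  windows each; centromeres at midpoint;
* `lambda = depth × window / footprint` = 0.05 × 1e6 / 300 ≈ 166.7
  expected pairs per diploid window;
* mappability `m(i)`: lognormal, mean 1, σ = 0.2, drawn once and shared by
  all samples — the component the parental ratio cancels; 2% of windows
  fully unmappable, placed as isolated bins (fully dead 1 Mb bins are
  rare and dispersed away from pericentromeres at this resolution; two
  adjacent dead bins would be a different, pericentromeric regime);
* parents carry individual lognormal jitter (σ = 0.05) on top of `m`;
  each line inherits one parent's jitter, giving parent selection a
  ground truth;
* counts ~ Poisson(`lambda · m_eff · cn/2`) with `cn` from the planted
  events: substitutions (wheat 0 or 1, alien 2 or 1), additions (alien 2),
  duplications (wheat 4), non-homoeologous translocations (alien 2 +
  wheat 4 elsewhere), wheat–wheat translocations (wheat 0 + homoeologous
  wheat 4);
* alien cross-mapping: concentrated in 0.5% "hot" alien windows shared
  across the panel, average mass 0.00025·lambda per alien window, i.e.
  ~0.05·lambda (~8 reads) per hot window. MQ ≥ 10 filtering leaves real
  cross-species mapping rare and clumped in conserved regions; the
  concentration (few non-zero background bins, each far below single-copy
  signal) is what reproduces the observed near-zero alien profiles of
  lines without alien content, keeps background from mimicking or
  extending gains, and still exercises the non-zero-bin logic of the
  dynamic baseline.

The default panel plants 30 events over 20 lines covering every class
(12 hom + 6 het substitutions, 2 additions, 3 non-homoeologous
translocations, 3 duplications, 4 wheat–wheat translocations), with
wheat targets drawn A/B/D at 18/7/75% and segment placement mostly distal,
as real recombination is. Two structures mirror the crossing design: one
BC₁-sharing line pair carries an identical substitution (must collapse to
one unique introgression) and one pair from different BC₁ plants shares an
alien junction into different wheat subgenomes (a hotspot). Pedigrees draw
BC₁ ancestors from a pool of 14 and accessions at 45/10/45%, echoing the
unequal use of the three source accessions.

What the generator does **not** model: GC bias, alignment artefacts,
segmental duplication polymorphism between parents, inversion events, and
sub-window breakpoints. Passing recovery tests therefore demonstrates the
statistical machinery under the stated noise model, not robustness to
reference artefacts in real data.

## Evaluation

A planted event is recovered when a call of the corresponding class (and
matching zygosity, for substitutions) in the same line overlaps it
reciprocally ≥ 0.5 on the primary interval — alien side where one exists,
wheat side otherwise. Standalone planted duplications are matched against
duplication segments not consumed as translocation evidence. Boundary
error is the maximum endpoint distance in windows over recovered events.
On default panels the pipeline recovers all 30 events with window-level
boundaries, heterozygous/homozygous substitution deviation means separate
into (0.35, 0.65) vs [0, 0.15), and null panels yield zero events.

## Numerical and degenerate-input choices

Ties: parent selection takes the first parent; duplication partner choice
takes the largest, then lowest chromosome index; top-decile baseline ties
are irrelevant to the mean. Degenerate inputs: all-zero alien windows give
zero deviation and baseline 0; a parent with zero wheat median is an
error; an empty marker panel is an error for spacing stats but chromosomes
with a single marker simply contribute no gaps. Scale invariance of both
statistics (counts × k leaves profiles unchanged) and self-deviation ≡ 1
are exact, not approximate, and tested as such. Problem sizes throughout
the test suite and acceptance script (100-window chromosomes, 20-line
panels, 500-fixture oracle sweeps) were chosen as the smallest sizes at
which every phenomenon of interest — run bridging, decile baselines,
pedigree collapsing, hotspot independence — is exercised with comfortable
margins.

## Known limitations

The dynamic alien baseline makes within-line alien deviation
self-normalizing: it cannot distinguish "no alien content" from "uniform
alien content" without the wheat-side evidence, which is why the pairing
cascade leads with the wheat loss. Published deviation profiles describe
alien values "approaching 2" for some real introgressions; under this
baseline a homozygous segment sits near 1, and the mechanism producing
near-2 values in real data (repeat collapse, additions over a
noise-dominated baseline) is not modelled — flagged rather than guessed.
Inversions, phasing and split-read breakpoint refinement are out of scope.
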