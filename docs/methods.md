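# Methods

## Data model and normalization

The pipeline operates on a dense gene × sample matrix of non-negative
hybridisation intensities with a sample sheet (strain ∈ {WT, KO}, time ∈
{0, 1, 2, 5, 10, 30} min, replicate ≥ 1). Samples are ordered canonically
by (strain, time, replicate); each strain must contain a t = 0 reference.
Replicates at a timepoint are collapsed by geometric mean before any ratio
is formed — the natural average on a ratio scale; with single replicates it
is the identity. The data model permits replicates even though the study
design appears to be single-replicate; the collapse rule is this package's
choice, not a claim about the original procedure.

Normalization runs in one fixed, documented order:
floor (0.01) → per-chip 50th percentile → per-gene median → non-changing
filter. The floor precedes division so that near-zero signals cannot
produce unbounded ratios. The median of an even-length vector is the mean
of the two middle order statistics; both normalizations depend on that
convention and it is asserted in the tests. The non-changing band
[0.667, 1.334] is read as a **closed** interval applied to **all** samples
of a gene on the normalized-ratio scale: a gene outside the band in any
single sample has changed somewhere and is kept. The band is symmetric
around 1 only on the ratio scale, which is why the filter runs after
per-gene normalization. Control-probe removal takes an explicit id list
(empty by default) because the platform's control list is not part of the
input contract; stale ids produce no error.

## Differential expression and time frames

The DE statistic is log2(level at t = 0 / level at t) with an inclusive
threshold of 0.5. The orientation is kept exactly as stated — an induced
gene has a *negative* value — and a negated fold-change column is emitted
alongside to prevent sign confusion. Counts are reported per strain and
per timepoint together with the per-timepoint two-strain intersection (not
a cumulative intersection).

Frame responses cover all 15 ordered timepoint pairs; the direction
threshold reuses the 0.5 log2 magnitude since no separate frame threshold
is defined. Strains are analysed separately throughout.

## Overrepresentation

The test is the one-sided upper-tail hypergeometric probability P(X ≥ k),
computed by log-space summation of exact point masses (gammaln +
logsumexp) so that tail values near 1e-300 retain full relative precision;
tests verify agreement with integer-exact enumeration to < 1e-9 relative
error for all populations N ≤ 25 and with `scipy.stats.hypergeom.sf` on
larger arguments. Depletion is out of scope. Significance is raw
p < 0.01 — deliberately uncorrected, matching the published criterion — and
a Benjamini–Hochberg q-value per selection family is emitted for reference
without driving any flag. The background is the annotated analysis set
(not the genome): genes with at least one COG after exclusions. The
frame-enrichment report excludes categories S and R and unannotated genes,
per the figure convention it mirrors; the per-group summary excludes
nothing except unannotated genes, since the published group table itself
reports S among overrepresented categories. A multi-COG gene counts once
in every category it belongs to. −log10 is used where a "−log(p)" is
reported; the base is this package's choice.

## Four-group classification

Pearson correlation of the six-point normalized profiles measures pattern
similarity (r ≥ 0.8 = similar); Spearman and log-ratio-profile variants
were considered and rejected as defaults because the published criterion
names only "correlation (of the expression pattern)" on expression levels.
The intrinsic criterion |log2(KO t0 / WT t0)| > 0.5 is read as a log2
ratio — a raw intensity ratio cannot be negative, and the log2 reading is
consistent with the DE statistic. The decision tree is: similar ∧
unaltered → 1; similar ∧ altered → 2; dissimilar ∧ KO-responsive ∧ ¬WT-
responsive → 3; dissimilar ∧ WT-responsive → 4. Two cells need
conventions the published criteria do not cover, both isolated in single
functions:

- *Constant profiles.* Correlation is undefined for a flat profile. A
  profile whose log2 range is ≤ 0.2 is treated as effectively constant —
  far below the 0.5 responsiveness threshold, far above the jitter the
  chip-median normalization introduces (±0.03 log2 at 6164 genes). A pair
  is "similar" when both are constant and the intrinsic level is
  unchanged; otherwise an undefined correlation counts as dissimilar.
  Without this tolerance the correlation of a near-flat profile is the
  sign of numerical noise.
- *Residual cell.* Dissimilar but neither strain responsive: assigned by
  the larger maximum |log2(t0/t)| excursion (KO larger → group 3, else 4).

Percentages in the group summary are integer, rounded half up — the
convention that reproduces the published counts-to-percentage arithmetic
(1287/6164 → 21, 472 → 8, 1762 → 29, 2643 → 43). Per-group COG
overrepresentation uses the same hypergeometric machinery, letters ordered
by increasing p-value.

## Synthetic data

The generator emulates the study's structure: 6164 genes × (2 strains × 6
timepoints × replicates). Defaults are the study conditions: group
fractions equal to the published classification sizes
(1287, 472, 1762, 2643)/6164; intrinsic-shift sub-fractions 473/1762
(group 3) and 1594/2643 (group 4); COG labels assigned as the exact
multiset of published category sizes (including S = 2292, R = 596 and 43
unannotated genes, which together sum exactly to 6164), scaled by largest
remainder at other sizes. Group allocation is deterministic (round the
first three groups, remainder to the last) so planted counts are exact.

Expression is baseline × archetype × noise on the log2 scale:
log2 x = b + s·a·curve(t) + δ·[KO] + ε, with baseline b ~ N(0, 1),
amplitude a ~ U(1, 2) log2, sign s = ±1 with equal probability, intrinsic
shift δ (magnitude U(0.8, 2), signed) and ε ~ N(0, σ), σ = 0.1 log2 by
default — i.i.d. Gaussian log-scale noise, the standard multiplicative
error approximation for array intensities. Archetype curves are
piecewise-linear in log2 space anchored at the six timepoints (immediate
peak at 1 min; rise to 5 min with undershoot; delayed onset after 5 min;
sustained plateau). The equal up/down sign mixture reflects that solvent
shock both induces and represses large gene sets, and it keeps each
simulated chip's median near the stable baseline — the assumption that
makes per-chip median normalization a near no-op, exactly as it must be
for data the method is suited to. Amplitude floors (≥ 1 log2, twice the
call threshold) are enforced at spec level so "responsive" genes are
responsive by construction. Group 4's KO profile is flat by default;
an anti-phase variant is available.

What the generator does *not* emulate: probe-level effects, chip spatial
artifacts, intensity-dependent variance, correlated noise between
timepoints, and any realistic effect-size distribution (none is published
for this response). Passing recovery tests therefore demonstrates the
pipeline's correctness on data satisfying its model assumptions, not
performance on raw array data.

## Verification harnesses and problem sizes

Recovery runs the full chain (generate → floor → chip → gene → filter →
classify) and compares with the planted truth: exact (100%) at zero noise
and ≥ 95% (measured ≈ 98%) at σ = 0.1 with the default amplitudes, at the
full 6164-gene scale. The residual errors are group-3/4 genes whose flat
strain, under noise, produces a six-point profile that correlates ≥ 0.8
with the responsive strain by chance (≈ 2–3% of six-point noise vectors).
Enrichment-detection power plants one category at 4× odds in group 3
(archetype fixed to immediate-up, positive sign, so the planted genes all
enter the KO 0→1 min up-selection) and counts detections at p < 0.01 over
50 simulations of 2000 genes — sized so the planted group exceeds 200
genes while 50 replicates complete in seconds. Loop oracles recompute DE
counts, frame directions and full enrichment tables gene by gene on
200-gene random fixtures.

## Numerical and formatting choices

All tables are UTF-8 TSV with one header row and `%.10g` floats, making
pipeline runs byte-reproducible for a fixed config and seed. Hard errors
name the offending gene/sample and stage. The hypergeometric tail clamps
at 1.0 to absorb rounding above the certain event; p > 0 is guaranteed
(k = 0 short-circuits to 1), so −log10(p) is always finite.

## Known limitations

The published figure-level results (DE-curve peak timing, specific
enriched category letters, the absolute group counts) depend on the
original accession's intensities and its upstream probe-level processing,
which are outside this package's input contract; the pipeline reproduces
the *procedure* and verifies it on planted ground truth. The classification
is threshold-based with no variance model, inheriting the published
criteria's sensitivity to noise near the 0.5/0.8 boundaries.
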