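# tolresponse

Analysis pipeline for a two-strain, six-timepoint transcriptome study of
sudden solvent (toluene) stress in *Pseudomonas putida* S12: a wild-type
strain and a regulator-deletion mutant (ΔtrgI, "KO") are sampled
immediately before (t = 0) and 1, 2, 5, 10 and 30 minutes after toluene
addition. The package answers two questions from the resulting gene ×
sample intensity matrix:

1. **How does the global response unfold over time in each strain?**
   Per-timepoint differential-expression calls, fold changes over all 15
   pairwise time frames, and hypergeometric overrepresentation of COG
   functional categories within each frame's up- and down-regulated gene
   sets.
2. **What did the deletion change, gene by gene?** Every gene is placed in
   one of four groups: (1) no effect, (2) intrinsic (pre-exposure) level
   altered, (3) toluene responsiveness gained, (4) responsiveness lost.

## Method

Intensities are floored at 0.01, each chip is divided by its 50th
percentile, each gene by its median, and *absolute non-changing loci* —
genes whose normalized ratios stay inside the closed band [0.667, 1.334]
in every sample — are removed along with control probes.

On the surviving analysis set, with expression level *x<sub>g</sub>(t)*:

- **DE call:** gene *g* is differentially expressed at time *t* when
  |log2(*x<sub>g</sub>*(0) / *x<sub>g</sub>*(*t*))| ≥ 0.5.
- **Frame response:** for a frame (*t<sub>i</sub>*, *t<sub>j</sub>*),
  log2 FC = log2(*x<sub>g</sub>*(*t<sub>j</sub>*) / *x<sub>g</sub>*(*t<sub>i</sub>*));
  up if ≥ 0.5, down if ≤ −0.5.
- **Overrepresentation:** for a selection of *n* genes of which *k* carry
  category *c* (background *N* genes, *K* with *c*), the upper-tail
  hypergeometric p-value P(X ≥ k); significant at raw p < 0.01.
- **Four-group classification:** intrinsic shift = log2(KO(0) / WT(0)),
  "altered" when |shift| > 0.5; pattern similarity = Pearson correlation of
  the six-point profiles, "similar" when r ≥ 0.8; responsiveness as the DE
  criterion over any post-exposure time. Similar ∧ unaltered → group 1;
  similar ∧ altered → group 2; dissimilar ∧ KO-responsive only → group 3;
  dissimilar ∧ WT-responsive → group 4.

Because the study's microarray data are not bundled, a synthetic-data
generator plants known archetypes (immediate, peak-at-5-min, delayed,
sustained; both directions), intrinsic shifts and COG labels drawn from the
published category sizes, so every stage can be tested against ground
truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
dataset at the published scale (6164 genes, group sizes 1287/472/1762/2643,
noise 0.1 log2):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_de_dynamics.py
python analysis/04_frame_enrichment.py
python analysis/05_strain_classification.py
```

The final step prints (seed 1):

```
                         label  n_genes  pct  n_intrinsic_altered
group
1                    no effect     1343   22                    0
2      intrinsic level altered      519    8                  519
3        responsiveness gained     1712   28                  458
4          responsiveness lost     2590   42                 1563

planted-group recovery: 98.15% of 6164 genes
```

i.e. the pipeline reassigns 98% of genes to their planted group under
realistic noise; the recovered group sizes and integer percentages track
the planted ones (1287 → 1343, 472 → 519, 1762 → 1712, 2643 → 2590). With
`--noise 0` recovery is exact. The same stages are available as a CLI
(`tolresponse simulate|preprocess|de-dynamics|enrich|classify|run`) and as
plain library calls.

## Layout

- `src/tolresponse/` — the library: `io` (types, TSV dialect, thresholds),
  `simulate` (generator), `preprocess`, `de_dynamics`, `frame_enrichment`,
  `strain_compare`, `evaluate` (recovery/power harnesses), `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — modelling assumptions, parameter choices, limitations.
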