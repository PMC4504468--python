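#!/usr/bin/env python
"""Per-timepoint differential-expression dynamics versus t=0.

A gene is DE at time t when |log2(level at t=0 / level at t)| >= 0.5.
Writes the per-gene call table, the three count curves (WT, KO, both) and
a line plot to results/de_dynamics/.
"""

import argparse
from pathlib import Path

from tolresponse.de_dynamics import call_de, count_series, log2_ratio_profile, plot_count_series
from tolresponse.io import Thresholds, read_expression_matrix

ap = argparse.ArgumentParser()
ap.add_argument("--data-dir", type=Path, default=Path("results/preprocess"))
ap.add_argument("--out-dir", type=Path, default=Path("results/de_dynamics"))
args = ap.parse_args()

m = read_expression_matrix(args.data_dir / "normalized_matrix.tsv",
                           args.data_dir / "normalized_samples.tsv")
profiles = {s: log2_ratio_profile(m, s) for s in m.strains()}
calls = call_de(profiles, Thresholds())
counts = count_series(calls)
args.out_dir.mkdir(parents=True, exist_ok=True)
calls.to_csv(args.out_dir / "de_calls.tsv", sep="\t", index=False, float_format="%.10g")
counts.to_csv(args.out_dir / "de_counts.tsv", sep="\t")
ax = plot_count_series(counts)
ax.figure.savefig(args.out_dir / "de_counts.png", dpi=150, bbox_inches="tight")
print(counts.to_string())
print(f"peak DE: WT {counts['n_de_wt'].max()} genes, KO {counts['n_de_ko'].max()} genes; "
      f"the planted archetypes keep most responders DE from 2 min onward")
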