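"""Recovery and power harnesses over the synthetic test bed.

These run the full documented chain — generate, floor, chip- and
gene-normalize, non-changing filter, classify — and compare the result with
the planted ground truth.  They are used by the test suite, the analysis
drivers and the acceptance script alike.
"""

from __future__ import annotations

import pandas as pd

from . import frame_enrichment, preprocess, simulate, strain_compare
from .io import Thresholds

__all__ = [
    "classify_with_truth",
    "group_recovery_rate",
    "planted_enrichment_pvalue",
    "enrichment_power",
]


def classify_with_truth(
    spec: simulate.SyntheticSpec, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Classification table joined with the planted truth for retained genes."""
    matrix, _, truth = simulate.generate(spec)
    norm, _ = preprocess.run_preprocess(matrix, thresholds)
    classes = strain_compare.classify(norm, thresholds)
    return classes.set_index("gene_id").join(truth.set_index("gene_id"), how="left")


def group_recovery_rate(
    spec: simulate.SyntheticSpec, thresholds: Thresholds = Thresholds()
) -> float:
    """Fraction of retained genes whose assigned group equals the planted group."""
    merged = classify_with_truth(spec, thresholds)
    return float((merged["group"] == merged["planted_group"]).mean())


def planted_enrichment_pvalue(
    spec: simulate.SyntheticSpec,
    cog: str,
    strain: str = "KO",
    frame: tuple[int, int] = (0, 1),
    direction: str = "up",
    thresholds: Thresholds = Thresholds(),
) -> float:
    """Overrepresentation p-value of one COG in one frame selection.

    Runs generate -> preprocess -> frame classification -> enrichment on the
    single requested frame and returns the upper-tail p-value for ``cog``.
    """
    matrix, ann, _ = simulate.generate(spec)
    norm, _ = preprocess.run_preprocess(matrix, thresholds)
    frames = frame_enrichment.classify_frames(norm, thresholds)
    one = frames[(frames["t_start"] == frame[0]) & (frames["t_end"] == frame[1])]
    enr = frame_enrichment.enrich(one, ann, thresholds)
    row = enr[
        (enr["strain"] == strain)
        & (enr["direction"] == direction)
        & (enr["cog"] == cog)
    ]
    if row.empty:
        return 1.0
    return float(row["p_value"].iloc[0])


def enrichment_power(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_genes: int = 2000,
    cog: str = "O",
    group: int = 3,
    odds: float = 4.0,
    alpha: float = 0.01,
    **spec_kwargs,
) -> float:
    """Detection power of a planted COG enrichment across simulation seeds.

    Each replicate plants ``cog`` at ``odds`` x base frequency among the
    genes of ``group`` (given the immediate-up archetype with positive sign,
    so they all enter the strain-specific (0,1)-minute up selection) and
    counts detection when the frame-enrichment p-value is below ``alpha``.
    """
    strain = "KO" if group == 3 else "WT"
    hits = 0
    for i in range(n_seeds):
        spec = simulate.SyntheticSpec(
            n_genes=n_genes,
            seed=base_seed + i,
            enrichment_plants=((cog, group, odds),),
            group_archetype={group: "immediate_up"},
            group_up_fraction={group: 1.0},
            **spec_kwargs,
        )
        p = planted_enrichment_pvalue(spec, cog, strain=strain, frame=(0, 1))
        if p < alpha:
            hits += 1
    return hits / n_seeds
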