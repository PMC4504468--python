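"""Normalization chain and non-changing-locus filter.

The fixed, only supported order is::

    floor_signals -> normalize_per_chip -> normalize_per_gene -> filter_nonchanging

Intensities below a small floor are clamped, every chip (sample column) is
divided by its 50th percentile, every gene row is divided by its median
across all samples, and finally "absolute non-changing" loci — genes whose
normalized ratios never leave the closed band [low, high] in any sample —
are dropped together with an explicit control-gene list.  The surviving
genes form the analysis set used by every downstream stage.

Median of an even-length vector is the mean of the two middle order
statistics (numpy's default); both normalizations depend on that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, Thresholds

__all__ = [
    "PreprocessReport",
    "floor_signals",
    "normalize_per_chip",
    "normalize_per_gene",
    "filter_nonchanging",
    "run_preprocess",
]


@dataclass(frozen=True)
class PreprocessReport:
    """Gene bookkeeping across the filter stage; the three parts sum to the input."""

    n_input_genes: int
    n_control_removed: int
    n_nonchanging_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input_genes != (
            self.n_control_removed + self.n_nonchanging_removed + self.n_retained
        ):
            raise ValueError("report parts do not sum to n_input_genes")


def floor_signals(m: ExpressionMatrix, floor: float = 0.01) -> ExpressionMatrix:
    """Clamp every intensity strictly below ``floor`` up to ``floor``."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    return m.with_values(m.values.clip(lower=floor))


def normalize_per_chip(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its own median (50th percentile)."""
    med = m.values.median(axis=0)
    zero = med.index[med == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has median 0; cannot chip-normalize")
    return m.with_values(m.values.div(med, axis=1))


def normalize_per_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene row by its own median across all samples."""
    med = m.values.median(axis=1)
    zero = med.index[med == 0]
    if len(zero):
        raise ValueError(f"gene {zero[0]!r} has median 0; cannot gene-normalize")
    return m.with_values(m.values.div(med, axis=0))


def filter_nonchanging(
    m: ExpressionMatrix,
    low: float = 0.667,
    high: float = 1.334,
    control_ids: set[str] | frozenset[str] = frozenset(),
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Drop control genes, then genes whose ratios all stay inside [low, high].

    ``m`` must already be per-gene normalized so its values are fold changes
    relative to the gene median.  The band is closed: a gene sitting exactly
    on a boundary in every sample is still non-changing.  Control ids absent
    from the matrix are ignored (a stale list is not an error).
    """
    if not (low < 1 < high):
        raise ValueError("need low < 1 < high")
    present_controls = [g for g in m.values.index if g in control_ids]
    v = m.values.drop(index=present_controls)
    inside = ((v >= low) & (v <= high)).all(axis=1)
    retained = v.index[~inside]
    report = PreprocessReport(
        n_input_genes=m.n_genes,
        n_control_removed=len(present_controls),
        n_nonchanging_removed=int(inside.sum()),
        n_retained=len(retained),
    )
    return m.subset_genes(list(retained)), report


def run_preprocess(
    m: ExpressionMatrix,
    thresholds: Thresholds = Thresholds(),
    control_ids: set[str] | frozenset[str] = frozenset(),
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Full chain: floor -> per-chip -> per-gene -> non-changing filter."""
    m = floor_signals(m, thresholds.signal_floor)
    m = normalize_per_chip(m)
    m = normalize_per_gene(m)
    return filter_nonchanging(
        m, thresholds.nonchanging_low, thresholds.nonchanging_high, control_ids
    )
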