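"""Domain types and tab-separated readers/writers shared by every stage.

The pipeline's single input object is an :class:`ExpressionMatrix`: a dense
gene x sample table of non-negative normalized hybridisation intensities,
plus a sample sheet mapping each column to a strain (wild type ``WT`` or the
deletion mutant ``KO``), a sampling time in minutes after solvent addition,
and a replicate number.  All files are UTF-8 tab-separated text with one
header row and ``.`` as the decimal separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRAINS",
    "TIMEPOINTS",
    "COG_LETTERS",
    "SampleMeta",
    "ExpressionMatrix",
    "GeneAnnotation",
    "Thresholds",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
]

#: Strain labels: wild type and the regulator-deletion strain.
STRAINS: tuple[str, str] = ("WT", "KO")

#: Sampling times in minutes; 0 is the pre-exposure reference.
TIMEPOINTS: tuple[int, ...] = (0, 1, 2, 5, 10, 30)

#: Valid single-letter COG functional categories.
COG_LETTERS: frozenset[str] = frozenset("ACDEFGHIJKLMNOPQRSTUVW")


@dataclass(frozen=True)
class SampleMeta:
    """One microarray sample: which strain, when, and which replicate."""

    sample_id: str
    strain: str
    time_min: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(
                f"sample {self.sample_id!r}: strain must be one of {STRAINS}, got {self.strain!r}"
            )
        if self.time_min not in TIMEPOINTS:
            raise ValueError(
                f"sample {self.sample_id!r}: time_min must be one of {TIMEPOINTS}, got {self.time_min!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-to-COG assignment; ``cogs`` may be empty (unannotated gene)."""

    gene_id: str
    cogs: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.cogs) - COG_LETTERS
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown COG letter(s) {''.join(sorted(bad))!r}"
            )


@dataclass(frozen=True)
class Thresholds:
    """Every cut-off the analysis uses, resolved once at startup.

    Attributes
    ----------
    signal_floor
        Intensities below this are clamped to it before any ratio is taken.
    nonchanging_low, nonchanging_high
        A gene whose per-gene-normalized values all stay inside this closed
        fold-change band is an absolute non-changing locus and is removed.
    de_abs_log2
        A (gene, time) is differentially expressed when
        ``|log2(level at t=0 / level at t)| >= de_abs_log2``.  The same
        magnitude classifies time-frame fold changes as up/down.
    corr_min
        Two strains show the "same" response pattern for a gene when the
        Pearson correlation of their six-point profiles is >= this value.
    intrinsic_abs_log2
        The pre-exposure (t=0) level differs between strains when
        ``|log2(KO/WT)|`` exceeds this value.
    enrich_alpha
        Raw hypergeometric p-value below which a COG category counts as
        overrepresented.
    """

    signal_floor: float = 0.01
    nonchanging_low: float = 0.667
    nonchanging_high: float = 1.334
    de_abs_log2: float = 0.5
    corr_min: float = 0.8
    intrinsic_abs_log2: float = 0.5
    enrich_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be > 0")
        if not (0 < self.nonchanging_low < 1 < self.nonchanging_high):
            raise ValueError("need 0 < nonchanging_low < 1 < nonchanging_high")
        if self.de_abs_log2 <= 0:
            raise ValueError("de_abs_log2 must be > 0")
        if not (0 < self.corr_min <= 1):
            raise ValueError("corr_min must be in (0, 1]")
        if self.intrinsic_abs_log2 <= 0:
            raise ValueError("intrinsic_abs_log2 must be > 0")
        if not (0 < self.enrich_alpha < 1):
            raise ValueError("enrich_alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, overrides: dict | None) -> "Thresholds":
        overrides = overrides or {}
        known = {f.name for f in fields(cls)}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown threshold name(s): {sorted(bad)}")
        return cls(**overrides)


class ExpressionMatrix:
    """Dense gene x sample intensity matrix plus its sample sheet.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``samples`` is a DataFrame indexed by sample id with columns
    ``strain``, ``time_min``, ``replicate``.  Construction validates the
    invariants (unique ids, non-negative finite values, matching sample
    sets, a t=0 reference per strain) and normalizes the sample order to
    (strain, time, replicate) with WT first.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        values = values.copy()
        samples = samples.copy()
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if samples.index.has_duplicates:
            dup = samples.index[samples.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing_meta = set(values.columns) - set(samples.index)
        if missing_meta:
            raise ValueError(
                f"sample(s) in matrix absent from metadata: {sorted(missing_meta)}"
            )
        missing_cols = set(samples.index) - set(values.columns)
        if missing_cols:
            raise ValueError(
                f"sample(s) in metadata absent from matrix: {sorted(missing_cols)}"
            )
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            coerced = values.apply(pd.to_numeric, errors="coerce")
            bad = coerced.isna() & values.notna()
            if bad.to_numpy().any():
                g, s = np.argwhere(bad.to_numpy())[0]
                raise ValueError(
                    f"non-numeric value at gene {values.index[g]!r}, sample {values.columns[s]!r}"
                )
            values = coerced
            arr = values.to_numpy()
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {values.index[g]!r}, sample {values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at gene {values.index[g]!r}, sample {values.columns[s]!r}"
            )
        for sid, row in samples.iterrows():
            SampleMeta(str(sid), str(row["strain"]), float(row["time_min"]), int(row["replicate"]))
        # one t=0 condition per strain present in the matrix
        for strain in sorted({str(s) for s in samples["strain"]}):
            sub = samples[samples["strain"] == strain]
            if not (sub["time_min"] == 0).any():
                raise ValueError(f"strain {strain!r} has no t=0 reference sample")
        order = samples.assign(_strain_rank=[STRAINS.index(s) for s in samples["strain"]]).sort_values(
            ["_strain_rank", "time_min", "replicate"]
        ).index
        self.samples = samples.loc[order, ["strain", "time_min", "replicate"]]
        self.values = values.astype(float).loc[:, order]

    # -- basic container protocol -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.samples.equals(other.samples)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """New matrix with the same sample sheet and replaced values."""
        return ExpressionMatrix(values, self.samples)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)

    def strains(self) -> list[str]:
        return [s for s in STRAINS if s in set(self.samples["strain"])]

    def timepoints(self, strain: str) -> list[float]:
        sub = self.samples[self.samples["strain"] == strain]
        return sorted(set(float(t) for t in sub["time_min"]))

    def profile(self, strain: str, times: Iterable[float] = TIMEPOINTS) -> pd.DataFrame:
        """Gene x time table for one strain, replicates collapsed by geometric mean.

        Geometric-mean collapse is the natural average for ratio-scale
        intensities; with a single replicate it is the identity.  Requires
        strictly positive values (call after signal flooring).
        """
        times = list(times)
        sub = self.samples[self.samples["strain"] == strain]
        if sub.empty:
            raise ValueError(f"strain {strain!r} not present in matrix")
        missing = [t for t in times if not (sub["time_min"] == t).any()]
        if missing:
            raise ValueError(f"strain {strain!r} is missing timepoint(s) {missing}")
        cols = {}
        for t in times:
            sids = sub.index[sub["time_min"] == t]
            block = self.values[sids].to_numpy()
            if (block <= 0).any():
                raise ValueError(
                    f"non-positive intensity in strain {strain!r} at t={t}; floor signals first"
                )
            cols[t] = np.exp2(np.log2(block).mean(axis=1))
        return pd.DataFrame(cols, index=self.values.index)


# -- file dialect ------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, meta_path: str | Path) -> None:
    """Write the matrix and its sample sheet as two tab-separated files."""
    v = m.values.copy()
    v.index.name = "gene_id"
    v.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    s = m.samples.copy()
    s.index.name = "sample_id"
    s.to_csv(meta_path, sep="\t")


def read_expression_matrix(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Load a matrix (first column gene id) and its sample sheet; validate both."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value at gene {raw.index[g]!r}, sample {raw.columns[s]!r} in {path}"
        )
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    required = {"strain", "time_min", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"sample sheet {meta_path} must have columns {sorted(required)}")
    return ExpressionMatrix(values, meta)


def write_annotation(ann: Sequence[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {"gene_id": a.gene_id, "cogs": "".join(sorted(a.cogs)), "description": a.description}
        for a in ann
    ]
    pd.DataFrame(rows, columns=["gene_id", "cogs", "description"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene -> COG table: columns gene_id, cogs (e.g. ``CE``), description."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene_id", "cogs"} <= set(df.columns):
        raise ValueError(f"annotation file {path} must have columns gene_id, cogs")
    out: list[GeneAnnotation] = []
    for _, row in df.iterrows():
        out.append(
            GeneAnnotation(
                gene_id=row["gene_id"],
                cogs=frozenset(row["cogs"]),
                description=row.get("description", ""),
            )
        )
    return out
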