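"""Shared fixtures: small hand-built matrices and random fixtures with
independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tolresponse.io import STRAINS, TIMEPOINTS, ExpressionMatrix


def standard_samples(n_replicates: int = 1) -> pd.DataFrame:
    rows = []
    for strain in STRAINS:
        for t in TIMEPOINTS:
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_t{t}_r{r}",
                        "strain": strain,
                        "time_min": t,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def make_matrix(values: np.ndarray, gene_ids=None, n_replicates: int = 1) -> ExpressionMatrix:
    """Matrix from a (genes x 12*reps) array laid out WT t0..t30 then KO t0..t30."""
    samples = standard_samples(n_replicates)
    if gene_ids is None:
        gene_ids = [f"g{i+1}" for i in range(values.shape[0])]
    vdf = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index)
    return ExpressionMatrix(vdf, samples)


def profile_matrix(wt: np.ndarray, ko: np.ndarray, gene_ids=None) -> ExpressionMatrix:
    """Matrix from per-strain (genes x 6) profile arrays of intensities."""
    return make_matrix(np.hstack([np.asarray(wt, float), np.asarray(ko, float)]), gene_ids)


@pytest.fixture
def random_matrix():
    """200-gene positive random matrix used by the loop-oracle tests."""
    rng = np.random.default_rng(42)
    values = np.exp2(rng.normal(0.0, 1.0, size=(200, 12)))
    return make_matrix(values)
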