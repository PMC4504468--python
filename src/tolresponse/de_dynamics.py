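"""Per-timepoint differential-expression calls and their time courses.

For each strain and each post-exposure time t, a gene is differentially
expressed (DE) when ``|log2(level at t=0 / level at t)| >= de_abs_log2``.
The ratio orientation is t0 over t exactly as stated with the threshold:
a gene UP-regulated after solvent addition therefore has a NEGATIVE
``log2_ratio_t0_over_t``.  A conventional fold-change column
(``log2_fc_t_over_t0``, the negation) is emitted alongside for readability.

The summary counts the DE genes per timepoint in each strain and the genes
DE in *both* strains at that same timepoint (the intersection is taken
per-timepoint, not cumulatively).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TIMEPOINTS, ExpressionMatrix, Thresholds

__all__ = ["RESPONSE_TIMES", "log2_ratio_profile", "call_de", "count_series"]

#: Post-exposure sampling times compared against the t=0 reference.
RESPONSE_TIMES: tuple[int, ...] = tuple(t for t in TIMEPOINTS if t > 0)


def log2_ratio_profile(m: ExpressionMatrix, strain: str) -> pd.DataFrame:
    """Gene x time table of log2(t0 / t) for the post-exposure times.

    Replicates are collapsed by geometric mean before the ratio; the matrix
    must be floored so every intensity is positive.
    """
    prof = m.profile(strain, TIMEPOINTS)
    ref = prof[0]
    out = pd.DataFrame(
        {t: np.log2(ref / prof[t]) for t in RESPONSE_TIMES}, index=prof.index
    )
    out.columns.name = "time_min"
    return out


def call_de(
    profiles: dict[str, pd.DataFrame], thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Tidy DE-call table from per-strain log2(t0/t) profiles.

    One row per (gene, strain, time) with the ratio in both orientations
    and the inclusive-threshold call ``is_de``.
    """
    rows = []
    for strain, prof in profiles.items():
        if not np.isfinite(prof.to_numpy()).all():
            raise ValueError(f"non-finite log2 ratio in strain {strain!r}")
        long = prof.stack().rename("log2_ratio_t0_over_t").reset_index()
        long.columns = ["gene_id", "time_min", "log2_ratio_t0_over_t"]
        long.insert(1, "strain", strain)
        rows.append(long)
    calls = pd.concat(rows, ignore_index=True)
    calls["log2_fc_t_over_t0"] = -calls["log2_ratio_t0_over_t"]
    calls["is_de"] = calls["log2_ratio_t0_over_t"].abs() >= thresholds.de_abs_log2
    return calls


def count_series(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint DE counts for WT, KO and the per-timepoint intersection.

    Returns a table indexed by time with columns ``n_de_wt``, ``n_de_ko``,
    ``n_de_both``; ``n_de_both <= min(n_de_wt, n_de_ko)`` always holds.
    """
    strains = set(calls["strain"])
    if strains != {"WT", "KO"}:
        raise ValueError(f"calls must cover both strains, found {sorted(strains)}")
    de = calls[calls["is_de"]]
    wt = de[de["strain"] == "WT"].groupby("time_min")["gene_id"].agg(set)
    ko = de[de["strain"] == "KO"].groupby("time_min")["gene_id"].agg(set)
    times = sorted(set(calls["time_min"]))
    rows = []
    for t in times:
        w = wt.get(t, set())
        k = ko.get(t, set())
        rows.append(
            {
                "time_min": t,
                "n_de_wt": len(w),
                "n_de_ko": len(k),
                "n_de_both": len(w & k),
            }
        )
    return pd.DataFrame(rows).set_index("time_min")


def plot_count_series(counts: pd.DataFrame, ax=None):
    """Line plot of the three DE-count curves over time (WT dashed, KO solid,
    both dotted)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = counts.index.to_numpy()
    ax.plot(t, counts["n_de_wt"], "k--", label="WT")
    ax.plot(t, counts["n_de_ko"], "k-", label="KO")
    ax.plot(t, counts["n_de_both"], "k:", label="both")
    ax.set_xlabel("time after toluene addition (min)")
    ax.set_ylabel("differentially expressed genes")
    ax.legend(frameon=False)
    return ax
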