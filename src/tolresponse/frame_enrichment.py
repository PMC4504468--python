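"""Pairwise time-frame response calls and COG overrepresentation.

Fold changes are computed for every ordered pair of sampling times
(t_i < t_j) — the 15 "time frames" of a six-point course — and a gene is
called *up* in a frame when ``log2(level at t_j / level at t_i)`` meets the
DE magnitude threshold, *down* when it meets the negated threshold, *none*
otherwise.  For each (strain, frame, direction) selection, every COG
category is tested for overrepresentation with the one-sided upper-tail
hypergeometric test against the annotated analysis-set background.

Per the figure convention this report excludes the uninformative categories
S (function unknown) and R (general function prediction only) plus genes
without any COG; the raw p < alpha criterion drives the significance flag
(a Benjamini-Hochberg column is emitted for reference only).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import TIMEPOINTS, ExpressionMatrix, GeneAnnotation, Thresholds

__all__ = [
    "FRAMES",
    "classify_frames",
    "hypergeom_upper_tail",
    "enrich",
    "DEFAULT_EXCLUDE",
]

#: All ordered timepoint pairs (t_i < t_j); 15 frames for six timepoints.
FRAMES: tuple[tuple[int, int], ...] = tuple(combinations(TIMEPOINTS, 2))

#: Categories excluded from the enrichment report by default.
DEFAULT_EXCLUDE: frozenset[str] = frozenset({"S", "R"})


def classify_frames(
    m: ExpressionMatrix, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Tidy table of per-gene frame responses for every strain.

    One row per (gene, strain, frame) with ``log2_fc`` oriented t_j over t_i
    and ``direction`` in {up, down, none}.  Frame (0, t) calls agree with
    the per-timepoint DE calls up to the sign flip of the t0/t orientation.
    """
    rows = []
    for strain in m.strains():
        prof = m.profile(strain, TIMEPOINTS)
        logp = np.log2(prof.to_numpy())
        idx = {t: i for i, t in enumerate(TIMEPOINTS)}
        for ti, tj in FRAMES:
            fc = logp[:, idx[tj]] - logp[:, idx[ti]]
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": prof.index,
                        "strain": strain,
                        "t_start": ti,
                        "t_end": tj,
                        "log2_fc": fc,
                    }
                )
            )
    frames = pd.concat(rows, ignore_index=True)
    thr = thresholds.de_abs_log2
    frames["direction"] = np.select(
        [frames["log2_fc"] >= thr, frames["log2_fc"] <= -thr],
        ["up", "down"],
        default="none",
    )
    return frames


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed by log-space summation of the exact point masses (log binomial
    coefficients via gammaln, combined with logsumexp) so that small tail
    probabilities keep full relative precision.
    """
    if not (0 <= n <= N and 0 <= K <= N and 0 <= k <= n and k <= K):
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    j = np.arange(k, min(n, K) + 1)
    j = j[n - j <= N - K]
    if j.size == 0:
        return 0.0

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = log_comb(K, j) + log_comb(N - K, n - j) - log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(terms))))


def _annotation_map(
    ann: Sequence[GeneAnnotation], exclude: Iterable[str]
) -> dict[str, frozenset[str]]:
    exclude = set(exclude)
    return {
        a.gene_id: frozenset(a.cogs - exclude)
        for a in ann
        if a.cogs - exclude
    }


def enrich(
    frames: pd.DataFrame,
    ann: Sequence[GeneAnnotation],
    thresholds: Thresholds = Thresholds(),
    exclude: Iterable[str] = DEFAULT_EXCLUDE,
) -> pd.DataFrame:
    """COG overrepresentation per (strain, frame, direction) selection.

    Background N = analysis genes carrying at least one COG after the
    exclusions; each selection is intersected with that background and a
    multi-COG gene counts once in every category it belongs to.  Returns one
    row per (strain, t_start, t_end, direction, cog) with k, n, K, N, the
    upper-tail p-value, -log10(p), the raw-alpha ``significant`` flag and a
    reference Benjamini-Hochberg q-value (per selection family).
    """
    gene_cogs = _annotation_map(ann, exclude)
    background = set(gene_cogs) & set(frames["gene_id"])
    if not background:
        raise ValueError("empty annotated background; nothing to test")
    N = len(background)
    cats = sorted({c for g in background for c in gene_cogs[g]})
    K = {c: sum(1 for g in background if c in gene_cogs[g]) for c in cats}

    out_rows = []
    sel_frames = frames[frames["direction"].isin(("up", "down"))]
    grouped = sel_frames.groupby(["strain", "t_start", "t_end", "direction"])
    for (strain, ti, tj, direction), grp in grouped:
        selected = set(grp["gene_id"]) & background
        n = len(selected)
        for c in cats:
            k = sum(1 for g in selected if c in gene_cogs[g])
            p = hypergeom_upper_tail(k, n, K[c], N) if n else 1.0
            out_rows.append(
                {
                    "strain": strain,
                    "t_start": ti,
                    "t_end": tj,
                    "direction": direction,
                    "cog": c,
                    "k": k,
                    "n": n,
                    "K": K[c],
                    "N": N,
                    "p_value": p,
                    "neg_log10_p": -np.log10(p),
                    "significant": p < thresholds.enrich_alpha,
                }
            )
    columns = [
        "strain", "t_start", "t_end", "direction", "cog",
        "k", "n", "K", "N", "p_value", "neg_log10_p", "significant",
    ]
    result = pd.DataFrame(out_rows, columns=columns)
    if result.empty:
        result["bh_q"] = pd.Series(dtype=float)
        return result
    result["bh_q"] = np.nan
    for _, idx in result.groupby(["strain", "t_start", "t_end", "direction"]).groups.items():
        result.loc[idx, "bh_q"] = multipletests(
            result.loc[idx, "p_value"], method="fdr_bh"
        )[1]
    return result


def enrichment_grid(enr: pd.DataFrame, strain: str) -> pd.DataFrame:
    """COG x (frame, direction) matrix of -log10(p) for one strain."""
    sub = enr[enr["strain"] == strain].copy()
    sub["frame"] = sub.apply(
        lambda r: f"{int(r.t_start)}-{int(r.t_end)}_{r.direction}", axis=1
    )
    return sub.pivot_table(index="cog", columns="frame", values="neg_log10_p")
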