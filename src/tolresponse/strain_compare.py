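"""Four-group classification of the deletion's effect on each gene.

Every analysis gene is placed in exactly one group by three measurements:

* *intrinsic shift* — log2 of the KO over WT level at t=0, immediately
  before solvent addition; "altered" when its magnitude exceeds the
  intrinsic threshold (default 0.5 log2);
* *responsiveness* per strain — whether any post-exposure time shows
  ``|log2(t0/t)| >=`` the DE threshold;
* *pattern similarity* — Pearson correlation of the two strains' six-point
  normalized profiles; "similar" when >= the correlation threshold
  (default 0.8).

Decision tree (groups as in the summary table):

1. similar pattern, intrinsic unchanged      -> group 1 (no effect)
2. similar pattern, intrinsic altered        -> group 2 (level shift only)
3. dissimilar, KO responsive, WT not         -> group 3 (responsiveness gained)
4. dissimilar, WT responsive                 -> group 4 (responsiveness lost)

The residual cell — dissimilar pattern with neither strain responsive — is
not covered by the published criteria; it is resolved by the larger maximum
log-ratio excursion (KO larger -> group 3, else group 4) and isolated in
:func:`_resolve_residual` so the convention is easy to audit or change.

A profile whose log2 range is below a small tolerance is treated as
constant: its correlation is undefined, and the pair counts as "similar"
only when both profiles are constant and the intrinsic level is unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frame_enrichment import hypergeom_upper_tail
from .io import TIMEPOINTS, ExpressionMatrix, GeneAnnotation, Thresholds

__all__ = [
    "pattern_correlation",
    "responsiveness",
    "classify",
    "summarize",
    "group_percentages",
    "FLAT_EPS_LOG2",
]

#: A six-point profile with log2 range <= this is "effectively constant";
#: well below the DE threshold, above normalization jitter.
FLAT_EPS_LOG2: float = 0.2

GROUP_LABELS = {
    1: "no effect",
    2: "intrinsic level altered",
    3: "responsiveness gained",
    4: "responsiveness lost",
}


def _is_flat(profile: np.ndarray, eps: float = FLAT_EPS_LOG2) -> bool:
    lp = np.log2(profile)
    return float(lp.max() - lp.min()) <= eps


def pattern_correlation(
    wt_profile: np.ndarray, ko_profile: np.ndarray, eps: float = FLAT_EPS_LOG2
) -> float:
    """Pearson correlation of two six-point profiles; NaN when either is
    effectively constant (correlation undefined)."""
    wt = np.asarray(wt_profile, dtype=float)
    ko = np.asarray(ko_profile, dtype=float)
    if wt.shape != (len(TIMEPOINTS),) or ko.shape != (len(TIMEPOINTS),):
        raise ValueError(f"profiles must have length {len(TIMEPOINTS)}")
    if _is_flat(wt, eps) or _is_flat(ko, eps):
        return float("nan")
    return float(np.corrcoef(wt, ko)[0, 1])


def responsiveness(profile: np.ndarray, thresholds: Thresholds = Thresholds()) -> bool:
    """True when any post-exposure point moves >= de_abs_log2 from t=0."""
    p = np.asarray(profile, dtype=float)
    if p.shape != (len(TIMEPOINTS),):
        raise ValueError(f"profile must have length {len(TIMEPOINTS)}")
    if (p <= 0).any():
        raise ValueError("profile must be strictly positive")
    ratios = np.abs(np.log2(p[0] / p[1:]))
    return bool((ratios >= thresholds.de_abs_log2).any())


def _max_excursion(profile: np.ndarray) -> float:
    p = np.asarray(profile, dtype=float)
    return float(np.abs(np.log2(p[0] / p[1:])).max())


def _resolve_residual(wt: np.ndarray, ko: np.ndarray) -> int:
    """Dissimilar pattern but neither strain responsive: side with the larger
    maximum excursion from t=0 decides (KO larger -> gained, else lost)."""
    return 3 if _max_excursion(ko) > _max_excursion(wt) else 4


def classify(
    m: ExpressionMatrix, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per-gene classification table.

    Returns one row per gene: ``intrinsic_log2``, ``intrinsic_altered``,
    ``responsive_wt``, ``responsive_ko``, ``pattern_correlation`` (NaN when
    undefined), ``similar`` and ``group``.
    """
    if set(m.strains()) != {"WT", "KO"}:
        raise ValueError(f"both strains required, found {m.strains()}")
    wt = m.profile("WT", TIMEPOINTS)
    ko = m.profile("KO", TIMEPOINTS)

    rows = []
    for gene in m.gene_ids:
        w = wt.loc[gene].to_numpy()
        k = ko.loc[gene].to_numpy()
        intrinsic = float(np.log2(k[0] / w[0]))
        altered = abs(intrinsic) > thresholds.intrinsic_abs_log2
        r = pattern_correlation(w, k)
        if np.isnan(r):
            similar = _is_flat(w) and _is_flat(k) and not altered
        else:
            similar = r >= thresholds.corr_min
        resp_wt = responsiveness(w, thresholds)
        resp_ko = responsiveness(k, thresholds)
        if similar:
            group = 2 if altered else 1
        elif resp_ko and not resp_wt:
            group = 3
        elif resp_wt:
            group = 4
        else:
            group = _resolve_residual(w, k)
        rows.append(
            {
                "gene_id": gene,
                "intrinsic_log2": intrinsic,
                "intrinsic_altered": altered,
                "responsive_wt": resp_wt,
                "responsive_ko": resp_ko,
                "pattern_correlation": r,
                "similar": similar,
                "group": group,
            }
        )
    return pd.DataFrame(rows)


def group_percentages(counts: list[int] | tuple[int, ...]) -> list[int]:
    """Integer percentages of four group counts, rounded half up."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    return [int(np.floor(c / total * 100 + 0.5)) for c in counts]


def summarize(
    classes: pd.DataFrame,
    ann: list[GeneAnnotation] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Summary-table view: per group, gene count, integer percentage,
    intrinsic-shift sub-count, and overrepresented COG letters.

    Per-group enrichment tests every COG (no category excluded) against the
    annotated analysis-set background; letters are ordered by increasing
    p-value so the most significant category comes first.
    """
    counts = [int((classes["group"] == g).sum()) for g in (1, 2, 3, 4)]
    pcts = group_percentages(counts)
    gene_cogs = {a.gene_id: set(a.cogs) for a in ann or [] if a.cogs}
    background = set(gene_cogs) & set(classes["gene_id"])
    N = len(background)
    cats = sorted({c for g in background for c in gene_cogs[g]})
    K = {c: sum(1 for g in background if c in gene_cogs[g]) for c in cats}

    rows = []
    for g, count, pct in zip((1, 2, 3, 4), counts, pcts):
        sub = classes[classes["group"] == g]
        selected = set(sub["gene_id"]) & background
        n = len(selected)
        sig = []
        for c in cats:
            k = sum(1 for gid in selected if c in gene_cogs[gid])
            p = hypergeom_upper_tail(k, n, K[c], N) if n else 1.0
            if p < thresholds.enrich_alpha:
                sig.append((p, c))
        rows.append(
            {
                "group": g,
                "label": GROUP_LABELS[g],
                "n_genes": count,
                "pct": pct,
                "n_intrinsic_altered": int(sub["intrinsic_altered"].sum()),
                "overrepresented_cogs": "".join(c for _, c in sorted(sig)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
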