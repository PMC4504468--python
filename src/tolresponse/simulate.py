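"""Synthetic two-strain, six-timepoint expression matrices with known truth.

The generator emulates the structure of the study data: thousands of genes
measured in a wild-type and a regulator-deletion strain immediately before
and 1, 2, 5, 10 and 30 minutes after solvent addition, with log-scale
multiplicative noise, a mixture of temporal response archetypes, and COG
labels drawn from the published category sizes (which, together with the
uninformative S and R categories and the unannotated genes, sum exactly to
the 6164-gene analysis set).

Every gene is planted in one of the four deletion-effect groups:

1. identical response and level in both strains;
2. identical response, pre-exposure level shifted by >0.5 log2 in KO;
3. flat in WT, responsive in KO (responsiveness gained);
4. responsive in WT, flat (or anti-phase) in KO (responsiveness lost).

Responsive genes receive a *signed* amplitude — up- or down-regulation with
equal probability.  Real solvent shock induces and represses genes in
comparable numbers, and the balance keeps each simulated chip's median
intensity close to the stable-gene baseline, which is the assumption the
per-chip median normalization rests on.

Response archetypes are piecewise-linear curves in log2 space anchored at
the six sampling times (unit amplitude)::

    flat           0    0    0    0    0    0
    immediate_up   0    1    1    0.75 0.5  0.25   (peak at 1 min)
    up_then_down   0    0.4  0.8  1    0   -1      (peak at 5 min, undershoot)
    delayed_down   0    0    0   -0.25 -1  -1      (onset after 5 min)
    sustained_up   0    0.5  1    1    1    1      (plateau from 2 min)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    COG_LETTERS,
    STRAINS,
    TIMEPOINTS,
    ExpressionMatrix,
    GeneAnnotation,
)

__all__ = [
    "ARCHETYPE_SHAPES",
    "RESPONSIVE_ARCHETYPES",
    "DEFAULT_COG_SIZES",
    "DEFAULT_GROUP_FRACTIONS",
    "SyntheticSpec",
    "generate",
    "write_truth",
    "read_truth",
    "write_dataset",
]

#: Unit-amplitude log2 offsets at t = 0, 1, 2, 5, 10, 30 min.
ARCHETYPE_SHAPES: dict[str, tuple[float, ...]] = {
    "flat": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "immediate_up": (0.0, 1.0, 1.0, 0.75, 0.5, 0.25),
    "up_then_down": (0.0, 0.4, 0.8, 1.0, 0.0, -1.0),
    "delayed_down": (0.0, 0.0, 0.0, -0.25, -1.0, -1.0),
    "sustained_up": (0.0, 0.5, 1.0, 1.0, 1.0, 1.0),
}

RESPONSIVE_ARCHETYPES: tuple[str, ...] = (
    "immediate_up",
    "up_then_down",
    "delayed_down",
    "sustained_up",
)

#: Published per-category gene counts (S and R included); with the 43
#: unannotated genes these sum to the 6164-gene analysis set.
DEFAULT_COG_SIZES: dict[str, int] = {
    "A": 16, "C": 260, "D": 24, "E": 431, "F": 90, "G": 164, "H": 131,
    "I": 166, "J": 78, "K": 418, "L": 225, "M": 214, "N": 72, "O": 117,
    "P": 246, "Q": 123, "S": 2292, "R": 596, "T": 239, "U": 56, "V": 159,
    "W": 4,
}

DEFAULT_N_UNANNOTATED: int = 43

#: Group sizes of the published classification (1287, 472, 1762, 2643 of 6164).
DEFAULT_GROUP_FRACTIONS: tuple[float, float, float, float] = (
    1287 / 6164, 472 / 6164, 1762 / 6164, 2643 / 6164,
)

TRUTH_COLUMNS = [
    "gene_id",
    "planted_group",
    "planted_archetype_wt",
    "planted_archetype_ko",
    "planted_intrinsic_log2",
    "planted_amplitude_log2",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated dataset; defaults mirror the study design."""

    n_genes: int = 6164
    seed: int = 0
    noise_sigma_log2: float = 0.1
    group_fractions: tuple[float, float, float, float] = DEFAULT_GROUP_FRACTIONS
    amplitude_range: tuple[float, float] = (1.0, 2.0)
    up_fraction: float = 0.5
    intrinsic_range: tuple[float, float] = (0.8, 2.0)
    shifted_fraction_g3: float = 473 / 1762
    shifted_fraction_g4: float = 1594 / 2643
    flat_fraction: float = 0.0
    baseline_sigma_log2: float = 1.0
    n_replicates: int = 1
    cog_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COG_SIZES))
    n_unannotated: int = DEFAULT_N_UNANNOTATED
    enrichment_plants: tuple[tuple[str, int, float], ...] = ()
    group_archetype: dict[int, str] = field(default_factory=dict)
    group_up_fraction: dict[int, float] = field(default_factory=dict)
    archetype_weights: dict[str, float] = field(
        default_factory=lambda: {a: 1.0 for a in RESPONSIVE_ARCHETYPES}
    )
    group4_ko_mode: str = "flat"  # or "antiphase"

    def __post_init__(self) -> None:
        if self.n_genes < sum(1 for f in self.group_fractions if f > 0):
            raise ValueError("n_genes smaller than the number of non-empty groups")
        if self.noise_sigma_log2 < 0:
            raise ValueError("noise_sigma_log2 must be >= 0")
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise ValueError("group_fractions must sum to 1")
        if any(f < 0 for f in self.group_fractions):
            raise ValueError("group_fractions must be non-negative")
        if self.amplitude_range[0] < 0.5:
            # responsive archetypes must clear the DE threshold by construction
            raise ValueError("amplitude_range low end must be >= the DE threshold 0.5")
        if self.intrinsic_range[0] <= 0.5:
            raise ValueError("intrinsic_range low end must exceed 0.5 log2")
        bad = set(self.cog_sizes) - COG_LETTERS
        if bad:
            raise ValueError(f"unknown COG letter(s) in cog_sizes: {sorted(bad)}")
        if self.group4_ko_mode not in ("flat", "antiphase"):
            raise ValueError("group4_ko_mode must be 'flat' or 'antiphase'")
        for cog, group, odds in self.enrichment_plants:
            if cog not in COG_LETTERS or group not in (1, 2, 3, 4) or odds <= 0:
                raise ValueError(f"invalid enrichment plant {(cog, group, odds)}")


def _group_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Deterministic allocation: round the first three, remainder to the last."""
    counts = [int(np.floor(f * n + 0.5)) for f in fractions[:-1]]
    counts.append(n - sum(counts))
    if counts[-1] < 0:
        raise ValueError("group fractions allocate more genes than available")
    return counts


def _scaled_label_pool(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    """Multiset of per-gene labels ('' = unannotated) scaled to n_genes by
    largest remainder, then shuffled."""
    sizes = dict(spec.cog_sizes)
    sizes[""] = spec.n_unannotated
    total = sum(sizes.values())
    exact = {c: s * spec.n_genes / total for c, s in sizes.items()}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = spec.n_genes - sum(counts.values())
    for c in sorted(exact, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    pool = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(pool)
    return pool


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, list[GeneAnnotation], pd.DataFrame]:
    """Simulate one dataset; returns (matrix, annotation, truth table).

    Deterministic for a fixed spec (all randomness flows from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]

    counts = _group_counts(n, spec.group_fractions)
    groups = np.repeat([1, 2, 3, 4], counts)
    rng.shuffle(groups)

    arch_names = list(spec.archetype_weights)
    w = np.array([spec.archetype_weights[a] for a in arch_names], dtype=float)
    w = w / w.sum()
    chosen = rng.choice(len(arch_names), size=n, p=w)
    responsive_arch = np.array([arch_names[i] for i in chosen])
    for g, a in spec.group_archetype.items():
        if a not in ARCHETYPE_SHAPES:
            raise ValueError(f"unknown archetype {a!r}")
        responsive_arch[groups == g] = a

    lo, hi = spec.amplitude_range
    amp = rng.uniform(lo, hi, size=n)
    up_p = np.full(n, spec.up_fraction)
    for g, f in spec.group_up_fraction.items():
        up_p[groups == g] = f
    signs = np.where(rng.random(n) < up_p, 1.0, -1.0)
    amp *= signs

    # intrinsic log2 shift (KO - WT baseline): group 2 always, a planted
    # sub-fraction of groups 3 and 4, never group 1
    ilo, ihi = spec.intrinsic_range
    intrinsic = np.zeros(n)
    shift_mag = rng.uniform(ilo, ihi, size=n)
    shift_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    intrinsic[groups == 2] = (shift_mag * shift_sign)[groups == 2]
    for g, frac in ((3, spec.shifted_fraction_g3), (4, spec.shifted_fraction_g4)):
        idx = np.flatnonzero(groups == g)
        k = int(np.floor(frac * len(idx) + 0.5))
        pick = rng.permutation(idx)[:k]
        intrinsic[pick] = (shift_mag * shift_sign)[pick]

    arch_wt = responsive_arch.copy()
    arch_ko = responsive_arch.copy()
    arch_wt[groups == 3] = "flat"
    if spec.group4_ko_mode == "flat":
        arch_ko[groups == 4] = "flat"
    # flat-in-both background genes carved out of group 1
    if spec.flat_fraction > 0:
        g1 = np.flatnonzero(groups == 1)
        k = int(np.floor(spec.flat_fraction * n + 0.5))
        pick = rng.permutation(g1)[:k]
        arch_wt[pick] = "flat"
        arch_ko[pick] = "flat"
        intrinsic[pick] = 0.0

    amp_signed = amp.copy()
    amp_signed[(arch_wt == "flat") & (arch_ko == "flat")] = 0.0
    if spec.group4_ko_mode == "antiphase":
        ko_amp = np.where(groups == 4, -amp_signed, amp_signed)
    else:
        ko_amp = amp_signed

    shapes = {a: np.asarray(s) for a, s in ARCHETYPE_SHAPES.items()}
    off_wt = np.stack([shapes[a] for a in arch_wt]) * amp_signed[:, None]
    off_ko = np.stack([shapes[a] for a in arch_ko]) * ko_amp[:, None]

    baseline = rng.normal(0.0, spec.baseline_sigma_log2, size=n)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for strain in STRAINS:
        off = off_wt if strain == "WT" else off_ko
        shift = intrinsic if strain == "KO" else np.zeros(n)
        for ti, t in enumerate(TIMEPOINTS):
            for rep in range(1, spec.n_replicates + 1):
                sid = f"{strain}_t{t}_r{rep}"
                log2v = baseline + off[:, ti] + shift
                if spec.noise_sigma_log2 > 0:
                    log2v = log2v + rng.normal(0.0, spec.noise_sigma_log2, size=n)
                cols[sid] = np.exp2(log2v)
                meta_rows.append(
                    {"sample_id": sid, "strain": strain, "time_min": t, "replicate": rep}
                )

    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ExpressionMatrix(values, samples)

    labels = _scaled_label_pool(spec, rng)
    base_freq = {
        c: labels.count(c) / n for c in set(labels) if c
    }
    for cog, group, odds in spec.enrichment_plants:
        p_plant = min(1.0, odds * base_freq.get(cog, spec.cog_sizes.get(cog, 0) / n))
        for i in np.flatnonzero(groups == group):
            if rng.random() < p_plant:
                labels[i] = cog
    ann = [
        GeneAnnotation(
            gene_id=gid,
            cogs=frozenset(lab) if lab else frozenset(),
            description=f"synthetic gene, group {grp}",
        )
        for gid, lab, grp in zip(gene_ids, labels, groups)
    ]

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_group": groups,
            "planted_archetype_wt": arch_wt,
            "planted_archetype_ko": arch_ko,
            "planted_intrinsic_log2": intrinsic,
            "planted_amplitude_log2": amp_signed,
        }
    )
    return matrix, ann, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated ground-truth table for recovery tests."""
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table {path} missing column(s) {sorted(missing)}")
    return df


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write matrix, sample sheet, annotation and truth files."""
    from .io import write_annotation, write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, ann, truth = generate(spec)
    paths = {
        "matrix": out / "expression_matrix.tsv",
        "samples": out / "sample_meta.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression_matrix(matrix, paths["matrix"], paths["samples"])
    write_annotation(ann, paths["annotation"])
    write_truth(truth, paths["truth"])
    return paths
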