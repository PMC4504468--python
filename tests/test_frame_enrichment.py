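from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from tolresponse.frame_enrichment import (
    FRAMES,
    classify_frames,
    enrich,
    hypergeom_upper_tail,
)
from tolresponse.io import GeneAnnotation, Thresholds

from conftest import make_matrix, profile_matrix


def enumeration_tail(k, n, K, N):
    """Exact integer-arithmetic oracle: count draws with >= k marked items."""
    hits = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1) if n - j <= N - K)
    return Fraction(hits, comb(N, n))


class TestClassifyFrames:
    def test_fifteen_frames_per_strain(self, random_matrix):
        frames = classify_frames(random_matrix)
        assert len(FRAMES) == 15
        per = frames.groupby(["strain", "gene_id"]).size()
        assert (per == 15).all()

    def test_monotone_doubling_is_up_everywhere(self):
        prof = np.exp2([[0, 1, 2, 3, 4, 5]])
        frames = classify_frames(profile_matrix(prof, prof))
        assert (frames["direction"] == "up").all()
        assert (frames["log2_fc"] >= 1.0 - 1e-12).all()

    def test_constant_gene_is_none_everywhere(self):
        prof = np.full((1, 6), 2.0)
        frames = classify_frames(profile_matrix(prof, prof))
        assert (frames["direction"] == "none").all()

    def test_up_then_down_peak_at_five_minutes(self):
        # rises into t=5, falls from 5 to 30
        prof = np.exp2([[0.0, 0.4, 0.8, 1.0, 0.0, -1.0]])
        frames = classify_frames(profile_matrix(prof, prof))
        wt = frames[frames["strain"] == "WT"].set_index(["t_start", "t_end"])
        assert wt.loc[(0, 5), "direction"] == "up"
        assert wt.loc[(5, 30), "direction"] == "down"

    def test_zero_to_t_frames_match_de_orientation(self, random_matrix):
        from tolresponse.de_dynamics import log2_ratio_profile

        frames = classify_frames(random_matrix)
        prof = log2_ratio_profile(random_matrix, "WT")
        wt = frames[(frames["strain"] == "WT") & (frames["t_start"] == 0)]
        for t in (1, 2, 5, 10, 30):
            sub = wt[wt["t_end"] == t].set_index("gene_id")["log2_fc"]
            np.testing.assert_allclose(sub[prof.index], -prof[t], rtol=1e-9)


class TestHypergeomUpperTail:
    def test_zero_successes_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 5, 20) == 1.0
        assert hypergeom_upper_tail(0, 0, 0, 7) == 1.0

    def test_spot_value_against_enumeration(self):
        # P(X >= 4 | N=20, K=5, n=5) = 76/15504
        expected = enumeration_tail(4, 5, 5, 20)
        assert expected == Fraction(76, 15504)
        assert hypergeom_upper_tail(4, 5, 5, 20) == pytest.approx(float(expected), rel=1e-12)

    def test_saturated_draw_is_certain(self):
        assert hypergeom_upper_tail(6, 6, 6, 6) == 1.0

    def test_inconsistent_arguments_rejected(self):
        for bad in [(3, 2, 5, 10), (1, 5, 0, 10), (2, 5, 5, 4), (-1, 2, 2, 4)]:
            with pytest.raises(ValueError):
                hypergeom_upper_tail(*bad)

    def test_matches_enumeration_small_sweep(self):
        # full N <= 12 sweep here; the N <= 25 sweep runs in the acceptance suite
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        exact = float(enumeration_tail(k, n, K, N))
                        got = hypergeom_upper_tail(k, n, K, N)
                        assert got == pytest.approx(exact, rel=1e-9, abs=1e-300)

    def test_matches_scipy_sf(self):
        # independent library cross-check on larger arguments
        for (k, n, K, N) in [(12, 40, 60, 300), (3, 10, 5, 50), (25, 100, 80, 500)]:
            assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
                float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_monotone_decreasing_in_k(self, data):
        N = data.draw(st.integers(2, 40))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ks = range(min(n, K) + 1)
        ps = [hypergeom_upper_tail(k, n, K, N) for k in ks]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def annotation_fixture(gene_ids, rng):
    letters = ["C", "E", "O", "J", "S", ""]
    return [
        GeneAnnotation(g, frozenset(rng.choice(letters)) - {""})
        for g in gene_ids
    ]


class TestEnrich:
    def test_empty_selection_all_p_one(self):
        prof = np.full((30, 6), 1.0)
        m = profile_matrix(prof, prof)
        rng = np.random.default_rng(0)
        ann = annotation_fixture(m.gene_ids, rng)
        enr = enrich(classify_frames(m), ann)
        # nothing moves, so there are no up/down selections at all
        assert enr.empty or (enr["p_value"] == 1.0).all()

    def test_whole_background_selection_not_significant(self):
        # every gene doubles monotonically -> every frame selection is the
        # whole background; enrichment cannot be significant
        rng = np.random.default_rng(1)
        prof = np.exp2(np.outer(np.ones(30), [0, 1, 2, 3, 4, 5]))
        m = profile_matrix(prof, prof)
        ann = annotation_fixture(m.gene_ids, rng)
        enr = enrich(classify_frames(m), ann)
        assert (~enr["significant"]).all()
        for _, row in enr.iterrows():
            assert row["k"] == row["K"] and row["n"] == row["N"]
            assert row["p_value"] == pytest.approx(1.0)

    def test_counts_and_pvalues_match_enumeration_oracle(self, random_matrix):
        rng = np.random.default_rng(2)
        ann = annotation_fixture(random_matrix.gene_ids, rng)
        frames = classify_frames(random_matrix)
        enr = enrich(frames, ann)
        gene_cogs = {a.gene_id: set(a.cogs) - {"S", "R"} for a in ann}
        background = {g for g, c in gene_cogs.items() if c}
        for _, row in enr.sample(60, random_state=0).iterrows():
            sel = frames[
                (frames["strain"] == row["strain"])
                & (frames["t_start"] == row["t_start"])
                & (frames["t_end"] == row["t_end"])
                & (frames["direction"] == row["direction"])
            ]["gene_id"]
            selected = set(sel) & background
            k = sum(1 for g in selected if row["cog"] in gene_cogs[g])
            assert row["k"] == k
            assert row["n"] == len(selected)
            exact = enumeration_tail(int(row["k"]), int(row["n"]), int(row["K"]), int(row["N"]))
            assert row["p_value"] == pytest.approx(float(exact), rel=1e-9)

    def test_excluded_categories_absent_and_background_reduced(self, random_matrix):
        rng = np.random.default_rng(3)
        ann = annotation_fixture(random_matrix.gene_ids, rng)
        enr = enrich(classify_frames(random_matrix), ann)
        assert not set(enr["cog"]) & {"S", "R"}
        n_bg = sum(1 for a in ann if a.cogs - {"S", "R"})
        assert (enr["N"] == n_bg).all()

    def test_up_and_down_selections_disjoint(self, random_matrix):
        frames = classify_frames(random_matrix)
        for _, grp in frames.groupby(["strain", "t_start", "t_end"]):
            up = set(grp[grp["direction"] == "up"]["gene_id"])
            down = set(grp[grp["direction"] == "down"]["gene_id"])
            assert not up & down

    def test_neg_log10_finite(self, random_matrix):
        rng = np.random.default_rng(4)
        ann = annotation_fixture(random_matrix.gene_ids, rng)
        enr = enrich(classify_frames(random_matrix), ann)
        assert np.isfinite(enr["neg_log10_p"]).all()

    def test_planted_category_detected_in_immediate_frame(self):
        # 40 immediate responders, 30 of them COG O; 160 flat genes with O rare
        rng = np.random.default_rng(5)
        n = 200
        prof_wt = np.zeros((n, 6))
        prof_wt[:40, 1:] = 1.0  # immediate, sustained rise
        m = profile_matrix(np.exp2(prof_wt), np.exp2(np.zeros((n, 6))))
        ann = []
        for i, g in enumerate(m.gene_ids):
            if i < 30:
                cogs = frozenset("O")
            else:
                cogs = frozenset(rng.choice(["C", "E", "J", "K"]))
            ann.append(GeneAnnotation(g, cogs))
        enr = enrich(classify_frames(m), ann)
        row = enr[
            (enr["strain"] == "WT")
            & (enr["t_start"] == 0)
            & (enr["t_end"] == 1)
            & (enr["direction"] == "up")
            & (enr["cog"] == "O")
        ]
        assert bool(row["significant"].iloc[0])
        exact = enumeration_tail(int(row["k"].iloc[0]), int(row["n"].iloc[0]),
                                 int(row["K"].iloc[0]), int(row["N"].iloc[0]))
        assert row["p_value"].iloc[0] == pytest.approx(float(exact), rel=1e-9)
        assert float(exact) < 0.01

    def test_empty_background_rejected(self, random_matrix):
        ann = [GeneAnnotation(g, frozenset()) for g in random_matrix.gene_ids]
        with pytest.raises(ValueError, match="background"):
            enrich(classify_frames(random_matrix), ann)
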