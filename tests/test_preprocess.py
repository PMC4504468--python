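import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tolresponse.io import Thresholds
from tolresponse.preprocess import (
    filter_nonchanging,
    floor_signals,
    normalize_per_chip,
    normalize_per_gene,
    run_preprocess,
)
from tolresponse.simulate import SyntheticSpec, generate

from conftest import make_matrix


class TestFloor:
    def test_below_floor_clamped_boundary_untouched(self):
        v = np.ones((1, 12))
        v[0, 0], v[0, 1], v[0, 2] = 0.005, 0.01, 0.02
        out = floor_signals(make_matrix(v), 0.01).values.to_numpy()
        assert out[0, 0] == 0.01 and out[0, 1] == 0.01 and out[0, 2] == 0.02

    def test_identity_when_all_above(self, random_matrix):
        out = floor_signals(random_matrix, 1e-6)
        assert out == random_matrix

    def test_rejects_nonpositive_floor(self, random_matrix):
        with pytest.raises(ValueError):
            floor_signals(random_matrix, 0)


class TestPerChip:
    def test_median_becomes_one(self, random_matrix):
        out = normalize_per_chip(random_matrix)
        np.testing.assert_allclose(out.values.median(axis=0), 1.0, atol=1e-12)

    def test_odd_chip_already_normalized(self):
        # chip (0.5, 1, 4) has median 1: column unchanged
        v = np.ones((3, 12))
        v[:, 0] = [0.5, 1.0, 4.0]
        out = normalize_per_chip(make_matrix(v)).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [0.5, 1.0, 4.0])

    def test_even_chip_uses_mean_of_middle_two(self):
        # independent oracle: numpy percentile with linear interpolation
        v = np.ones((4, 12))
        v[:, 0] = [1.0, 2.0, 3.0, 4.0]
        out = normalize_per_chip(make_matrix(v)).values.to_numpy()
        oracle = np.percentile([1, 2, 3, 4], 50)
        assert oracle == 2.5
        np.testing.assert_allclose(out[:, 0], np.array([1, 2, 3, 4]) / oracle)

    def test_constant_chip_becomes_ones(self):
        v = np.full((3, 12), 2.0)
        out = normalize_per_chip(make_matrix(v)).values.to_numpy()
        np.testing.assert_allclose(out, 1.0)

    def test_zero_median_chip_is_named(self):
        v = np.ones((3, 12))
        v[:, 5] = 0.0
        with pytest.raises(ValueError, match="WT_t30_r1"):
            normalize_per_chip(make_matrix(v))


class TestPerGene:
    def test_two_point_row(self):
        # row (1, 4): median 2.5 -> (0.4, 1.6); brute-force median oracle
        v = np.tile([1.0, 4.0], (1, 6))
        out = normalize_per_gene(make_matrix(v)).values.to_numpy()
        med = sorted(v[0])[5:7]
        assert sum(med) / 2 == 2.5
        np.testing.assert_allclose(np.unique(out[0]), [0.4, 1.6])

    def test_constant_row_and_row_median_one(self, random_matrix):
        out = normalize_per_gene(random_matrix)
        np.testing.assert_allclose(out.values.median(axis=1), 1.0, atol=1e-12)
        v = np.full((1, 12), 7.0)
        np.testing.assert_allclose(
            normalize_per_gene(make_matrix(v)).values.to_numpy(), 1.0
        )

    def test_zero_median_gene_is_named(self):
        v = np.ones((2, 12))
        v[1, :] = 0.0
        with pytest.raises(ValueError, match="g2"):
            normalize_per_gene(make_matrix(v))


class TestNonchangingFilter:
    def band_matrix(self):
        v = np.ones((4, 12))
        v[1, 0] = 1.5          # outside band once -> retained
        v[2, :] = 0.7          # inside band everywhere
        v[2, 6:] = 1.3
        v[3, 3] = 0.5          # below band once -> retained
        return make_matrix(v)

    def test_band_membership_is_closed_and_all_samples(self):
        m = self.band_matrix()
        kept, report = filter_nonchanging(m, 0.667, 1.334)
        assert kept.gene_ids == ["g2", "g4"]
        assert report.n_nonchanging_removed == 2
        assert report.n_retained == 2
        # exact boundary values count as inside (closed interval)
        v = np.ones((1, 12))
        v[0, :6], v[0, 6:] = 0.667, 1.334
        kept2, _ = filter_nonchanging(make_matrix(v), 0.667, 1.334)
        assert kept2.n_genes == 0

    def test_control_removal_and_absent_control_tolerated(self):
        m = self.band_matrix()
        kept, report = filter_nonchanging(
            m, 0.667, 1.334, control_ids={"g2", "not_present"}
        )
        assert "g2" not in kept.gene_ids
        assert report.n_control_removed == 1
        assert report.n_input_genes == 4

    def test_idempotent_on_own_output(self):
        kept, _ = filter_nonchanging(self.band_matrix(), 0.667, 1.334)
        again, report = filter_nonchanging(kept, 0.667, 1.334)
        assert report.n_nonchanging_removed == 0
        assert again.gene_ids == kept.gene_ids

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        low=st.floats(0.3, 0.99, exclude_max=True),
        widen=st.floats(0.0, 0.5),
        seed=st.integers(0, 100),
    )
    def test_widening_band_is_monotone(self, low, widen, seed):
        rng = np.random.default_rng(seed)
        v = np.exp2(rng.normal(0, 1, size=(30, 12)))
        m = normalize_per_gene(make_matrix(v))
        high = 1.0 / low
        kept_narrow, _ = filter_nonchanging(m, low, high)
        kept_wide, _ = filter_nonchanging(m, low - widen * low * 0.5, high + widen)
        assert set(kept_wide.gene_ids) <= set(kept_narrow.gene_ids)


class TestChain:
    def test_zero_noise_removes_exactly_planted_flat_genes(self):
        spec = SyntheticSpec(
            n_genes=300,
            seed=5,
            noise_sigma_log2=0.0,
            flat_fraction=0.2,
            amplitude_range=(1.5, 2.0),
        )
        m, _, truth = generate(spec)
        kept, report = run_preprocess(m, Thresholds())
        flat_both = truth[
            (truth["planted_archetype_wt"] == "flat")
            & (truth["planted_archetype_ko"] == "flat")
            & (truth["planted_intrinsic_log2"] == 0)
        ]["gene_id"]
        assert set(m.gene_ids) - set(kept.gene_ids) == set(flat_both)
        assert report.n_nonchanging_removed == len(flat_both)

    def test_report_parts_sum(self, random_matrix):
        _, report = run_preprocess(random_matrix)
        assert (
            report.n_control_removed + report.n_nonchanging_removed + report.n_retained
            == report.n_input_genes
        )
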