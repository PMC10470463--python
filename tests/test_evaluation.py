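"""Faithfulness tests: patch sensitivity, deletion curves, random baseline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import eegattr as ea
from eegattr.errors import InputError
from eegattr.evaluation import _pearson
from eegattr.model_core import softmax

from conftest import make_linear_model, make_sample


class TestPatchArithmetic:
    @pytest.mark.parametrize(
        "T, n_lo, n_hi",
        [(254, 25, 127), (200, 20, 100), (384, 38, 192)],
    )
    def test_fraction_to_patch_length(self, T, n_lo, n_hi):
        assert ea.patch_length(0.1, T) == n_lo
        assert ea.patch_length(0.5, T) == n_hi

    @pytest.mark.parametrize(
        "n, N, T, pct",
        [(25, 22, 254, 0.45), (127, 22, 254, 2.27), (20, 32, 200, 0.31),
         (100, 32, 200, 1.56), (38, 30, 384, 0.33), (192, 30, 384, 1.67)],
    )
    def test_patch_percentage_of_sample(self, n, N, T, pct):
        assert ea.patch_percent_of_sample(n, N, T) == pytest.approx(pct, abs=0.005)

    def test_evaluation_set_bookkeeping(self):
        assert ea.session_trial_count([12, 12, 12, 12, 20], 5) == 340
        assert ea.evaluation_sample_count(9, 4, 25) == 900
        assert ea.evaluation_sample_count(10, 1, 100) == 1000
        assert ea.evaluation_sample_count(11, 2, 50) == 1100


class TestPerturbPatch:
    def test_zero_sample_is_fixed_point(self):
        s = make_sample(np.zeros((2, 10)))
        out = ea.perturb_patch(s, 0, 3, ea.PerturbationSpec(patch_length=4))
        np.testing.assert_array_equal(out.values, s.values)

    def test_patch_zero_count_and_row_sums(self):
        s = make_sample(np.ones((2, 10)))
        out = ea.perturb_patch(s, 1, 3, ea.PerturbationSpec(patch_length=4))
        assert (out.values == 0).sum() == 4
        np.testing.assert_array_equal(out.values.sum(axis=1), [10.0, 6.0])

    def test_restoring_patch_is_identity(self):
        rng = np.random.default_rng(0)
        s = make_sample(rng.normal(size=(3, 20)))
        out = ea.perturb_patch(s, 2, 5, ea.PerturbationSpec(patch_length=6))
        out.values[2, 5:11] = s.values[2, 5:11]
        np.testing.assert_array_equal(out.values, s.values)

    def test_out_of_range_patch_rejected(self):
        s = make_sample(np.ones((2, 10)))
        with pytest.raises(InputError):
            ea.perturb_patch(s, 0, 8, ea.PerturbationSpec(patch_length=4))


class TestPearson:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=50), rng.normal(size=50)
        r, undefined = _pearson(a, b)
        assert not undefined
        assert r == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)

    def test_zero_variance_flagged(self):
        r, undefined = _pearson(np.ones(10), np.arange(10.0))
        assert undefined


class TestSensitivity:
    def test_linear_model_gradient_x_input_gives_perfect_correlation(self):
        rng = np.random.default_rng(1)
        W, b = rng.normal(size=(2, 200)), rng.normal(size=2)
        model = make_linear_model(W, b, (4, 50))
        x = rng.normal(size=(4, 50))
        s = make_sample(x)
        cmap = ea.compute_contribution(model, s, 0, ea.AttributionConfig(method="gradient_x_input"))
        res = ea.sensitivity_test(model, s, cmap, ea.PerturbationSpec(patch_length=10, seed=3))
        assert not res.undefined
        assert res.pcc == pytest.approx(1.0, abs=1e-9)
        assert len(res.records) == 100

    def test_input_independent_map_correlates_poorly(self):
        """A saliency-style constant map cannot track score drops driven by
        heterogeneous inputs; brute-force deltas on a fixed 4x50 fixture."""
        rng = np.random.default_rng(2)
        W, b = rng.normal(size=(2, 200)), rng.normal(size=2)
        model = make_linear_model(W, b, (4, 50))
        s = make_sample(rng.normal(size=(4, 50)))
        cmap = ea.compute_contribution(model, s, 0, ea.AttributionConfig(method="saliency"))
        res = ea.sensitivity_test(model, s, cmap, ea.PerturbationSpec(patch_length=10, seed=3))
        assert res.pcc < 0.5

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        model = make_linear_model(rng.normal(size=(2, 40)), np.zeros(2), (2, 20))
        s = make_sample(rng.normal(size=(2, 20)))
        cmap = ea.compute_contribution(model, s, 0, ea.AttributionConfig(method="gradient_x_input"))
        spec = ea.PerturbationSpec(patch_length=5, seed=11)
        r1 = ea.sensitivity_test(model, s, cmap, spec)
        r2 = ea.sensitivity_test(model, s, cmap, spec)
        assert r1.pcc == r2.pcc
        pd.testing.assert_frame_equal(r1.records, r2.records)


class TestChannelSensitivity:
    def test_linear_channel_separable_gives_perfect_correlation(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(2, 60))
        model = make_linear_model(W, np.zeros(2), (3, 20))
        s = make_sample(rng.normal(size=(3, 20)))
        cmap = ea.compute_contribution(model, s, 0, ea.AttributionConfig(method="gradient_x_input"))
        chmap = ea.channel_contribution(cmap)
        res = ea.sensitivity_test_channels(model, s, chmap)
        assert res.pcc == pytest.approx(1.0, abs=1e-9)

    def test_constant_channel_map_flagged_undefined(self):
        rng = np.random.default_rng(5)
        model = make_linear_model(rng.normal(size=(2, 60)), np.zeros(2), (3, 20))
        s = make_sample(rng.normal(size=(3, 20)))
        chmap = ea.ChannelContributionMap(np.ones(3), 0, "saliency")
        res = ea.sensitivity_test_channels(model, s, chmap)
        assert res.undefined

    def test_two_channel_result_flagged_low_power(self):
        rng = np.random.default_rng(6)
        model = make_linear_model(rng.normal(size=(2, 20)), np.zeros(2), (2, 10))
        s = make_sample(rng.normal(size=(2, 10)))
        chmap = ea.ChannelContributionMap(np.array([1.0, 2.0]), 0, "x")
        assert ea.sensitivity_test_channels(model, s, chmap).low_power

    def test_random_channel_maps_center_at_zero(self, trained_setup):
        model, eval_ds = trained_setup["model"], trained_setup["eval"]
        s = eval_ds.samples[0]
        c = int(np.argmax(model.forward(s.values)[0]))
        pccs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            chmap = ea.ChannelContributionMap(rng.uniform(-1, 1, size=s.n_channels), c, "random")
            pccs.append(ea.sensitivity_test_channels(model, s, chmap).pcc)
        assert abs(np.median(pccs)) < 0.2  # single-r estimates over 8 channels are noisy


class TestDeletion:
    def _sum_model(self):
        # two classes: S0 = sum(x), S1 = 0
        W = np.vstack([np.ones(20), np.zeros(20)])
        return make_linear_model(W, np.zeros(2), (2, 10))

    def test_closed_form_on_sum_model(self):
        """Map = input values on S(x)=sum(x): the probability curve is the
        softmax of the complement sums, computable in closed form."""
        model = self._sum_model()
        vals = np.arange(20, dtype=float).reshape(2, 10)
        s = make_sample(vals)
        cmap = ea.ContributionMap(vals.copy(), 0, "gradient_x_input")
        fr = np.arange(1, 11) / 10
        curve = ea.deletion_curve(model, s, cmap, fractions=fr, mode="sample")
        order = np.argsort(-vals.ravel(), kind="stable")
        expected = []
        for f in fr:
            m = math.ceil(f * 20)
            kept = np.delete(vals.ravel(), order[:m]).sum()
            expected.append(softmax(np.array([kept, 0.0]))[0])
        np.testing.assert_allclose(curve.probabilities, expected, atol=1e-12)
        np.testing.assert_allclose(curve.auc, np.trapezoid(expected, fr), atol=1e-12)

    def test_uniform_map_deletes_in_raster_order(self):
        model = self._sum_model()
        vals = np.random.default_rng(7).uniform(1, 2, size=(2, 10))
        s = make_sample(vals)
        cmap = ea.ContributionMap(np.ones((2, 10)), 0, "x")
        fr = np.arange(1, 21) / 20
        curve = ea.deletion_curve(model, s, cmap, fractions=fr, mode="sample")
        flat = vals.ravel()
        expected = [softmax(np.array([flat[k:].sum(), 0.0]))[0] for k in range(1, 21)]
        np.testing.assert_allclose(curve.probabilities, expected, atol=1e-12)

    def test_fraction_one_evaluates_all_fill_sample(self):
        model = self._sum_model()
        vals = np.random.default_rng(8).normal(size=(2, 10))
        s = make_sample(vals)
        cmap = ea.ContributionMap(vals.copy(), 0, "x")
        curve = ea.deletion_curve(model, s, cmap, mode="sample")
        assert curve.fractions[-1] == 1.0
        expected = softmax(model.forward(np.zeros((2, 10)))[0])[0]
        assert curve.probabilities[-1] == pytest.approx(expected, abs=1e-12)

    def test_monotone_for_nonnegative_inputs_and_identity_map(self):
        model = self._sum_model()
        vals = np.random.default_rng(9).uniform(0, 3, size=(2, 10))
        s = make_sample(vals)
        cmap = ea.ContributionMap(vals.copy(), 0, "x")
        curve = ea.deletion_curve(model, s, cmap, mode="sample")
        assert np.all(np.diff(curve.probabilities) <= 1e-12)

    def test_channel_mode_cumulative_ordering(self):
        model = self._sum_model()
        vals = np.array([[5.0] * 10, [1.0] * 10])
        s = make_sample(vals)
        chmap = ea.ChannelContributionMap(np.array([5.0, 1.0]), 0, "x")
        curve = ea.deletion_curve(model, s, chmap, mode="channel")
        # first deletes the high-score channel (row 0), then everything
        np.testing.assert_allclose(
            curve.probabilities,
            [softmax(np.array([10.0, 0.0]))[0], softmax(np.array([0.0, 0.0]))[0]],
            atol=1e-12,
        )

    def test_channel_deletion_single_one_at_a_time(self):
        model = self._sum_model()
        vals = np.array([[5.0] * 10, [1.0] * 10])
        s = make_sample(vals)
        chmap = ea.ChannelContributionMap(np.array([5.0, 1.0]), 0, "x")
        probs = ea.channel_deletion_single(model, s, chmap)
        np.testing.assert_allclose(
            probs,
            [softmax(np.array([10.0, 0.0]))[0], softmax(np.array([50.0, 0.0]))[0]],
            atol=1e-12,
        )

    def test_empty_fraction_grid_rejected(self):
        model = self._sum_model()
        s = make_sample(np.ones((2, 10)))
        cmap = ea.ContributionMap(np.ones((2, 10)), 0, "x")
        with pytest.raises(InputError):
            ea.deletion_curve(model, s, cmap, fractions=[], mode="sample")


class TestRandomMap:
    def test_seeded_reproducibility(self):
        a = ea.random_contribution_map((8, 256), seed=5)
        b = ea.random_contribution_map((8, 256), seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_mean_within_law_of_large_numbers_bound(self):
        m = ea.random_contribution_map((16, 128), seed=6)
        assert abs(m.scores.mean()) < 3 / math.sqrt(16 * 128)

    def test_sensitivity_pcc_distribution_centered_at_zero(self):
        """Over 200 seeds the random-map PCC distribution has |median| < 0.1."""
        rng = np.random.default_rng(10)
        model = make_linear_model(rng.normal(size=(2, 128)), np.zeros(2), (4, 32))
        s = make_sample(rng.normal(size=(4, 32)))
        pccs = []
        for seed in range(200):
            cmap = ea.random_contribution_map((4, 32), seed=seed)
            res = ea.sensitivity_test(
                model, s, cmap, ea.PerturbationSpec(patch_length=6, num_perturbations=50, seed=seed)
            )
            pccs.append(res.pcc)
        assert abs(np.median(pccs)) < 0.1


class TestBenchmark:
    def _setup(self):
        rng = np.random.default_rng(11)
        model = make_linear_model(rng.normal(size=(2, 80)), np.zeros(2), (4, 20))
        samples = [make_sample(rng.normal(size=(4, 20))) for _ in range(3)]
        return model, samples

    def test_single_cell_detail_row(self):
        model, samples = self._setup()
        t = ea.benchmark(model, samples[:1], ["gradient_x_input"], tests=("sensitivity",),
                         patch_fractions=(0.2,), num_perturbations=20, seed=1)
        details = t[t["sample"] != "summary"]
        assert len(details) == 1

    def test_sample_order_invariance_of_summaries(self):
        model, samples = self._setup()
        kw = dict(tests=("sensitivity", "deletion"), patch_fractions=(0.2, 0.4),
                  num_perturbations=20, seed=2)
        t1 = ea.benchmark(model, samples, ["gradient_x_input", "random"], **kw)
        t2 = ea.benchmark(model, samples[::-1], ["gradient_x_input", "random"], **kw)
        s1 = t1[t1["sample"] == "summary"].reset_index(drop=True)
        s2 = t2[t2["sample"] == "summary"].reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)

    def test_unknown_method_rejected(self):
        model, samples = self._setup()
        from eegattr.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            ea.benchmark(model, samples, ["occlusion"])
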