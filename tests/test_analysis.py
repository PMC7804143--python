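"""Representation-analysis operations on fabricated and degenerate inputs.

The directional effects on trained networks live in test_acceptance.py; here
the machinery itself is validated against analytic response maps and edge
cases.
"""

import numpy as np
import pytest

from priorpop import analysis as an
from priorpop.encoder import EncoderSpec, TaskSpec
from priorpop.network import NetworkParams, forward_hidden, init_params


@pytest.fixture
def cued_params():
    return init_params(50, 30, TaskSpec.cued_classification(), np.random.default_rng(0))


class TestTuningCurveGeometry:
    grid = np.arange(-20.0, 20.0 + 0.125, 0.25)

    def test_gaussian_bump_recovers_analytic_geometry(self):
        # FWHM = 2 sqrt(2 ln 2) sigma_t; steepest slope at +-sigma_t
        sigma_t = 2.0
        response = 1.7 * np.exp(-((self.grid - 3.0) ** 2) / (2 * sigma_t**2))
        s = an.summarize_tuning_curve(0, self.grid, response)
        assert s.active
        assert s.peak_location == pytest.approx(3.0, abs=0.25)
        assert s.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma_t, abs=0.3)
        assert abs(abs(s.max_slope_location - 3.0) - sigma_t) < 0.3

    def test_constant_response_has_no_geometry(self):
        s = an.summarize_tuning_curve(1, self.grid, np.full_like(self.grid, 0.8))
        assert s.fwhm is None and s.max_slope_location is None

    def test_monotone_ramp_peaks_at_edge_without_fwhm(self):
        ramp = np.linspace(0.0, 2.0, self.grid.size)
        s = an.summarize_tuning_curve(2, self.grid, ramp)
        assert s.peak_location == self.grid[-1]
        assert s.fwhm is None  # right flank never crosses half-max

    def test_silent_unit_marked_inactive(self):
        s = an.summarize_tuning_curve(3, self.grid, np.zeros_like(self.grid))
        assert not s.active

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            an.summarize_tuning_curve(0, self.grid[:4], np.zeros(4))

    def test_estimated_curves_on_known_network(self, spec_est):
        """A hand-built unit whose input weights copy one tuning curve has a
        hidden tuning curve peaking near that neuron's center."""
        task = TaskSpec.estimation(prior_variance=25.0)
        params = init_params(50, 3, task, np.random.default_rng(1))
        params.W[:] = 0.0
        params.b[:] = 0.0
        target = 30  # center ~ 4.5
        params.W[target, 0] = 1.0
        summaries = an.estimate_tuning_curves(
            params, spec_est, n_repeats=50, rng=np.random.default_rng(2)
        )
        assert summaries[0].active
        assert summaries[0].peak_location == pytest.approx(
            spec_est.centers[target], abs=1.0
        )


class TestActivityStats:
    def test_dead_network_has_zero_activity(self, spec_cls):
        task = TaskSpec.classification(prior=0.5)
        params = init_params(50, 20, task, np.random.default_rng(0))
        params.W[:] = 0.0
        params.b[:] = -1.0
        df = an.activity_stats(params, task, spec_cls, [2.6], 200, np.random.default_rng(1))
        assert (df["active_count"] == 0).all() and (df["mean_activity"] == 0).all()

    def test_zero_contrast_activity_is_stimulus_independent(self, spec_cls):
        task = TaskSpec.classification(prior=0.5)
        params = init_params(50, 20, task, np.random.default_rng(3))
        df = an.activity_stats(params, task, spec_cls, [0.0], 500, np.random.default_rng(4))
        # no spikes -> identical hidden state on every trial of either class
        assert df["active_count"].nunique() == 1
        assert df["mean_activity"].nunique() == 1

    def test_posterior_bins_partition_trials(self, spec_cls):
        task = TaskSpec.classification(prior=0.5)
        params = init_params(50, 20, task, np.random.default_rng(5))
        df = an.activity_stats(
            params, task, spec_cls, [2.6], 400, np.random.default_rng(6),
            by_posterior_bin=True,
        )
        assert df["n"].sum() == 400
        assert df["posterior_bin"].between(0, 9).all()


class TestPreactivation:
    def test_no_spikes_concentrates_mass_at_biases(self, spec_cls):
        task = TaskSpec.classification(prior=0.5)
        params = init_params(50, 40, task, np.random.default_rng(7))
        df = an.preactivation_histogram(
            params, task, spec_cls, [0.0], 100, np.random.default_rng(8)
        )
        assert df["mean"].iloc[0] == pytest.approx(params.b.mean())
        q10, q90 = np.quantile(params.b, [0.1, 0.9])
        assert df["interdecile"].iloc[0] == pytest.approx(q90 - q10, rel=1e-9)


class TestSubpopulations:
    def test_identical_bias_and_weights_give_no_difference(self):
        # units alternate class preference but share bias/input weights
        U = np.tile([[0.4, 0.2], [0.2, 0.4]], (5, 1))
        params = NetworkParams(W=np.ones((50, 10)), b=np.ones(10), U=U)
        df = an.subpopulation_param_means(params)
        for pname in ("bias", "input_weight"):
            row = df[df["parameter"] == pname].iloc[0]
            assert row["mean_h1"] == row["mean_h2"]
            assert not (row["p"] < 0.01)  # zero-variance groups -> NaN, never significant

    def test_ties_assigned_to_h2(self):
        U = np.array([[0.5, 0.5], [0.6, 0.4], [0.1, 0.3]])
        params = NetworkParams(W=np.zeros((5, 3)), b=np.zeros(3), U=U)
        split = an.subpopulation_split(params)
        np.testing.assert_array_equal(split.h1, [False, True, False])

    def test_degenerate_split_flagged(self):
        U = np.tile([1.0, 0.0], (6, 1))  # every unit prefers class 1
        params = NetworkParams(W=np.zeros((5, 6)), b=np.arange(6.0), U=U)
        df = an.subpopulation_param_means(params)
        assert df["p"].isna().all()
        assert (df["n_h2"] == 0).all()


class TestCueOps:
    def test_swapping_cue_labels_swaps_attribution_rows(self, cued_params):
        att = an.cue_attribution(cued_params)
        swapped = cued_params.copy()
        swapped.g_cue = cued_params.g_cue[::-1].copy()
        swapped.b_cue = cued_params.b_cue[::-1].copy()
        att2 = an.cue_attribution(swapped)
        a = att.set_index(["cue", "parameter"])
        b = att2.set_index(["cue", "parameter"])
        for p in ("gain", "cue_bias"):
            assert a.loc[(0, p), "mean_h1"] == b.loc[(1, p), "mean_h1"]

    def test_ablate_none_is_identity(self, cued_params):
        r = np.random.default_rng(9).poisson(2.0, size=(5, 50))
        ab = an.ablate_cue(cued_params, "none")
        for cue in (0, 1):
            np.testing.assert_array_equal(
                forward_hidden(r, ab, cue_id=cue),
                forward_hidden(r, cued_params, cue_id=cue),
            )

    def test_ablating_both_channels_removes_cue_dependence(self, cued_params):
        r = np.random.default_rng(10).poisson(2.0, size=(5, 50))
        ab = an.ablate_cue(an.ablate_cue(cued_params, "gain"), "bias")
        np.testing.assert_allclose(
            forward_hidden(r, ab, cue_id=0), forward_hidden(r, ab, cue_id=1)
        )

    def test_unknown_channel_and_missing_cues_rejected(self, cued_params):
        with pytest.raises(ValueError):
            an.ablate_cue(cued_params, "bias_and_gain")
        plain = NetworkParams(W=np.zeros((5, 3)), b=np.zeros(3), U=np.zeros((3, 2)))
        with pytest.raises(ValueError):
            an.ablate_cue(plain, "gain")
        with pytest.raises(ValueError):
            an.cue_attribution(plain)


class TestExpectedUnexpected:
    def _summaries(self, locations):
        grid = np.arange(-20.0, 20.25, 0.25)
        out = []
        for i, loc in enumerate(locations):
            resp = np.exp(-((grid - loc) ** 2) / 8.0)
            out.append(an.summarize_tuning_curve(i, grid, resp))
        return out

    def test_all_expected_flags_empty_group(self):
        task = TaskSpec.estimation(prior_variance=100.0)  # sd 10 covers all
        summaries = self._summaries([-3, 0, 3])
        params = NetworkParams(W=np.zeros((5, 3)), b=np.arange(3.0), U=np.zeros((3, 1)))
        res = an.expected_unexpected_bias(summaries, params, task)
        assert res["degenerate"] and res["n_unexpected"] == 0

    def test_planted_bias_difference_detected_by_permutation(self):
        task = TaskSpec.estimation(prior_variance=4.0)  # sd 2
        locations = list(np.linspace(-1.5, 1.5, 10)) + list(np.linspace(5, 15, 30))
        summaries = self._summaries(locations)
        b = np.concatenate([np.full(10, 1.0), np.full(30, 0.0)])
        b += np.random.default_rng(0).normal(0, 0.05, size=40)
        params = NetworkParams(W=np.zeros((5, 40)), b=b, U=np.zeros((40, 1)))
        res = an.expected_unexpected_bias(
            summaries, params, task, rng=np.random.default_rng(1)
        )
        assert res["difference"] > 0.8
        assert res["p_permutation"] < 0.01


def test_bimodality_test_separates_clear_cases():
    rng = np.random.default_rng(2)
    unimodal = rng.normal(0, 3, size=200)
    bimodal = np.concatenate([rng.normal(-6, 1, 100), rng.normal(6, 1, 100)])
    res_u = an.peak_bimodality_test(unimodal, np.random.default_rng(3), n_boot=99)
    res_b = an.peak_bimodality_test(bimodal, np.random.default_rng(4), n_boot=99)
    assert res_b["p"] < 0.05 <= res_u["p"]
    assert res_b["component_means"][0] < 0 < res_b["component_means"][1]
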