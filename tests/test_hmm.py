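"""HMM engine: forward-backward and Viterbi against exhaustive path
enumeration, EM/VB monotonicity guarantees, parameter recovery, and
state-count selection on small synthetic batches."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from fretscope import hmm
from fretscope.synthetic import simulate_state_path, simulate_trace, yeast_ykt6_model


def _model(means, variances, initial=None, transition=None):
    K = len(means)
    return hmm.HmmModel(
        K=K,
        initial=np.full(K, 1.0 / K) if initial is None else np.asarray(initial, float),
        transition=np.full((K, K), 1.0 / K) if transition is None else np.asarray(transition, float),
        means=np.asarray(means, float),
        variances=np.asarray(variances, float),
    )


def brute_force_loglik(model, series):
    """Oracle: total likelihood by summing over every state path."""
    total = 0.0
    for path in itertools.product(range(model.K), repeat=len(series)):
        p = model.initial[path[0]] * norm.pdf(series[0], model.means[path[0]],
                                              np.sqrt(model.variances[path[0]]))
        for t in range(1, len(series)):
            p *= model.transition[path[t - 1], path[t]] * norm.pdf(
                series[t], model.means[path[t]], np.sqrt(model.variances[path[t]])
            )
        total += p
    return np.log(total)


def brute_force_viterbi(model, series):
    """Oracle: max-probability path by enumeration; first (lexicographically
    smallest) path wins ties, matching the lower-state-index rule."""
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(model.K), repeat=len(series)):
        lp = np.log(model.initial[path[0]]) + norm.logpdf(
            series[0], model.means[path[0]], np.sqrt(model.variances[path[0]])
        )
        for t in range(1, len(series)):
            lp += np.log(model.transition[path[t - 1], path[t]]) + norm.logpdf(
                series[t], model.means[path[t]], np.sqrt(model.variances[path[t]])
            )
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


class TestForwardBackward:
    def test_single_state_closed_form(self):
        model = _model([0.4], [0.01], initial=[1.0], transition=[[1.0]])
        x = np.array([0.35, 0.45, 0.40, 0.50])
        ll, gamma = hmm.forward_backward(model, x)
        assert ll == pytest.approx(norm.logpdf(x, 0.4, 0.1).sum(), rel=1e-10)
        assert np.allclose(gamma, 1.0)

    @pytest.mark.parametrize("K,T", [(2, 2), (2, 5), (3, 4), (3, 6)])
    def test_matches_path_enumeration(self, K, T, rng):
        means = np.linspace(0.2, 0.8, K)
        model = _model(means, np.full(K, 0.02),
                       initial=np.arange(1, K + 1) / np.arange(1, K + 1).sum(),
                       transition=(np.full((K, K), 0.1) + np.eye(K) * (0.9 - 0.1 * (K - 1)))
                       / (0.1 * K + (0.9 - 0.1 * (K - 1))))
        x = rng.uniform(0, 1, T)
        ll, gamma = hmm.forward_backward(model, x)
        assert ll == pytest.approx(brute_force_loglik(model, x), rel=1e-9)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_symmetric_model_symmetric_posteriors(self):
        model = _model([-0.3, 0.3], [0.04, 0.04], initial=[0.5, 0.5],
                       transition=[[0.9, 0.1], [0.1, 0.9]])
        x = np.array([-0.2, 0.0, 0.2])
        _, gamma = hmm.forward_backward(model, x)
        assert np.allclose(gamma, gamma[::-1, ::-1], atol=1e-10)


class TestViterbi:
    def test_noiseless_alternation_recovered(self):
        model = _model([0.2, 0.7], [0.0025, 0.0025], initial=[0.5, 0.5],
                       transition=[[0.8, 0.2], [0.2, 0.8]])
        x = np.array([0.2, 0.7, 0.7, 0.2, 0.7])
        ideal = hmm.viterbi(model, x)
        assert np.array_equal(ideal.state_path, [0, 1, 1, 0, 1])
        assert np.allclose(ideal.idealized_efficiency, model.means[ideal.state_path])

    def test_tie_breaks_to_lower_state_index(self):
        # perfectly symmetric: every path has equal probability at x=0.5
        model = _model([0.5 - 1e-15, 0.5 + 1e-15], [0.01, 0.01], initial=[0.5, 0.5],
                       transition=[[0.5, 0.5], [0.5, 0.5]])
        ideal = hmm.viterbi(model, np.full(4, 0.5))
        assert np.array_equal(ideal.state_path, np.zeros(4))

    @pytest.mark.parametrize("T", [4, 6])
    def test_matches_exhaustive_maximization(self, T, rng):
        model = _model([0.2, 0.45, 0.7], np.full(3, 0.02),
                       initial=[0.5, 0.3, 0.2],
                       transition=[[0.8, 0.15, 0.05], [0.2, 0.6, 0.2], [0.05, 0.25, 0.7]])
        x = rng.uniform(0, 1, T)
        ideal = hmm.viterbi(model, x)
        oracle_path, oracle_lp = brute_force_viterbi(model, x)
        assert np.array_equal(ideal.state_path, oracle_path)


class TestBaumWelch:
    def test_single_state_fixed_point_is_sample_moments(self, rng):
        x = rng.normal(0.4, 0.08, 500)
        fit = hmm.baum_welch(x, K=1, n_restarts=1, seed=0)
        assert fit.model.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert fit.model.variances[0] == pytest.approx(x.var(), rel=1e-4)

    def test_two_state_recovery(self):
        model = yeast_ykt6_model(
            K=2, occupancy=np.array([0.5, 0.5]),
            efficiency_means=np.array([0.2, 0.7]),
            efficiency_sds=np.array([0.05, 0.05]),
            transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
            bleach_lifetime_s=np.inf, camera_sd=0.0,
        )
        path = simulate_state_path(model, 2000, seed=4)
        e = model.efficiency_means[path] + 0.05 * np.random.default_rng(5).standard_normal(2000)
        fit = hmm.baum_welch(e, K=2, n_restarts=3, seed=1)
        assert np.allclose(fit.model.means, [0.2, 0.7], atol=0.02)

    def test_loglik_nondecreasing(self, yeast_small_series):
        for series in yeast_small_series[:5]:
            fit = hmm.baum_welch(series, K=3, n_restarts=2, seed=2)
            assert np.all(np.diff(fit.objective_trace) >= -1e-7)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            hmm.baum_welch(np.zeros(5), K=3)


class TestVbEm:
    def test_elbo_nondecreasing(self, yeast_small_series):
        for series in yeast_small_series[:5]:
            fit = hmm.vb_em(series, K=3, n_restarts=2, seed=3)
            assert np.all(np.diff(fit.objective_trace) >= -1e-7)

    def test_agrees_with_ml_in_data_dominated_limit(self):
        """With thousands of frames the posterior-mean emissions match
        the maximum-likelihood fit to +-0.01."""
        model = yeast_ykt6_model(bleach_lifetime_s=np.inf, camera_sd=0.0)
        path = simulate_state_path(model, 4000, seed=6)
        e = model.efficiency_means[path] + 0.05 * np.random.default_rng(7).standard_normal(4000)
        vb = hmm.vb_em(e, K=3, n_restarts=4, seed=8)
        ml = hmm.baum_welch(e, K=3, n_restarts=4, seed=8)
        assert np.allclose(vb.model.means, ml.model.means, atol=0.01)

    def test_empty_series_degenerate(self):
        fit = hmm.vb_em(np.empty(0), K=2)
        assert fit.degenerate and fit.objective == 0.0

    def test_loglik_cross_check_against_hmmlearn(self, rng):
        """Independent oracle: hmmlearn's GaussianHMM scores the same
        model/series to the same log-likelihood."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = _model([0.2, 0.6], [0.01, 0.02], initial=[0.3, 0.7],
                       transition=[[0.85, 0.15], [0.4, 0.6]])
        x = rng.uniform(0, 1, 50)
        ll, _ = hmm.forward_backward(model, x)
        gm = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        gm.startprob_ = model.initial
        gm.transmat_ = model.transition
        gm.means_ = model.means[:, None]
        gm.covars_ = model.variances[:, None]
        assert ll == pytest.approx(gm.score(x[:, None]), rel=1e-8)


class TestCanonicalOrder:
    def test_models_always_mean_sorted(self, yeast_small_series):
        for series in yeast_small_series[:8]:
            for fitter in (hmm.baum_welch, hmm.vb_em):
                fit = fitter(series, K=3, n_restarts=2, seed=9)
                assert np.all(np.diff(fit.model.means) > 0)

    def test_invalid_unsorted_model_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            _model([0.7, 0.2], [0.01, 0.01])


class TestSelectStates:
    def test_single_state_data_selects_one(self, rng):
        series = [rng.normal(0.5, 0.05, 150) for _ in range(8)]
        K, table = hmm.select_states(series, K_range=range(1, 5), seed=1, n_restarts=2)
        assert K == 1

    def test_two_state_data_selects_two(self):
        model = yeast_ykt6_model(
            K=2, occupancy=np.array([0.6, 0.4]),
            efficiency_means=np.array([0.25, 0.65]),
            efficiency_sds=np.array([0.05, 0.05]),
            transition_matrix=np.array([[0.92, 0.08], [0.12, 0.88]]),
            bleach_lifetime_s=np.inf,
        )
        rng = np.random.default_rng(10)
        series = []
        for i in range(10):
            path = simulate_state_path(model, 250, seed=i)
            tr = simulate_trace(path, model, seed=100 + i)
            from fretscope.traces import compute_efficiency

            series.append(compute_efficiency(tr).prebleach_efficiency())
        K, _ = hmm.select_states(series, K_range=range(1, 5), seed=2, n_restarts=4)
        assert K == 2

    def test_bic_criterion_runs(self, yeast_small_series):
        K, table = hmm.select_states(yeast_small_series[:6], K_range=range(1, 4),
                                     criterion="bic", seed=3, n_restarts=2)
        assert K in (2, 3) and len(table) == 3

    def test_short_traces_dropped_with_warning(self, rng):
        series = [rng.normal(0.5, 0.05, 150), rng.normal(0.5, 0.05, 8)]
        K, table = hmm.select_states(series, K_range=range(1, 5), seed=1, n_restarts=2)
        assert len(table["scores"].iloc[0]) == 1
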