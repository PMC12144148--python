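"""HMM baseline: forward likelihood against a brute-force path-enumeration
oracle (and hmmlearn's independent scorer), EM behavior and sampling laws."""

import itertools

import numpy as np
import pytest
import scipy.stats

from gazegan.errors import InsufficientDataError
from gazegan.hmm import (HMMModel, fit_baum_welch, log_likelihood, sample_hmm,
                         select_state_count)


def brute_force_loglik(model: HMMModel, y) -> float:
    """Sum over every hidden-state path of path probability x emission density."""
    K, total = model.n_states, 0.0
    sds = np.sqrt(model.variances)
    for path in itertools.product(range(K), repeat=len(y)):
        p = model.initial_probs[path[0]]
        for a, b in zip(path, path[1:]):
            p *= model.transition[a, b]
        for s, obs in zip(path, y):
            p *= scipy.stats.norm.pdf(obs, model.means[s], sds[s])
        total += p
    return float(np.log(total))


@pytest.fixture
def toy_model():
    return HMMModel(2, [0.6, 0.4], [[0.7, 0.3], [0.2, 0.8]],
                    [0.2, 0.7], [0.01, 0.04])


class TestForwardLikelihood:
    def test_matches_brute_force_enumeration(self, toy_model, rng):
        for n in (1, 3, 4, 6):
            y = rng.random(n)
            assert log_likelihood(toy_model, y) == pytest.approx(
                brute_force_loglik(toy_model, y), abs=1e-9)

    def test_three_state_case(self, rng):
        model = HMMModel(3, [0.2, 0.3, 0.5],
                         [[0.8, 0.1, 0.1], [0.3, 0.4, 0.3], [0.25, 0.25, 0.5]],
                         [0.1, 0.5, 0.9], [0.02, 0.05, 0.01])
        y = rng.random(5)
        assert log_likelihood(model, y) == pytest.approx(
            brute_force_loglik(model, y), abs=1e-9)

    def test_matches_hmmlearn_scorer(self, toy_model, rng):
        from hmmlearn.hmm import GaussianHMM
        ref = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = toy_model.initial_probs
        ref.transmat_ = toy_model.transition
        ref.means_ = toy_model.means[:, None]
        ref.covars_ = toy_model.variances[:, None]
        y = rng.random(200)
        assert log_likelihood(toy_model, y) == pytest.approx(
            ref.score(y[:, None]), abs=1e-8)

    def test_one_state_reduces_to_sum_of_log_densities(self, rng):
        model = HMMModel(1, [1.0], [[1.0]], [0.4], [0.02])
        y = rng.random(50)
        expected = scipy.stats.norm.logpdf(y, 0.4, np.sqrt(0.02)).sum()
        assert log_likelihood(model, y) == pytest.approx(expected, abs=1e-9)

    def test_appending_observation_decreases_loglik_when_densities_below_one(self, rng):
        model = HMMModel(2, [0.5, 0.5], [[0.9, 0.1], [0.2, 0.8]],
                         [0.3, 0.7], [0.25, 0.36])  # peak densities < 1
        y = rng.random(20)
        lls = [log_likelihood(model, y[:n]) for n in range(1, 21)]
        assert all(b < a for a, b in zip(lls, lls[1:]))

    def test_empty_series_raises(self, toy_model):
        with pytest.raises(ValueError):
            log_likelihood(toy_model, [])


class TestFit:
    def test_one_state_closed_form(self, rng):
        y = rng.normal(0.5, 0.1, 400).clip(0, 1)
        model = fit_baum_welch(y, 1)
        assert model.means[0] == pytest.approx(y.mean(), abs=1e-6)
        assert model.variances[0] == pytest.approx(y.var(), rel=1e-3)
        assert model.transition.ravel() == pytest.approx([1.0])

    def test_loglik_trace_non_decreasing_on_random_data(self, rng):
        for _ in range(5):
            y = rng.beta(0.5, 3.0, size=600)
            model = fit_baum_welch(y, 2, seed=int(rng.integers(1000)), max_iter=50)
            assert np.all(np.diff(model.loglik_trace) >= -1e-8)

    def test_two_state_parameter_recovery(self):
        truth = HMMModel(2, [0.5, 0.5], [[0.95, 0.05], [0.10, 0.90]],
                         [0.02, 0.30], [0.01 ** 2, 0.08 ** 2])
        y, _ = sample_hmm(truth, 20_000, seed=3)
        fit = fit_baum_welch(y, 2, seed=0)
        order = np.argsort(fit.means)
        A = fit.transition[np.ix_(order, order)]
        assert np.max(np.abs(A - truth.transition)) < 0.02
        assert np.max(np.abs(fit.means[order] - truth.means)) < 0.01

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_baum_welch(rng.random(25), 3)


class TestSampling:
    def test_identity_transition_freezes_state(self):
        model = HMMModel(2, [0.0, 1.0], np.eye(2), [0.2, 0.8], [0.001, 0.001])
        _, states = sample_hmm(model, 500, seed=0)
        assert np.all(states == 1)

    def test_transition_frequency_matches_matrix(self, toy_model):
        _, states = sample_hmm(toy_model, 100_000, seed=7)
        from_1 = states[:-1] == 0
        freq = np.mean(states[1:][from_1] == 1)
        assert freq == pytest.approx(toy_model.transition[0, 1], abs=0.01)

    def test_same_seed_identical(self, toy_model):
        a, sa = sample_hmm(toy_model, 300, seed=9)
        b, sb = sample_hmm(toy_model, 300, seed=9)
        assert np.array_equal(a, b) and np.array_equal(sa, sb)

    def test_emissions_respect_unit_interval(self):
        model = HMMModel(2, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                         [0.05, 0.95], [0.04, 0.04])
        obs, _ = sample_hmm(model, 5000, seed=1)
        assert obs.min() >= 0.0 and obs.max() <= 1.0

    def test_bad_length_raises(self, toy_model):
        with pytest.raises(ValueError):
            sample_hmm(toy_model, 0)


class TestStateSelection:
    def test_single_candidate_table(self, rng):
        y = rng.beta(0.8, 4.0, size=800)
        table, best = select_state_count(y, candidates=(1,), seed=0,
                                         max_iter=30, n_restarts=2)
        assert len(table) == 1 and best == 1

    def test_table_order_and_divergence_range(self, rng):
        y = rng.beta(0.8, 4.0, size=1500)
        table, best = select_state_count(y, candidates=(1, 2, 3), seed=0,
                                         max_iter=30, n_restarts=2)
        assert list(table["n_states"]) == [1, 2, 3]
        assert ((table["D_JS"] >= 0) & (table["D_JS"] <= 1)).all()
        assert best in (1, 2, 3)
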