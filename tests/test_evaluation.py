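"""Metric correctness: histogram D_JS, ACF, moments, spectral score and the
epoch-integral efficiency scores."""

import numpy as np
import pytest
import scipy.spatial.distance
import statsmodels.tsa.stattools
from hypothesis import given
from hypothesis import strategies as st

from gazegan import evaluation as ev
from gazegan.errors import DegenerateRangeError


def _pair(P, Q):
    edges = np.linspace(0, 1, len(P) + 1)
    return ev.HistogramPair(edges, np.asarray(P, float), np.asarray(Q, float))


class TestJSDivergence:
    def test_identical_distributions(self):
        assert ev.js_divergence(_pair([0.3, 0.7], [0.3, 0.7])) == 0.0

    def test_disjoint_supports_hit_upper_bound(self):
        assert ev.js_divergence(_pair([1, 0], [0, 1])) == pytest.approx(1.0)

    def test_worked_example(self):
        assert ev.js_divergence(_pair([1, 0], [0.5, 0.5])) == pytest.approx(
            0.31128, abs=5e-6)

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            P = rng.random(10)
            Q = rng.random(10)
            P, Q = P / P.sum(), Q / Q.sum()
            ref = scipy.spatial.distance.jensenshannon(P, Q, base=2) ** 2
            assert ev.js_divergence(_pair(P, Q)) == pytest.approx(ref, abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
           st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
    def test_symmetry_and_bounds(self, p, q):
        n = min(len(p), len(q))
        P, Q = np.asarray(p[:n]) + 1e-12, np.asarray(q[:n]) + 1e-12
        P, Q = P / P.sum(), Q / Q.sum()
        d1 = ev.js_divergence(_pair(P, Q))
        d2 = ev.js_divergence(_pair(Q, P))
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert -1e-12 <= d1 <= 1.0 + 1e-12

    def test_histogram_probs_contracts(self, rng):
        a = rng.random(500)
        pair = ev.histogram_probs(a, a, 20)
        assert np.array_equal(pair.P, pair.Q)
        pair = ev.histogram_probs(rng.uniform(0, 1, 1000),
                                  rng.uniform(1, 2, 1000), 2)
        assert pair.P == pytest.approx([1, 0]) and pair.Q == pytest.approx([0, 1])
        for _ in range(20):
            pair = ev.histogram_probs(rng.normal(size=50), rng.normal(size=70), 13)
            assert pair.P.sum() == pytest.approx(1.0)
            assert pair.Q.sum() == pytest.approx(1.0)

    def test_degenerate_range_raises(self):
        with pytest.raises(DegenerateRangeError):
            ev.histogram_probs(np.ones(5), np.ones(5))


def acf_direct(x, max_lag):
    x = np.asarray(x, float)
    T = len(x)
    xb = x.mean()
    denom = sum((x[t] - xb) ** 2 for t in range(T))
    out = []
    for h in range(max_lag + 1):
        out.append(sum((x[t] - xb) * (x[t + h] - xb)
                       for t in range(T - h)) / denom)
    return np.array(out)


class TestACF:
    def test_lag_zero_is_one(self, rng):
        assert ev.acf(rng.normal(size=50), 5)[0] == pytest.approx(1.0)

    def test_alternating_series(self):
        assert ev.acf([1, -1, 1, -1], 1)[1] == pytest.approx(-0.75)

    def test_linear_series(self):
        assert ev.acf([1, 2, 3, 4], 1)[1] == pytest.approx(0.25)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 51))
            x = rng.normal(size=n)
            lag = int(rng.integers(1, n))
            assert np.max(np.abs(ev.acf(x, lag) - acf_direct(x, lag))) < 1e-12

    def test_matches_statsmodels(self, rng):
        x = rng.normal(size=200)
        ref = statsmodels.tsa.stattools.acf(x, nlags=10, fft=False, adjusted=False)
        assert ev.acf(x, 10) == pytest.approx(ref, abs=1e-10)

    def test_constant_series_raises(self):
        with pytest.raises(DegenerateRangeError):
            ev.acf(np.ones(10), 2)


def moments_direct(x):
    """Independent textbook central-moment accumulation."""
    x = np.asarray(x, dtype=np.longdouble)
    n = len(x)
    mu = float(x.sum() / n)
    m2 = float(((x - mu) ** 2).sum() / n)
    m3 = float(((x - mu) ** 3).sum() / n)
    m4 = float(((x - mu) ** 4).sum() / n)
    return mu, np.sqrt(m2), m3 / m2 ** 1.5, m4 / m2 ** 2 - 3


class TestMoments:
    def test_symmetric_two_point_distribution(self):
        x = np.array([-1.0, 1.0] * 50)
        m = ev.moment_summary(x)
        assert m.skewness == pytest.approx(0.0, abs=1e-12)
        assert m.kurtosis == pytest.approx(-2.0)

    def test_matches_independent_accumulation(self, rng):
        x = rng.gamma(2.0, 1.5, size=5000)
        m = ev.moment_summary(x)
        mu, sd, sk, ku = moments_direct(x)
        assert m.mean == pytest.approx(mu, rel=1e-10)
        assert m.sd == pytest.approx(sd, rel=1e-10)
        assert m.skewness == pytest.approx(sk, rel=1e-10)
        assert m.kurtosis == pytest.approx(ku, rel=1e-8)

    def test_gaussian_large_sample(self, rng):
        x = rng.standard_normal(10 ** 6)
        m = ev.moment_summary(x)
        assert abs(m.skewness) < 0.01
        assert abs(m.kurtosis) < 0.02

    def test_affine_invariance_of_shape_moments(self, rng):
        x = rng.gamma(1.0, 1.0, size=2000)
        m1 = ev.moment_summary(x)
        m2 = ev.moment_summary(3.5 * x - 2.0)
        assert m1.skewness == pytest.approx(m2.skewness)
        assert m1.kurtosis == pytest.approx(m2.kurtosis)

    def test_pearson_convention_offsets_by_three(self, rng):
        x = rng.normal(size=500)
        assert ev.moment_summary(x, "pearson").kurtosis == pytest.approx(
            ev.moment_summary(x, "excess").kurtosis + 3.0)


class TestSpectralScore:
    def test_zero_on_identical_populations(self, rng):
        x = rng.random((4, 16))
        assert ev.spectral_score(x, x.copy()) == pytest.approx(0.0, abs=1e-18)

    def test_worked_pair_is_loss_over_length(self):
        val = ev.spectral_score(np.array([[1, 0, 0, 0]]), np.array([[2, 0, 0, 0]]))
        assert val == pytest.approx(np.log(2) ** 2, rel=1e-6)

    def test_shuffle_invariance(self, rng):
        a, b = rng.random((8, 12)), rng.random((8, 12))
        perm = rng.permutation(8)
        assert ev.spectral_score(a, b) == pytest.approx(
            ev.spectral_score(a[perm], b[perm]))


def _records(epochs, l_spec, d_js, wall=1.0):
    from gazegan.training import EpochRecord
    return [EpochRecord(e, 0, 0, ls, ls, dj, 0, wall)
            for e, ls, dj in zip(epochs, l_spec, d_js)]


class TestIntegralScores:
    def test_constant_curve_rectangle(self):
        epochs = range(100, 501)
        recs = _records(epochs, [2.0] * 401, [0.25] * 401)
        score = ev.integral_scores(recs)
        assert score.integral_D_JS == pytest.approx(400 * 0.25)
        assert score.integral_L_spectral == pytest.approx(400 * 2.0)

    def test_linear_curve_trapezoid(self):
        epochs = list(range(100, 501))
        ramp = np.linspace(0.0, 1.0, 401)
        score = ev.integral_scores(_records(epochs, ramp, ramp))
        assert score.integral_D_JS == pytest.approx(200.0)

    def test_volume_is_product(self):
        recs = _records(range(100, 501), [2 / 400] * 401, [3 / 400] * 401, wall=4.0)
        score = ev.integral_scores(recs)
        assert score.integral_L_spectral == pytest.approx(2.0)
        assert score.volume == pytest.approx(2.0 * 3.0 * 4.0)

    def test_uncovered_window_raises(self):
        with pytest.raises(ValueError):
            ev.integral_scores(_records(range(150, 300), [1] * 150, [1] * 150))
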