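import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lccnet import (
    HopfParams,
    TimeSeriesEnsemble,
    combine_lcc_ddc,
    correlation_estimate,
    cut_series,
    ddc_linear,
    ddc_matrix,
    estimate_with,
    lcc_estimate,
    naive_transfer_entropy,
    partial_correlation,
    simulate_hopf,
    spectral_peak,
    threshold_matrix,
    xcorr_fft,
)
from lccnet.errors import DegenerateSignalError
from lccnet.estimators import EstimatedConnectivity, METHOD_NAMES
from lccnet import LinearParams, build_linear_gt, simulate_linear

from conftest import make_network


def brute_force_xcorr(x, y, max_lag):
    """O(T^2) time-domain oracle for R(tau) = sum_t x(t) y(t+tau) / norm."""
    x = x - x.mean()
    y = y - y.mean()
    norm = np.sqrt((x**2).sum() * (y**2).sum())
    out = []
    for tau in range(-max_lag, max_lag + 1):
        if tau >= 0:
            out.append(np.dot(x[: x.size - tau], y[tau:]) / norm)
        else:
            out.append(np.dot(x[-tau:], y[: y.size + tau]) / norm)
    return np.array(out)


def _ens(x, dt=1.0):
    return TimeSeriesEnsemble(x=np.asarray(x, float), y=None, dt=dt, seed=0)


class TestXcorrFFT:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_time_domain_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=512)
        y = rng.normal(size=512)
        res = xcorr_fft(x, y)
        expected = brute_force_xcorr(x, y, 511)
        assert np.max(np.abs(res.corr_sequence - expected)) < 1e-8

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(8, 200))
    def test_fft_equals_oracle_property(self, seed, T):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=T)
        y = rng.normal(size=T)
        L = min(20, T - 1)
        res = xcorr_fft(x, y, max_lag=L)
        assert np.max(np.abs(res.corr_sequence - brute_force_xcorr(x, y, L))) < 1e-8

    def test_autocorrelation_identity(self):
        x = np.random.default_rng(3).normal(size=4096)
        res = xcorr_fft(x, x)
        assert res.tau_max == 0
        assert res.r_max == pytest.approx(1.0, abs=1e-12)

    def test_delayed_copy_has_positive_lag_when_first_leads(self):
        base = np.random.default_rng(7).normal(size=10_050)
        x, y = base[50:], base[:-50]  # x(t) = base(t+50): x leads y by 50
        res = xcorr_fft(x, y, max_lag=200)
        assert res.tau_max == 50
        assert res.r_max > 0.95
        # swapping the arguments mirrors the lag axis
        assert xcorr_fft(y, x, max_lag=200).tau_max == -50

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateSignalError):
            xcorr_fft(np.ones(100), np.random.default_rng(0).normal(size=100))


def _smooth_driver(T, seed, tau=30.0):
    """Autocorrelated driver so a delayed copy stays correlated."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=T)
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -(1.0 - 1.0 / tau)], noise)


class TestLCC:
    def test_two_node_delayed_copy_direction(self):
        base = _smooth_driver(20_100, seed=1)
        leader = base[50:]                # leader(t) = base(t + 50)
        follower = base[:-50] + 0.1 * np.random.default_rng(2).normal(size=20_050)
        est = lcc_estimate(_ens([leader[:20_000], follower[:20_000]]), max_lag=200)
        assert est.weights[1, 0] > 0.5    # 0 -> 1 detected
        assert est.weights[0, 1] == 0.0

    def test_direction_recovery_rate_over_many_toys(self):
        correct = 0
        for seed in range(100):
            base = _smooth_driver(5100, seed=seed)
            leader = base[40:]
            follower = base[:-40] + 0.2 * np.random.default_rng(1000 + seed).normal(size=5060)
            est = lcc_estimate(_ens([leader[:5000], follower[:5000]]), max_lag=100)
            if est.weights[1, 0] > 0 and est.weights[0, 1] == 0:
                correct += 1
        assert correct >= 95

    def test_independent_white_noise_gives_negligible_entries(self):
        rng = np.random.default_rng(0)
        est = lcc_estimate(_ens(rng.normal(size=(2, 100_000))), max_lag=200)
        assert np.abs(est.weights).max() < 0.05

    def test_zero_diagonal_and_tagging(self):
        base = _smooth_driver(10_000, seed=3)
        rng = np.random.default_rng(4)
        est = lcc_estimate(_ens(np.vstack([base, rng.normal(size=10_000)])))
        assert np.all(np.diag(est.weights) == 0)
        assert est.method == "lcc"
        assert est.params["value"] == "lagged"

    def test_degenerate_node_zeroed_with_warning(self):
        rng = np.random.default_rng(5)
        x = np.vstack([np.ones(5000), rng.normal(size=5000), rng.normal(size=5000)])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            est = lcc_estimate(_ens(x))
        assert np.all(est.weights[0] == 0) and np.all(est.weights[:, 0] == 0)


class TestThresholdAndCut:
    def test_worked_example_keeps_boundary_value(self):
        m = np.array([[0.05, 0.5], [0.1, 0.0]])
        out = threshold_matrix(m, 0.1)
        assert np.array_equal(out, np.array([[0.0, 0.5], [0.1, 0.0]]))

    def test_negative_entries_are_clamped(self):
        assert threshold_matrix(np.array([[-0.5, 0.2]]), 0.1).tolist() == [[0.0, 0.2]]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 1000), st.floats(0, 1))
    def test_threshold_idempotent_and_identity_at_zero(self, seed, thr):
        m = np.random.default_rng(seed).uniform(-1, 1, size=(4, 4))
        once = threshold_matrix(m, thr)
        assert np.array_equal(threshold_matrix(once, thr), once)
        assert np.array_equal(threshold_matrix(np.abs(m), 0.0), np.abs(m))

    def test_cut_length_and_dt(self):
        ts = _ens(np.random.default_rng(0).normal(size=(2, 200_000)), dt=0.1)
        cut = cut_series(ts, 15)
        assert cut.n_samples == 13_334
        assert cut.dt == pytest.approx(1.5)
        assert np.array_equal(cut_series(ts, 1).x, ts.x)
        with pytest.raises(ValueError):
            cut_series(ts, 200_000)

    def test_cut_aliases_above_new_nyquist(self):
        # 60 Hz sampled at 1 kHz, cut to 66.67 Hz -> alias at |60 - 66.67| Hz
        t = np.arange(40_000) * 1e-3
        ts = _ens(np.sin(2 * np.pi * 60.0 * t)[None, :].repeat(2, 0), dt=1.0)
        cut = cut_series(ts, 15)
        assert abs(spectral_peak(cut.x[0], cut.dt) - 1000 / 15 + 60) < 0.1


class TestDDC:
    def test_recovers_generator_of_noiseless_linear_flow(self):
        """X solving dX/dt = A X exactly gives Chat = A (central scheme is
        second-order on smooth data; forward is first-order)."""
        rng = np.random.default_rng(1)
        A = -1.5 * np.eye(4) + 0.3 * rng.normal(size=(4, 4))
        from scipy.linalg import expm

        dt = 1e-3
        step = expm(A * dt)
        X = np.empty((4, 4000))
        X[:, 0] = rng.normal(size=4)
        for t in range(3999):
            X[:, t + 1] = step @ X[:, t]
        assert np.max(np.abs(ddc_matrix(X, dt, scheme="central") - A)) < 1e-3
        assert np.max(np.abs(ddc_matrix(X, dt) - A)) < 1e-2

    def test_linear_model_consistency(self):
        C = build_linear_gt(10, 0.2, seed=5)
        ts = simulate_linear(C, LinearParams(duration=500, seed=5))
        gt = C.copy()
        np.fill_diagonal(gt, 0.0)
        from lccnet import matrix_correlation

        assert matrix_correlation(gt, ddc_linear(ts).weights) > 0.9

    def test_estimate_diagonal_is_zero_with_decay_in_params(self):
        ts = simulate_linear(build_linear_gt(5, 0.2, seed=1), LinearParams(duration=100, seed=1))
        est = ddc_linear(ts)
        assert np.all(np.diag(est.weights) == 0)
        assert all(d < 0 for d in est.params["diagonal"])


class TestCombine:
    def test_value_comes_from_lcc(self):
        lcc = EstimatedConnectivity(np.array([[0.0, 0.5], [0.05, 0.0]]), "lcc", {})
        ddc = EstimatedConnectivity(np.array([[0.0, 0.3], [0.4, 0.0]]), "ddc", {})
        out = combine_lcc_ddc(lcc, ddc, thr=0.1)
        assert out.weights[0, 1] == 0.5  # above thr in both, LCC value kept
        assert out.weights[1, 0] == 0.0  # LCC side below thr

    def test_empty_intersection_cases(self):
        a = EstimatedConnectivity(np.array([[0.0, 0.5], [0.5, 0.0]]), "lcc", {})
        zero = EstimatedConnectivity(np.zeros((2, 2)), "ddc", {})
        assert np.all(combine_lcc_ddc(a, zero).weights == 0)
        assert np.all(combine_lcc_ddc(a, a, thr=0.9).weights == 0)
        with pytest.raises(ValueError):
            combine_lcc_ddc(a, EstimatedConnectivity(np.zeros((3, 3)), "ddc", {}))


class TestBaselines:
    def test_correlation_is_symmetric_with_unit_pair(self):
        base = _smooth_driver(10_000, seed=2)
        est = correlation_estimate(_ens(np.vstack([base, base])))
        assert est.weights[0, 1] == pytest.approx(1.0)
        assert np.array_equal(est.weights, est.weights.T)
        assert np.all(np.diag(est.weights) == 0)

    def test_partial_correlation_attenuates_indirect_link(self):
        """Chain 0 -> 1 -> 2: conditioning on node 1 removes the 0-2 link."""
        C0 = np.zeros((3, 3))
        C0[1, 0] = C0[2, 1] = 1.0
        C = C0 - 2.0 * np.eye(3)
        ts = simulate_linear(C, LinearParams(duration=500, seed=3))
        plain = correlation_estimate(ts).weights
        partial = partial_correlation(ts, l1_penalty=0.01).weights
        assert abs(partial[0, 2]) < abs(plain[0, 2]) / 2
        assert np.allclose(partial, partial.T)

    def test_partial_correlation_of_independent_nodes_is_small(self):
        rng = np.random.default_rng(6)
        est = partial_correlation(_ens(rng.normal(size=(4, 20_000))), l1_penalty=0.05)
        assert np.abs(est.weights).max() < 0.05

    def test_nte_detects_direction_of_deterministic_drive(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30_000)
        x = np.empty(30_000)
        x[0] = 0.0
        x[1:] = y[:-1] + 0.05 * rng.normal(size=29_999)
        est = naive_transfer_entropy(_ens(np.vstack([x, y])), n_bins=8)
        te_y_to_x = est.weights[0, 1]
        te_x_to_y = est.weights[1, 0]
        assert te_y_to_x > 5 * te_x_to_y
        assert np.all(est.weights >= 0)

    def test_nte_of_independent_series_below_shuffle_null(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30_000)
        y = rng.normal(size=30_000)
        est = naive_transfer_entropy(_ens(np.vstack([x, y])), n_bins=8)
        nulls = []
        for k in range(20):
            y_shift = np.roll(y, 997 * (k + 1))
            nulls.append(
                naive_transfer_entropy(_ens(np.vstack([x, y_shift])), n_bins=8).weights[0, 1]
            )
        assert est.weights[0, 1] <= np.percentile(nulls, 95) * 1.5

    def test_nte_history_beyond_one_not_implemented(self):
        with pytest.raises(NotImplementedError):
            naive_transfer_entropy(_ens(np.zeros((2, 100))), history=2)


@pytest.mark.parametrize("method", METHOD_NAMES)
def test_every_method_returns_finite_zero_diagonal(method, short_hopf_run):
    _, _, ts = short_hopf_run
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = estimate_with(method, ts)
    assert est.weights.shape == (6, 6)
    assert np.all(np.isfinite(est.weights))
    assert np.all(np.diag(est.weights) == 0)
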