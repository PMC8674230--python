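"""ALS baseline (with a dense linear-algebra oracle), relative peak
criterion, sliding averages, lag and growth rate."""
import numpy as np
import pytest

from capflex import kinetics as kn
from capflex import simulate as sim
from capflex.types import InsufficientDataError, PeakTable, Trace, ValidationError


def dense_als_oracle(y, p=0.001, lam_log10=4.0, iterations=20, tol=0.005):
    """Direct dense solve of the penalized system, one pass per iteration.

    Independent of the package's sparse implementation: builds the full
    (W + λ·D₂ᵀD₂) matrix and calls numpy's dense solver, with the same
    reweighting schedule.  Returns the baseline after every iteration.
    """
    n = y.size
    lam = 10.0 ** lam_log10
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i:i + 3] = [1.0, -2.0, 1.0]
    penalty = lam * d2.T @ d2
    w = np.ones(n)
    z = y.copy()
    history = []
    for _ in range(iterations):
        a = np.diag(w) + penalty
        z_new = np.linalg.solve(a, w * y)
        change = np.max(np.abs(z_new - z) / np.maximum(np.abs(z), 1e-300))
        z = z_new
        history.append(z.copy())
        w = np.where(y > z, p, 1.0 - p)
        if change < tol:
            break
    return history


class TestAlsBaseline:
    def test_constant_trace_fixed_point(self):
        y = np.full(120, 3.3)
        z = kn.als_baseline(y)
        np.testing.assert_allclose(z, y, rtol=1e-9)

    def test_asymmetry_keeps_baseline_below_spikes(self, rng):
        """The baseline hugs the lower envelope: any bulge under a spike
        stays far below the spike amplitude."""
        spike = 5.0
        y = np.full(500, 2.0)
        y[rng.choice(500, 25, replace=False)] += spike
        z = kn.als_baseline(y)
        frac_below = np.mean(z <= y + 1e-3 * spike)
        assert frac_below >= 1 - 2 * 0.001
        assert z.max() < 2.0 + 0.01 * spike  # never tracks the spikes

    def test_matches_dense_oracle_per_iteration(self, rng):
        """Sparse solver output equals a dense direct solve to < 1e-8
        relative error after every re-weighting pass (n = 200)."""
        y = 2.0 + 0.1 * np.sin(np.linspace(0, 6, 200))
        y[[40, 90, 150]] += 4.0
        oracle_hist = dense_als_oracle(y)
        for k in range(1, len(oracle_hist) + 1):
            z = kn.als_baseline(y, iterations=k, tol=0.0)
            err = np.max(np.abs(z - oracle_hist[k - 1]) / np.abs(oracle_hist[k - 1]))
            assert err < 1e-8

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            kn.als_baseline(np.ones(5))

    def test_insensitive_to_sparse_spikes(self, rng):
        """Spikes on <5% of samples shift the baseline by <1%."""
        y0 = np.full(2000, 3.0)
        y1 = y0.copy()
        y1[rng.choice(2000, 80, replace=False)] += 10.0
        z0, z1 = kn.als_baseline(y0), kn.als_baseline(y1)
        assert np.max(np.abs(z1 - z0) / z0) < 0.01


class TestKineticPeaks:
    @staticmethod
    def _flat_trace(n=400, level=2.0):
        return Trace(np.arange(n) / 100.0, np.full(n, level))

    def test_one_percent_criterion(self):
        """1.005× baseline is not a peak; 1.02× is."""
        for factor, expected in ((1.005, 0), (1.02, 1)):
            tr = self._flat_trace()
            y = tr.signal.copy()
            y[200:203] = 2.0 * factor
            tr = Trace(tr.time, y)
            z = np.full(len(tr), 2.0)
            assert kn.detect_kinetic_peaks(tr, z).n == expected

    def test_quiet_noise_yields_no_peaks(self, rng):
        tr = Trace(np.arange(1000) / 100.0,
                   10.0 + rng.normal(0, 0.01, 1000))  # sd = 0.1% of baseline
        z = np.full(1000, 10.0)
        assert kn.detect_kinetic_peaks(tr, z).n == 0

    def test_nonpositive_baseline_rejected(self):
        tr = self._flat_trace()
        z = np.zeros(len(tr))
        with pytest.raises(ValidationError):
            kn.detect_kinetic_peaks(tr, z)

    def test_peak_times_match_ground_truth(self):
        trace, truth = sim.simulate_kinetics_trace(13, noise_sd=0.0)
        z = kn.als_baseline(trace)
        peaks = kn.detect_kinetic_peaks(trace, z)
        # every true event has a detected peak within one sampling interval
        for t_e in truth["event_times"]:
            assert np.min(np.abs(peaks.peak_times - t_e)) <= trace.dt + 1e-9


class TestSlidingAverage:
    @staticmethod
    def _peaks(heights, times=None):
        h = np.asarray(heights, dtype=float)
        t = np.asarray(times, dtype=float) if times is not None else np.arange(h.size, dtype=float)
        return PeakTable(t, h, h.copy(), np.zeros(h.size, dtype=bool), 0.01)

    def test_ten_equal_heights_single_point(self):
        times, means = kn.sliding_peak_average(self._peaks(np.full(10, 4.2)))
        assert means.size == 1
        assert means[0] == pytest.approx(4.2)

    def test_arithmetic_series(self):
        times, means = kn.sliding_peak_average(self._peaks(np.arange(1.0, 21.0)))
        assert means[0] == pytest.approx(5.5)
        assert means[-1] == pytest.approx(15.5)

    def test_order_by_time_not_by_index(self, rng):
        h = np.arange(1.0, 21.0)
        t = np.arange(20.0)
        perm = rng.permutation(20)
        t1, m1 = kn.sliding_peak_average(self._peaks(h, t))
        t2, m2 = kn.sliding_peak_average(self._peaks(h[perm], t[perm]))
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(t1, t2)

    def test_fewer_peaks_than_window_warns_empty(self):
        with pytest.warns(UserWarning):
            times, means = kn.sliding_peak_average(self._peaks([1.0, 2.0]))
        assert times.size == 0


class TestOnsetAndRate:
    def test_simulated_onset_recovered(self):
        """30 s droplet-formation delay recovered within a sampling interval."""
        trace, truth = sim.simulate_kinetics_trace(17, onset_s=30.0, noise_sd=0.0)
        z = kn.als_baseline(trace)
        peaks = kn.detect_kinetic_peaks(trace, z)
        res = kn.onset_and_rate(peaks, kn.sliding_peak_average(peaks))
        assert res.lag_time_s == pytest.approx(30.0, abs=trace.dt + 1e-9)

    def test_immediate_onset(self):
        trace, _ = sim.simulate_kinetics_trace(18, onset_s=1.0, noise_sd=0.0)
        z = kn.als_baseline(trace)
        peaks = kn.detect_kinetic_peaks(trace, z)
        res = kn.onset_and_rate(peaks, kn.sliding_peak_average(peaks))
        assert res.lag_time_s == pytest.approx(1.0, abs=trace.dt + 1e-9)

    def test_linear_growth_rate_exact(self):
        """OLS on an exactly linear averaged series returns its slope."""
        t = np.linspace(0, 120, 40)
        means = 0.5 + (1.7 / 60.0) * t  # 1.7 FU/min
        peaks = PeakTable(t, means, means, np.zeros(40, dtype=bool), 0.01)
        res = kn.onset_and_rate(peaks, (t, means), fit_end=120.0)
        assert res.rate_fu_per_min == pytest.approx(1.7, rel=1e-9)

    def test_no_peaks_sentinel(self):
        empty = PeakTable(np.array([]), np.array([]), np.array([]),
                          np.array([], dtype=bool), 0.01)
        res = kn.onset_and_rate(empty, (np.array([]), np.array([])))
        assert res.no_peaks and np.isnan(res.lag_time_s) and res.rate_fu_per_min == 0.0

    def test_recovered_rate_close_on_simulation(self):
        trace, truth = sim.simulate_kinetics_trace(19, onset_s=10.0,
                                                   growth_rate_fu_per_min=1.0)
        z = kn.als_baseline(trace)
        peaks = kn.detect_kinetic_peaks(trace, z)
        res = kn.onset_and_rate(peaks, kn.sliding_peak_average(peaks),
                                fit_start=10.0, fit_end=130.0)
        assert res.rate_fu_per_min == pytest.approx(1.0, rel=0.15)
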