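"""Standard curve, dilute-phase baseline extraction, spike detection,
partitioning and reversibility."""
import numpy as np
import pytest

from capflex import baseline as bl
from capflex import simulate as sim
from capflex.types import (
    CalibrationError,
    InsufficientDataError,
    PeakTable,
    SyntheticGroundTruth,
    Trace,
    ValidationError,
)


def droplet_free_config(dilute, total=None, noise=0.0):
    gt = SyntheticGroundTruth(total_conc=total or dilute, dilute_conc=dilute,
                              droplet_count=0)
    return sim.SimulationConfig(ground_truth=gt, noise_sd=noise)


class TestStandardCurve:
    def test_exact_collinear_points(self):
        curve = bl.fit_standard_curve([10.0, 20.0, 50.0], [1.0, 2.0, 5.0])
        assert curve.slope == pytest.approx(0.1, rel=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.inverse(3.5) == pytest.approx(35.0)

    def test_single_concentration_underdetermined(self):
        with pytest.raises(CalibrationError):
            bl.fit_standard_curve([10.0, 10.0, 10.0], [1.0, 1.1, 0.9])

    def test_negative_slope_rejected(self):
        with pytest.raises(CalibrationError, match="slope"):
            bl.fit_standard_curve([10.0, 20.0, 50.0], [5.0, 2.0, 1.0])

    def test_noisy_standards_match_closed_form_ols(self, rng):
        """The fit equals the closed-form OLS solution, and the true slope
        falls inside its 95% confidence interval."""
        conc = np.array([5.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        true_slope = 0.05
        base = true_slope * conc + rng.normal(0, 0.01, conc.size)
        curve = bl.fit_standard_curve(conc, base)
        # independent closed form
        cx = conc - conc.mean()
        slope_hat = (cx * (base - base.mean())).sum() / (cx ** 2).sum()
        intercept_hat = base.mean() - slope_hat * conc.mean()
        assert curve.slope == pytest.approx(slope_hat, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept_hat, rel=1e-9, abs=1e-12)
        resid = base - curve.predict(conc)
        se = np.sqrt((resid ** 2).sum() / (conc.size - 2) / (cx ** 2).sum())
        assert abs(curve.slope - true_slope) < 2.78 * se  # t(4, 97.5%)


class TestExtractBaseline:
    def test_noise_free_exact_inversion(self, calibration):
        cfg = droplet_free_config(dilute=70.0, total=100.0)
        trace, _ = sim.simulate_trace(cfg, 1)
        res = bl.extract_baseline(trace, calibration, 100.0)
        assert res.baseline_fu == pytest.approx(3.5, abs=0.01)
        assert res.dilute_phase_conc == pytest.approx(70.0, abs=0.2)

    def test_spiked_noisy_trace_recovers_dilute_conc(self, calibration):
        """100 µM total, 70 µM dilute truth, 200 spikes, noise sd 0.05."""
        gt = SyntheticGroundTruth(total_conc=100.0, dilute_conc=70.0,
                                  droplet_count=200)
        cfg = sim.SimulationConfig(ground_truth=gt, noise_sd=0.05)
        trace, _ = sim.simulate_trace(cfg, 2)
        res = bl.extract_baseline(trace, calibration, 100.0)
        assert res.dilute_phase_conc == pytest.approx(70.0, abs=2.0)

    def test_non_phase_separated_trace_reads_total(self, calibration):
        cfg = droplet_free_config(dilute=100.0, noise=0.05)
        trace, _ = sim.simulate_trace(cfg, 3)
        res = bl.extract_baseline(trace, calibration, 100.0)
        assert res.dilute_phase_conc == pytest.approx(100.0, abs=2.0)

    def test_front_time_precedes_region(self, calibration):
        cfg = droplet_free_config(dilute=70.0, noise=0.02)
        trace, _ = sim.simulate_trace(cfg, 4)
        res = bl.extract_baseline(trace, calibration, 70.0)
        assert res.front_time <= res.baseline_region[0]
        assert res.sigmoid_params["upper"] > res.sigmoid_params["lower"]

    def test_too_few_surviving_samples(self, calibration):
        t = np.arange(0.0, 0.5, 0.01)
        y = 3.5 / (1 + np.exp(-40 * (t - 0.2)))
        with pytest.raises(InsufficientDataError):
            bl.extract_baseline(Trace(t, y), calibration, 70.0)

    def test_inverse_calibration_identity_over_grid(self, calibration):
        """Recovered dilute conc equals the simulated value for droplet-free
        traces across the concentration grid."""
        for conc in (5.0, 40.0, 70.0, 100.0):
            cfg = droplet_free_config(dilute=conc, total=100.0, noise=0.01)
            trace, _ = sim.simulate_trace(cfg, int(conc))
            res = bl.extract_baseline(trace, calibration, 100.0)
            assert res.dilute_phase_conc == pytest.approx(conc, abs=3 * 0.01 / 0.05)

    def test_baseline_insensitive_to_droplets(self, calibration):
        """Adding spikes moves the recovered dilute conc by < 1%."""
        gt0 = SyntheticGroundTruth(total_conc=100.0, dilute_conc=70.0, droplet_count=0)
        gt1 = SyntheticGroundTruth(total_conc=100.0, dilute_conc=70.0, droplet_count=250)
        r = []
        for gt in (gt0, gt1):
            cfg = sim.SimulationConfig(ground_truth=gt, noise_sd=0.02)
            trace, _ = sim.simulate_trace(cfg, 12)
            r.append(bl.extract_baseline(trace, calibration, 100.0).dilute_phase_conc)
        assert abs(r[1] - r[0]) / r[0] < 0.01


class TestDetectPeaks:
    def test_flat_trace_no_peaks(self, calibration):
        cfg = droplet_free_config(dilute=70.0)
        trace, _ = sim.simulate_trace(cfg, 5)
        res = bl.extract_baseline(trace, calibration, 70.0)
        assert bl.detect_peaks(trace, res).n == 0

    def test_threshold_is_absolute_point_two_fu(self, calibration):
        """0.3 FU above baseline → detected; 0.1 FU → not."""
        for amp, expected in ((0.3, 1), (0.1, 0)):
            cfg = sim.SimulationConfig(
                ground_truth=SyntheticGroundTruth(
                    total_conc=100.0, dilute_conc=70.0, droplet_count=1,
                    volume_mu=np.log(amp / 3.0), volume_sigma=1e-12),
                noise_sd=0.0)
            trace, _ = sim.simulate_trace(cfg, 6)
            res = bl.extract_baseline(trace, calibration, 100.0)
            assert bl.detect_peaks(trace, res, threshold=0.2).n == expected

    def test_count_exact_for_nonoverlapping_spikes(self, calibration):
        """150 supra-threshold non-overlapping spikes at noise sd 0.02 → 150."""
        gt = SyntheticGroundTruth(total_conc=100.0, dilute_conc=70.0,
                                  droplet_count=150, volume_mu=0.2,
                                  volume_sigma=0.3)
        cfg = sim.SimulationConfig(ground_truth=gt, noise_sd=0.02,
                                   non_overlapping=True)
        trace, events = sim.simulate_trace(cfg, 7)
        res = bl.extract_baseline(trace, calibration, 100.0)
        peaks = bl.detect_peaks(trace, res)
        assert peaks.n == len(events)

    def test_rectangular_spike_integral_exact(self, calibration):
        cfg = sim.SimulationConfig(
            ground_truth=SyntheticGroundTruth(
                total_conc=100.0, dilute_conc=70.0, droplet_count=1,
                volume_mu=np.log(2.0), volume_sigma=1e-12),
            noise_sd=0.0)
        trace, events = sim.simulate_trace(cfg, 8)
        res = bl.extract_baseline(trace, calibration, 100.0)
        peaks = bl.detect_peaks(trace, res)
        assert peaks.n == 1
        assert peaks.integrals[0] == pytest.approx(sim.spike_area(events[0], cfg),
                                                   rel=0.02)

    def test_saturated_flagging(self, calibration):
        cfg = sim.SimulationConfig(
            ground_truth=SyntheticGroundTruth(
                total_conc=100.0, dilute_conc=70.0, droplet_count=5,
                volume_mu=4.5, volume_sigma=1e-12),
            noise_sd=0.0, non_overlapping=True)
        trace, _ = sim.simulate_trace(cfg, 9)
        res = bl.extract_baseline(trace, calibration, 100.0)
        peaks = bl.detect_peaks(trace, res, saturation_ceiling=50.0)
        assert peaks.saturated.all()
        assert (peaks.heights > 0).all()


class TestPartitioningAndReversibility:
    def test_partitioned_amount(self):
        assert bl.partitioned_amount(100.0, 70.0) == pytest.approx(30.0)
        assert bl.partitioned_amount(100.0, 100.0) == 0.0

    def test_negative_partitioning_flagged_within_noise(self):
        amount = bl.partitioned_amount(50.0, 57.0)
        assert amount == pytest.approx(-7.0)
        assert bl.is_within_noise(amount, 7.0)
        assert not bl.is_within_noise(amount, 5.0)

    @staticmethod
    def _table(n):
        if n == 0:
            return PeakTable(np.array([]), np.array([]), np.array([]),
                             np.array([], dtype=bool), 0.2)
        return PeakTable(np.linspace(10, 20, n), np.ones(n), np.ones(n),
                         np.zeros(n, dtype=bool), 0.2)

    def test_full_dissolution_is_reversible(self):
        ok, summary = bl.reversibility_check(self._table(120), self._table(0))
        assert ok and summary["fraction_lost"] == 1.0

    def test_persisting_spikes_not_reversible(self):
        ok, _ = bl.reversibility_check(self._table(120), self._table(118))
        assert not ok

    def test_no_peaks_before_is_undefined(self):
        with pytest.raises(ValidationError):
            bl.reversibility_check(self._table(0), self._table(0))

    def test_monotone_in_min_fraction_lost(self):
        """Once a fraction threshold fails, all stricter ones fail too."""
        before, after = self._table(100), self._table(30)
        verdicts = [bl.reversibility_check(before, after, f)[0]
                    for f in np.linspace(0.05, 0.95, 19)]
        assert verdicts == sorted(verdicts, reverse=True)

    def test_recovered_conc_nonincreasing_in_partitioned_fraction(self, calibration):
        """More label in droplets ⇒ lower dilute-phase readout."""
        recovered = []
        for dilute in (100.0, 70.0, 40.0, 5.0):
            gt = SyntheticGroundTruth(total_conc=100.0, dilute_conc=dilute,
                                      droplet_count=100)
            cfg = sim.SimulationConfig(ground_truth=gt, noise_sd=0.05)
            trace, _ = sim.simulate_trace(cfg, 21)
            recovered.append(
                bl.extract_baseline(trace, calibration, 100.0).dilute_phase_conc)
        assert all(a > b for a, b in zip(recovered, recovered[1:]))
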