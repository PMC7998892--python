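"""Phase segmentation and the anchored-exponential release fit."""

import numpy as np
import pytest

from naagif.errors import InsufficientDataError, InvalidParameterError
from naagif.kinetics import (
    BandRatioTrace,
    fit_release,
    percent_change,
    release_model,
    segment_phases,
)
from naagif.spectrum import SpectralTimeSeries, Spectrum
from naagif.synthetic import generate_ratio_trace

WL = np.arange(430.0, 801.0, 1.0)


def flat_series(times, schedule):
    v = 0.2 + 0.3 * np.exp(-0.5 * ((WL - 480) / 12) ** 2) \
        + 0.25 * np.exp(-0.5 * ((WL - 700) / 15) ** 2)
    spectra = [Spectrum(WL, v, kind="intensity") for _ in times]
    return SpectralTimeSeries(np.asarray(times, float), spectra, schedule)


def release_labels(n):
    return np.full(n, "release", dtype=object)


def anchored_amplitude(r_max, r_start, span, tau):
    """Amplitude A of the end-anchored model whose curve starts at r_start:
    r_start = r_max + A*(1 - exp(span/tau))."""
    return (r_max - r_start) / (np.exp(span / tau) - 1.0)


class TestSegmentPhases:
    def test_standard_protocol(self):
        times = np.arange(-1800.0, 43200.0 + 1, 600.0)
        series = flat_series(times, [(-1800.0, None), (0.0, 7.4), (7200.0, 5.0)])
        labels = segment_phases(series)
        assert set(labels[times < 0]) == {"wetting"}
        assert set(labels[(times >= 0) & (times < 7200)]) == {"stabilization"}
        assert set(labels[times >= 7200]) == {"release"}

    def test_single_ph_means_no_release(self):
        times = np.arange(0.0, 3600.0, 300.0)
        series = flat_series(times, [(0.0, 7.4)])
        labels = segment_phases(series)
        assert set(labels) == {"stabilization"}

    def test_labels_partition_all_points(self):
        times = np.arange(-600.0, 3600.0, 150.0)
        series = flat_series(times, [(-600.0, None), (0.0, 7.4), (1800.0, 5.0)])
        labels = segment_phases(series)
        assert labels.size == times.size
        assert set(labels) <= {"wetting", "stabilization", "release"}

    def test_schedule_gap_rejected(self):
        times = np.arange(-600.0, 3600.0, 150.0)
        with pytest.raises(Exception):
            flat_series(times, [(0.0, 7.4)])  # schedule starts after the series


class TestFitRelease:
    def test_noise_free_round_trip(self):
        """Sampling the model and refitting recovers (A, t_release) to 0.1%."""
        times = np.arange(7200.0, 43200.0, 10.0)
        true_tau, r_max = 17289.0, 1.42
        true_a = anchored_amplitude(r_max, 1.07, times[-1] - times[0], true_tau)
        trace = generate_ratio_trace(r_max, times[-1], true_a, true_tau, times)
        fit = fit_release(trace)
        assert fit.t_release == pytest.approx(true_tau, rel=1e-3)
        assert fit.amplitude == pytest.approx(true_a, rel=1e-3)
        assert fit.r_max == pytest.approx(r_max, rel=1e-4)

    def test_fitted_curve_passes_through_anchor(self):
        times = np.arange(0.0, 36000.0, 10.0)
        a = anchored_amplitude(1.3, 1.0, times[-1], 13588.0)
        trace = generate_ratio_trace(1.3, times[-1], a, 13588.0, times)
        fit = fit_release(trace)
        assert fit.predict(fit.t_max) == pytest.approx(fit.r_max, abs=1e-12)

    def test_time_translation_invariance(self):
        times = np.arange(7200.0, 43200.0, 10.0)
        a = anchored_amplitude(1.42, 1.07, times[-1] - times[0], 17289.0)
        trace = generate_ratio_trace(1.42, times[-1], a, 17289.0, times)
        shifted = BandRatioTrace(trace.times + 5.0e4, trace.ratios,
                                 trace.phase_labels)
        a = fit_release(trace)
        b = fit_release(shifted)
        assert b.t_release == pytest.approx(a.t_release, rel=1e-9)
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-9)
        assert b.t_max == pytest.approx(a.t_max + 5.0e4)

    def test_flat_trace_flagged_degenerate(self):
        times = np.arange(0.0, 3600.0, 10.0)
        trace = BandRatioTrace(times, np.full(times.size, 1.3),
                               release_labels(times.size))
        fit = fit_release(trace)
        assert fit.degenerate

    def test_too_few_release_points(self):
        times = np.array([0.0, 10.0, 20.0])
        labels = np.array(["stabilization", "stabilization", "release"],
                          dtype=object)
        trace = BandRatioTrace(times, np.array([1.0, 1.0, 1.1]), labels)
        with pytest.raises(InsufficientDataError):
            fit_release(trace)

    def test_stabilization_points_are_excluded(self):
        """Adding stabilization points that sit on the model curve must not
        change the fitted parameters (they are not part of the fit)."""
        t_rel = np.arange(7200.0, 43200.0, 10.0)
        a = anchored_amplitude(1.42, 1.07, t_rel[-1] - t_rel[0], 17289.0)
        trace = generate_ratio_trace(1.42, t_rel[-1], a, 17289.0, t_rel)
        fit_a = fit_release(trace)
        t_stab = np.arange(0.0, 7200.0, 10.0)
        labels = np.concatenate([np.full(t_stab.size, "stabilization",
                                         dtype=object), trace.phase_labels])
        times = np.concatenate([t_stab, t_rel])
        # stabilization held flat at the first release value
        ratios = np.concatenate([np.full(t_stab.size, trace.ratios[0]),
                                 trace.ratios])
        fit_b = fit_release(BandRatioTrace(times, ratios, labels))
        assert fit_b.t_release == pytest.approx(fit_a.t_release, rel=1e-9)

    def test_noisy_recovery_median_within_5_percent(self):
        """1% ratio noise, 10 s sampling over 10 h: the median recovered
        characteristic time over seeded replicates stays within 5%."""
        times = np.arange(7200.0, 43200.0, 10.0)
        true_tau = 13588.0
        r_max = 1.42
        amp = anchored_amplitude(r_max, 1.07, times[-1] - times[0], true_tau)
        errors = []
        for seed in range(25):
            trace = generate_ratio_trace(r_max, times[-1], amp, true_tau,
                                         times, noise_sigma=0.01 * r_max,
                                         seed=seed)
            fit = fit_release(trace)
            errors.append(abs(fit.t_release / true_tau - 1))
        assert np.median(errors) < 0.05

    def test_recovery_across_release_time_range(self):
        """Median relative error < 5% for t_release spanning 5,000-50,000 s
        at 1% ratio noise."""
        times = np.arange(7200.0, 43200.0, 10.0)
        for true_tau in (5000.0, 20000.0, 50000.0):
            amp = anchored_amplitude(1.42, 0.92, times[-1] - times[0], true_tau)
            errors = []
            for seed in range(15):
                trace = generate_ratio_trace(1.42, times[-1], amp, true_tau,
                                             times, noise_sigma=0.0142,
                                             seed=100 + seed)
                fit = fit_release(trace)
                errors.append(abs(fit.t_release / true_tau - 1))
            assert np.median(errors) < 0.05, f"t_release = {true_tau}"


class TestPercentChange:
    @pytest.mark.parametrize("a,b,expected", [
        (13588.0, 17289.0, 27),
        (17289.0, 47038.0, 172),
        (5.0, 5.0, 0),
    ])
    def test_values(self, a, b, expected):
        assert percent_change(a, b) == expected

    def test_negative_change(self):
        assert percent_change(100.0, 50.0) == -50

    def test_nonpositive_base_rejected(self):
        with pytest.raises(InvalidParameterError):
            percent_change(0.0, 10.0)


class TestReleaseModel:
    def test_anchor_value(self):
        assert release_model(100.0, 1.3, 100.0, 0.5, 1000.0) == pytest.approx(1.3)

    def test_saturation_limit(self):
        val = release_model(1e9, 1.0, 0.0, 0.4, 1000.0)
        assert val == pytest.approx(1.4)
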