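"""Release-kinetics analysis of flow-cell spectral time series.

A flow-cell run has three phases: wetting (dry lead-in until the signal
stabilizes, t < 0), stabilization (neutral buffer, pH 7.4, no release) and
release (acidic buffer, pH 5.0, cargo leaves the pores). The observable is
the signal/reference band ratio R(t); during release it rises and is
fitted with the anchored exponential

    R(t) = R_max + A * (1 - exp(-(t - t_max) / t_release))

where (t_max, R_max) are fixed at the time and value of the maximum
measured ratio (not fitted) and the free parameters are the amplitude A
and the characteristic release time t_release. Only release-phase points
enter the fit; wetting and stabilization points are excluded.

Note on the anchoring: for a monotonically rising trace the measured
maximum is the last point, so t - t_max <= 0 over the whole fit range and
the exponential is evaluated at positive arguments. This is harmless: the
model family R(t) = C - B*exp(-t/tau) is closed under re-anchoring, so the
anchored form can represent any single-exponential saturation; the anchor
merely pins the curve to the measured maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .bands import BandDefinition, DEFAULT_BANDS, band_ratio
from .errors import FitError, InsufficientDataError, InvalidParameterError
from .spectrum import SpectralTimeSeries

__all__ = [
    "PHASES",
    "BandRatioTrace",
    "ReleaseFit",
    "segment_phases",
    "extract_ratio_trace",
    "fit_release",
    "release_model",
    "percent_change",
]

PHASES = ("wetting", "stabilization", "release")

#: Exponent clip bound: keeps exp() and the squared residual cost finite
#: even when the optimizer probes a tau far below the data's time span.
_EXP_CLIP = 100.0


def segment_phases(series: SpectralTimeSeries) -> np.ndarray:
    """Label every time point as wetting, stabilization or release.

    Times before t = 0 are wetting. From t = 0 on, the first scheduled pH
    defines the stabilization buffer; any later, more acidic pH marks the
    release phase. A schedule that never turns acidic yields no release
    points (degenerate but valid).
    """
    labels = np.empty(len(series), dtype=object)
    stab_ph = None
    for start, ph in series.ph_schedule:
        if start >= 0 and ph is not None:
            stab_ph = ph
            break
    if stab_ph is None:
        # schedule defined entirely by times; treat every t >= 0 pH as stabilization
        for _, ph in series.ph_schedule:
            if ph is not None:
                stab_ph = ph
                break
    for i, t in enumerate(series.times):
        if t < 0:
            labels[i] = "wetting"
            continue
        ph = series.ph_at(t)
        if ph is None or stab_ph is None or ph >= stab_ph:
            labels[i] = "stabilization"
        else:
            labels[i] = "release"
    return labels


@dataclass
class BandRatioTrace:
    """Time series of the signal/reference band ratio with phase labels."""

    times: np.ndarray
    ratios: np.ndarray
    phase_labels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.phase_labels = np.asarray(self.phase_labels, dtype=object)
        if not (self.times.shape == self.ratios.shape == self.phase_labels.shape):
            raise InvalidParameterError("times, ratios and labels must align")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.ratios <= 0):
            raise InvalidParameterError("band ratios must be positive")
        bad = set(self.phase_labels) - set(PHASES)
        if bad:
            raise InvalidParameterError(f"unknown phase labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.times.size

    def release_mask(self) -> np.ndarray:
        return self.phase_labels == "release"


def extract_ratio_trace(series: SpectralTimeSeries,
                        bands: BandDefinition = DEFAULT_BANDS,
                        *, smooth_width: int = 1) -> BandRatioTrace:
    """Apply the band-ratio metric to every spectrum of a time series.

    Vectorized over time (all spectra share one grid), but point-for-point
    identical to calling :func:`naagif.bands.band_ratio` per spectrum.
    """
    labels = segment_phases(series)
    wl = series.wavelengths
    values = np.stack([s.values for s in series.spectra])
    from .bands import _smooth
    values = _smooth(values, smooth_width)
    heights = {}
    for name, window in (("signal", bands.signal_window),
                         ("reference", bands.reference_window)):
        mask = (wl >= window[0]) & (wl <= window[1])
        if mask.sum() < 3:
            from .errors import RangeError
            raise RangeError(f"{name} window covers fewer than 3 grid points")
        heights[name] = values[:, mask].max(axis=1)
    if np.any(heights["reference"] == 0):
        from .errors import DegenerateSpectrumError
        raise DegenerateSpectrumError("reference-band maximum is zero")
    ratios = heights["signal"] / heights["reference"]
    return BandRatioTrace(series.times.copy(), ratios, labels)


def release_model(t, r_max: float, t_max: float, amplitude: float,
                  t_release: float) -> np.ndarray:
    """Anchored exponential R(t) = R_max + A*(1 - exp(-(t - t_max)/t_release))."""
    arg = np.clip(-(np.asarray(t, float) - t_max) / t_release, -_EXP_CLIP, _EXP_CLIP)
    return r_max + amplitude * (1.0 - np.exp(arg))


@dataclass
class ReleaseFit:
    """Result of the anchored-exponential fit.

    ``r_max`` and ``t_max`` are the measured maximum ratio and its time
    (fixed by construction, so the fitted curve passes exactly through
    that point); ``amplitude`` (A) and ``t_release`` are fitted.
    ``degenerate`` flags a flat trace for which t_release is
    unidentifiable.
    """

    r_max: float
    t_max: float
    amplitude: float
    t_release: float
    residual_sum: float
    n_points_fit: int
    degenerate: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if self.t_release <= 0:
            raise InvalidParameterError("t_release must be positive")
        if self.n_points_fit < 3:
            raise InvalidParameterError("a fit needs at least 3 points")

    def predict(self, t) -> np.ndarray:
        return release_model(t, self.r_max, self.t_max, self.amplitude,
                             self.t_release)


def _anchor_point(t: np.ndarray, y: np.ndarray, window) -> tuple:
    """(t_max, r_max): time and value of the maximum measured ratio.

    On noisy traces the raw sample maximum is an extreme-value statistic
    that sits several noise standard deviations above the underlying
    curve, so the maximum is read off a local-polynomial (Savitzky-Golay)
    smooth of the trace instead. The quadratic local fit is unbiased for
    smooth trends, including at the trace end, and reduces to the raw
    maximum exactly in the noise-free limit; ``window = 1`` disables
    smoothing, ``window = "auto"`` uses ~5% of the points.
    """
    if window == "auto":
        window = min(max(int(t.size // 20) | 1, 1), 301)
    window = int(window)
    if window > 1 and window % 2 == 0:
        raise InvalidParameterError("anchor smoothing window must be odd")
    if window >= 5 and window <= t.size:
        smooth = savgol_filter(y, window, polyorder=2, mode="interp")
    else:
        smooth = y
    i = int(np.argmax(smooth))
    if i >= t.size - window:
        # Saturating monotone trace: the maximum sits at the trace end.
        # Pin the anchor time there instead of letting noise select among
        # the near-equal final points (an extreme-value statistic whose
        # positive bias would propagate into t_release); the local
        # polynomial estimate at the fixed endpoint has symmetric noise.
        i = t.size - 1
    return float(t[i]), float(smooth[i])


def fit_release(trace: BandRatioTrace, *, anchor_smooth="auto",
                max_nfev: int = 2000) -> ReleaseFit:
    """Fit the anchored exponential to the release-phase points of a trace.

    The anchor (R_max, t_max) is the maximum measured ratio of the
    analyzed (release-phase) part of the trace and its time, read from a
    local-polynomial smooth so that noise spikes cannot become the anchor
    (see :func:`_anchor_point`); amplitude and t_release are then found by
    damped least squares with an analytic Jacobian, initialized at
    A0 = R_max - (first release ratio) and tau0 = one third of the
    release-phase time span. Both signs of A are permitted.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 release-phase points.
    FitError
        The optimizer failed to converge (the message carries the last
        iterate).
    """
    mask = trace.release_mask()
    n_fit = int(mask.sum())
    if n_fit < 3:
        raise InsufficientDataError(
            f"only {n_fit} release-phase points; need at least 3"
        )
    t = trace.times[mask]
    y = trace.ratios[mask]
    t_max, r_max = _anchor_point(t, y, anchor_smooth)
    span = float(t[-1] - t[0])
    if span <= 0:
        raise InsufficientDataError("release phase has zero time span")
    a0 = r_max - float(y[0])
    tau0 = span / 3.0

    degenerate = bool(np.ptp(y) <= 1e-12 * max(abs(r_max), 1.0))

    def residuals(p):
        a, tau = p
        return release_model(t, r_max, t_max, a, tau) - y

    def jacobian(p):
        a, tau = p
        arg = np.clip(-(t - t_max) / tau, -_EXP_CLIP, _EXP_CLIP)
        e = np.exp(arg)
        j = np.empty((t.size, 2))
        j[:, 0] = 1.0 - e
        j[:, 1] = -a * e * (t - t_max) / tau**2
        return j

    result = least_squares(
        residuals, x0=[a0, tau0], jac=jacobian,
        bounds=([-np.inf, 1e-9 * max(span, 1.0)], [np.inf, np.inf]),
        method="trf", max_nfev=max_nfev,
    )
    if not result.success:
        raise FitError(
            f"release fit did not converge: {result.message}; "
            f"last iterate A = {result.x[0]:.6g}, t_release = {result.x[1]:.6g} s"
        )
    a_fit, tau_fit = result.x
    if abs(a_fit) <= 1e-12 * max(abs(r_max), 1.0):
        degenerate = True
    return ReleaseFit(
        r_max=r_max,
        t_max=t_max,
        amplitude=float(a_fit),
        t_release=float(tau_fit),
        residual_sum=float(np.sum(result.fun**2)),
        n_points_fit=n_fit,
        degenerate=degenerate,
        message=str(result.message),
    )


def percent_change(t_a: float, t_b: float) -> int:
    """Percent change from t_a to t_b, rounded to the nearest integer.

    100 * (t_b - t_a) / t_a, half away from zero, as release-time
    increases are conventionally quoted.
    """
    if t_a <= 0:
        raise InvalidParameterError("t_a must be positive")
    raw = 100.0 * (t_b - t_a) / t_a
    return int(np.sign(raw) * np.floor(abs(raw) + 0.5))
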