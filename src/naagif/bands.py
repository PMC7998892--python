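"""Band observables: stopband maxima, signal/reference ratio, redshift.

The loading metric is the ratio of the signal-band maximum to the
reference-band maximum. The maximum is the raw extremum within a
wavelength window (no baseline subtraction, no lineshape fit), which makes
the ratio invariant under any overall intensity rescaling and therefore
equally valid for calibrated reflectance and raw flow-cell intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSpectrumError, InvalidParameterError, RangeError
from .spectrum import Spectrum

__all__ = [
    "BandDefinition",
    "BandReading",
    "locate_band_max",
    "band_ratio",
    "redshift",
    "DEFAULT_BANDS",
]


@dataclass(frozen=True)
class BandDefinition:
    """Wavelength windows (nm) bracketing the signal and reference stopbands."""

    signal_window: tuple = (430.0, 560.0)
    reference_window: tuple = (600.0, 800.0)

    def __post_init__(self) -> None:
        for name in ("signal_window", "reference_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidParameterError(f"{name} must satisfy lo < hi")
        s_lo, s_hi = self.signal_window
        r_lo, r_hi = self.reference_window
        if max(s_lo, r_lo) < min(s_hi, r_hi):
            raise InvalidParameterError("signal and reference windows overlap")


#: Windows bracketing the measured band positions of the fabricated filters
#: (signal 474-500 nm, reference 678-724 nm).
DEFAULT_BANDS = BandDefinition()


@dataclass(frozen=True)
class BandReading:
    """Peak wavelength and height of a stopband within its window."""

    peak_wavelength: float
    peak_height: float
    window: tuple


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered running mean along the last axis; width must be odd."""
    if width <= 1:
        return values
    if width % 2 == 0:
        raise InvalidParameterError("smooth_width must be odd")
    from scipy.ndimage import uniform_filter1d
    return uniform_filter1d(values, width, axis=-1, mode="nearest")


def locate_band_max(spectrum: Spectrum, window, *, smooth_width: int = 1) -> BandReading:
    """Find the maximum of a spectrum within a wavelength window.

    Ties break toward the shorter wavelength (argmax of an increasing grid
    returns the first occurrence). ``smooth_width`` > 1 applies a running
    mean of that many samples before peak-picking, for noisy flow-cell
    intensity data; the default is no smoothing.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise InvalidParameterError("window must satisfy lo < hi")
    wl = spectrum.wavelengths
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 3:
        raise RangeError(
            f"window ({lo}, {hi}) nm covers only {int(mask.sum())} grid points "
            f"of the {wl[0]:.0f}-{wl[-1]:.0f} nm grid; need at least 3"
        )
    values = _smooth(spectrum.values, smooth_width)[mask]
    i = int(np.argmax(values))
    return BandReading(float(wl[mask][i]), float(values[i]), (lo, hi))


def band_ratio(spectrum: Spectrum, bands: BandDefinition = DEFAULT_BANDS,
               *, smooth_width: int = 1) -> float:
    """Signal-band maximum divided by reference-band maximum."""
    sig = locate_band_max(spectrum, bands.signal_window, smooth_width=smooth_width)
    ref = locate_band_max(spectrum, bands.reference_window, smooth_width=smooth_width)
    if ref.peak_height == 0:
        raise DegenerateSpectrumError("reference-band maximum is zero")
    return sig.peak_height / ref.peak_height


def redshift(before: Spectrum, after: Spectrum, window) -> float:
    """Peak-wavelength shift (after - before) within a window, in nm.

    Positive when the band moves to longer wavelengths, e.g. when the
    pores fill with a medium of higher refractive index (wetting).
    """
    return (locate_band_max(after, window).peak_wavelength
            - locate_band_max(before, window).peak_wavelength)
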