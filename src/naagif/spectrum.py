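"""Wavelength-indexed spectra.

The package's central container is :class:`Spectrum`: a strictly increasing
wavelength grid (nm) with one value per wavelength, either calibrated
reflectance (dimensionless, in [0, 1]) or raw detector intensity (arbitrary
units). Band metrics operate on both kinds identically because the
signal/reference ratio cancels any overall intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, StructuralError

SPECTRUM_KINDS = ("reflectance", "intensity")

#: Tolerance for reflectance values marginally outside [0, 1] from round-off.
_REFLECTANCE_SLACK = 1e-9


@dataclass
class Spectrum:
    """A single spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelength grid in nm, strictly increasing.
    values : array of float
        Reflectance (in [0, 1]) or raw intensity, one per wavelength.
    kind : {"reflectance", "intensity"}
        How to interpret ``values``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise StructuralError("wavelengths must be a non-empty 1-D array")
        if self.values.shape != self.wavelengths.shape:
            raise StructuralError(
                f"values shape {self.values.shape} does not match "
                f"wavelengths shape {self.wavelengths.shape}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise StructuralError("wavelengths must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise InvalidParameterError(
                f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}"
            )
        if self.kind == "reflectance":
            lo = self.values.min()
            hi = self.values.max()
            if lo < -_REFLECTANCE_SLACK or hi > 1 + _REFLECTANCE_SLACK:
                raise InvalidParameterError(
                    f"reflectance values outside [0, 1]: min {lo:.3g}, max {hi:.3g}"
                )
            # round-off slack is tolerated but clipped away
            np.clip(self.values, 0.0, 1.0, out=self.values)

    def __len__(self) -> int:
        return self.wavelengths.size

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy scaled by a positive factor (result is intensity-kind)."""
        if factor <= 0:
            raise InvalidParameterError("scale factor must be positive")
        return Spectrum(self.wavelengths.copy(), self.values * factor, kind="intensity")


def default_wavelength_grid(start: float = 400.0, stop: float = 900.0,
                            step: float = 1.0) -> np.ndarray:
    """Default simulation grid: 400-900 nm in 1 nm steps, endpoints included."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass
class SpectralTimeSeries:
    """A time-stamped sequence of spectra with an attached pH schedule.

    Times are in seconds with t = 0 at the instant the signal stabilizes
    after wetting; negative times are the (dry or wetting) lead-in. The pH
    schedule is an ordered list of ``(start_time_s, pH)`` pairs (pH ``None``
    marks the dry lead-in) that must cover the full time range.
    """

    times: np.ndarray
    spectra: list = field(default_factory=list)
    ph_schedule: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise StructuralError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise StructuralError("times must be strictly increasing")
        if len(self.spectra) != self.times.size:
            raise StructuralError(
                f"{len(self.spectra)} spectra for {self.times.size} time points"
            )
        grid = self.spectra[0].wavelengths
        for i, s in enumerate(self.spectra[1:], start=1):
            if s.wavelengths.shape != grid.shape or not np.array_equal(s.wavelengths, grid):
                raise StructuralError(f"spectrum {i} is on a different wavelength grid")
        if not self.ph_schedule:
            raise StructuralError("ph_schedule must not be empty")
        starts = [float(t) for t, _ in self.ph_schedule]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise StructuralError("ph_schedule start times must be strictly increasing")
        if starts[0] > self.times[0]:
            raise StructuralError(
                f"ph_schedule starts at t = {starts[0]} s but the series "
                f"starts at t = {self.times[0]} s (schedule gap)"
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def ph_at(self, t: float):
        """pH in effect at time t (step function; None during the dry lead-in)."""
        current = self.ph_schedule[0][1]
        for start, ph in self.ph_schedule:
            if t >= start:
                current = ph
            else:
                break
        return current
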