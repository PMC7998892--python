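"""Layered-structure builder for stacked rugate filters in nanoporous anodic alumina.

A gradient-index filter (GIF) is grown by sinusoidal-current anodization: a
constant current density plus a sinusoidal term of period T1 for N cycles,
then period T2 for N cycles. The pore-diameter modulation that results is
treated, to first order, as a sinusoidal modulation of the alumina host
volume fraction with depth, with one spatial period per stack (Lambda_top,
Lambda_bottom). This module generates the applied current waveform and
discretizes the two-stack composition profile into uniform layers that the
optics modules consume.

Conventions
-----------
* Layers are ordered incidence-side first (top rugate, bottom rugate,
  barrier layer last).
* Each rugate stack starts its sinusoid at phase 0 (sin = 0, rising); the
  composition of each sub-layer is sampled at the sub-layer midpoint
  (second-order accurate for smooth profiles).
* The compact barrier layer at the pore bottoms is modeled as pure host
  oxide; an optional surface film of pure cargo material can be prepended.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "AnodizationProfile",
    "GifDesign",
    "Layer",
    "CompositionProfile",
    "generate_current_waveform",
    "build_composition_profile",
]

_CLOSURE_TOL = 1e-12


@dataclass(frozen=True)
class AnodizationProfile:
    """Sinusoidal anodization current programme.

    j(t) = j_average + j_amplitude * sin(2*pi*t/T1) for the first N*T1
    seconds, then the same with period T2 for another N*T2 seconds. The
    current must never go negative, hence j_amplitude <= j_average.

    Units: current densities in mA/cm^2, periods in s.
    """

    j_average: float
    j_amplitude: float
    period_1: float
    period_2: float
    n_cycles: int

    def __post_init__(self) -> None:
        if self.j_average <= 0:
            raise InvalidParameterError("j_average must be positive")
        if not 0 <= self.j_amplitude <= self.j_average:
            raise InvalidParameterError(
                "j_amplitude must lie in [0, j_average] so the current stays non-negative"
            )
        if self.period_1 <= 0 or self.period_2 <= 0:
            raise InvalidParameterError("periods must be positive")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be at least 1")

    @property
    def total_duration(self) -> float:
        """N*T1 + N*T2, in seconds."""
        return self.n_cycles * (self.period_1 + self.period_2)


@dataclass(frozen=True)
class GifDesign:
    """Structural and physical parameterization of a two-stack NAA-GIF.

    Attributes
    ----------
    period_top, period_bottom : float
        Spatial modulation periods Lambda of the top and bottom rugate
        stacks, nm.
    n_periods_top, n_periods_bottom : int
        Number of modulation periods per stack.
    layers_per_period : int
        Discretization of each period into uniform sub-layers (>= 2).
    f_host_avg : float
        Mean alumina host volume fraction (1 - average porosity).
    f_ampl : float
        Amplitude of the sinusoidal host-fraction modulation.
    f_drug : float
        Cargo-molecule volume fraction, constant with depth (conformal
        layer on the pore walls).
    barrier_thickness : float
        Thickness of the compact pure-oxide barrier layer at the pore
        bottoms, nm (0 = none).
    surface_layer_thickness : float
        Thickness of an optional continuous cargo film on the top
        surface, nm (0 = none).
    medium_index : float
        Refractive index of the medium filling the pores and surrounding
        the structure (1.33 for water, 1.0 for air).
    """

    period_top: float = 164.0
    period_bottom: float = 284.0
    n_periods_top: int = 100
    n_periods_bottom: int = 100
    layers_per_period: int = 8
    f_host_avg: float = 0.9
    f_ampl: float = 0.025
    f_drug: float = 0.0
    barrier_thickness: float = 40.0
    surface_layer_thickness: float = 0.0
    medium_index: float = 1.33

    def __post_init__(self) -> None:
        if self.period_top <= 0 or self.period_bottom <= 0:
            raise InvalidParameterError("rugate periods must be positive")
        if self.n_periods_top < 1 or self.n_periods_bottom < 1:
            raise InvalidParameterError("each stack needs at least one period")
        if self.layers_per_period < 2:
            raise InvalidParameterError("layers_per_period must be >= 2")
        for name in ("f_host_avg", "f_ampl", "f_drug"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.f_host_avg + self.f_ampl + self.f_drug > 1 + _CLOSURE_TOL:
            raise InvalidParameterError(
                "f_host_avg + f_ampl + f_drug exceeds 1: the medium fraction "
                "would be negative at the modulation peak"
            )
        if self.barrier_thickness < 0 or self.surface_layer_thickness < 0:
            raise InvalidParameterError("layer thicknesses must be non-negative")
        if self.medium_index < 1:
            raise InvalidParameterError("medium_index must be >= 1")

    def with_drug_fraction(self, f_drug: float) -> "GifDesign":
        return replace(self, f_drug=f_drug)

    def with_medium_index(self, medium_index: float) -> "GifDesign":
        return replace(self, medium_index=medium_index)


LAYER_TAGS = ("surface", "rugate_top", "rugate_bottom", "barrier")


@dataclass(frozen=True)
class Layer:
    """One uniform layer: thickness (nm) and volume fractions closing to 1."""

    thickness: float
    f_host: float
    f_drug: float
    f_medium: float
    tag: str

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidParameterError("layer thickness must be positive")
        for name in ("f_host", "f_drug", "f_medium"):
            v = getattr(self, name)
            if not -_CLOSURE_TOL <= v <= 1 + _CLOSURE_TOL:
                raise InvalidParameterError(
                    f"{name} = {v} outside [0, 1] in {self.tag} layer"
                )
        total = self.f_host + self.f_drug + self.f_medium
        if abs(total - 1.0) > _CLOSURE_TOL:
            raise InvalidParameterError(
                f"fractions sum to {total}, not 1, in {self.tag} layer"
            )
        if self.tag not in LAYER_TAGS:
            raise InvalidParameterError(f"unknown layer tag {self.tag!r}")


@dataclass
class CompositionProfile:
    """Ordered stack of uniform layers, incidence side first."""

    layers: list

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self) -> Iterator[Layer]:
        return iter(self.layers)

    @property
    def total_thickness(self) -> float:
        return float(sum(layer.thickness for layer in self.layers))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer_index": np.arange(len(self.layers)),
                "tag": [l.tag for l in self.layers],
                "thickness_nm": [l.thickness for l in self.layers],
                "f_host": [l.f_host for l in self.layers],
                "f_drug": [l.f_drug for l in self.layers],
                "f_medium": [l.f_medium for l in self.layers],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def generate_current_waveform(profile: AnodizationProfile, time_step: float):
    """Sample the two-phase sinusoidal anodization current.

    Returns ``(times, current)`` with samples at t = k * time_step from 0 to
    the total duration N*(T1 + T2) inclusive. During the first phase
    (0 <= t <= N*T1) the period is T1; afterwards the sinusoid restarts at
    phase 0 with period T2, measured from the phase boundary.

    Parameters
    ----------
    profile : AnodizationProfile
    time_step : float
        Sampling interval in s; must be positive and at most
        min(T1, T2)/4 to resolve the oscillation.
    """
    if time_step <= 0:
        raise InvalidParameterError("time_step must be positive")
    if time_step > min(profile.period_1, profile.period_2) / 4:
        raise InvalidParameterError(
            "time_step must not exceed a quarter of the shorter period"
        )
    total = profile.total_duration
    n_steps = int(np.floor(total / time_step + 1e-9))
    times = time_step * np.arange(n_steps + 1)
    if times[-1] < total - 1e-9 * total:
        times = np.append(times, total)
    t_switch = profile.n_cycles * profile.period_1
    phase1 = times <= t_switch
    current = np.empty_like(times)
    current[phase1] = profile.j_average + profile.j_amplitude * np.sin(
        2 * np.pi * times[phase1] / profile.period_1
    )
    current[~phase1] = profile.j_average + profile.j_amplitude * np.sin(
        2 * np.pi * (times[~phase1] - t_switch) / profile.period_2
    )
    return times, current


def _rugate_layers(period: float, n_periods: int, layers_per_period: int,
                   f_host_avg: float, f_ampl: float, f_drug: float,
                   tag: str) -> list:
    """Discretize one rugate stack into uniform sub-layers.

    The host fraction is sampled at sub-layer midpoints of
    f_host(z) = f_host_avg + f_ampl * sin(2*pi*z/Lambda), with z = 0 at the
    top of the stack. The sinusoid pattern repeats every period, so only
    ``layers_per_period`` distinct compositions occur per stack.
    """
    d = period / layers_per_period
    midpoints = (np.arange(layers_per_period) + 0.5) / layers_per_period
    f_host_period = f_host_avg + f_ampl * np.sin(2 * np.pi * midpoints)
    layers = []
    for k in range(n_periods * layers_per_period):
        f_host = float(f_host_period[k % layers_per_period])
        f_medium = 1.0 - f_host - f_drug
        if not 0 <= f_host <= 1 or f_medium < -_CLOSURE_TOL:
            raise InvalidParameterError(
                f"composition leaves [0, 1] at {tag} layer {k}: "
                f"f_host = {f_host:.6f}, f_medium = {f_medium:.6f}"
            )
        layers.append(Layer(d, f_host, f_drug, max(f_medium, 0.0), tag))
    return layers


def build_composition_profile(design: GifDesign) -> CompositionProfile:
    """Build the full discretized layer stack for a GIF design.

    Layer order (incidence side first): optional pure-cargo surface film,
    top rugate stack, bottom rugate stack, pure-oxide barrier layer. Both
    rugate stacks start their host-fraction sinusoid at phase 0 and carry a
    constant cargo fraction ``f_drug``; the medium fraction closes each
    layer's composition to 1.
    """
    layers: list = []
    if design.surface_layer_thickness > 0:
        layers.append(
            Layer(design.surface_layer_thickness, 0.0, 1.0, 0.0, "surface")
        )
    layers += _rugate_layers(
        design.period_top, design.n_periods_top, design.layers_per_period,
        design.f_host_avg, design.f_ampl, design.f_drug, "rugate_top",
    )
    layers += _rugate_layers(
        design.period_bottom, design.n_periods_bottom, design.layers_per_period,
        design.f_host_avg, design.f_ampl, design.f_drug, "rugate_bottom",
    )
    if design.barrier_thickness > 0:
        layers.append(Layer(design.barrier_thickness, 1.0, 0.0, 0.0, "barrier"))
    return CompositionProfile(layers)
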