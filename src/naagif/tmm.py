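"""Transfer-matrix optics for stratified media and the GIF forward model.

The characteristic-matrix (Abeles) formulation: each uniform layer of
thickness d and complex index n contributes a 2x2 matrix

    M = [[cos(delta),            i sin(delta)/eta],
         [i eta sin(delta),      cos(delta)     ]]

with phase thickness delta = (2*pi/lambda) n d cos(theta) and tilted
optical admittance eta (n cos(theta) for s-polarization, n/cos(theta) for
p). The product over layers, closed by the incident and exit admittances,
yields the amplitude reflection coefficient and hence R = |r|^2 and, for
completeness, the transmittance T. The complex refraction angle follows
Snell's law with the branch chosen so that Im(n cos(theta)) >= 0 (decaying
evanescent waves).

`simulate_gif_spectrum` composes the full forward model: discretized
composition profile -> Bruggeman effective index per layer -> reflectance.
The structure is free-standing in the release medium (same incident and
exit medium, no substrate), so the spectrum shows the two rugate stopbands
against a low background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, StructuralError
from .materials import MaterialSet, Material, bruggeman_mix, _sqrt_passive
from .spectrum import Spectrum, default_wavelength_grid
from .structure import CompositionProfile, GifDesign, build_composition_profile

__all__ = [
    "OpticalStack",
    "compute_reflectance",
    "compute_reflectance_transmittance",
    "simulate_gif_spectrum",
    "stack_from_profile",
    "bragg_wavelengths",
]

POLARIZATIONS = ("s", "p", "unpolarized")


@dataclass
class OpticalStack:
    """Layer thicknesses and complex indices aligned on one wavelength grid.

    ``thicknesses`` has shape (n_layers,); ``indices`` has shape
    (n_layers, n_wavelengths). The incident and exit media are
    semi-infinite.
    """

    wavelengths: np.ndarray
    thicknesses: np.ndarray
    indices: np.ndarray
    incident_index: np.ndarray
    exit_index: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.thicknesses = np.asarray(self.thicknesses, dtype=float)
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=complex))
        n_wl = self.wavelengths.size
        if self.wavelengths.ndim != 1 or n_wl == 0:
            raise StructuralError("wavelengths must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise StructuralError("wavelengths must be strictly increasing")
        if self.thicknesses.size == 0:
            self.indices = np.empty((0, n_wl), dtype=complex)
        if self.indices.shape != (self.thicknesses.size, n_wl):
            raise StructuralError(
                f"indices shape {self.indices.shape} does not match "
                f"({self.thicknesses.size} layers, {n_wl} wavelengths)"
            )
        if np.any(self.thicknesses <= 0):
            raise InvalidParameterError("layer thicknesses must be positive")
        self.incident_index = np.broadcast_to(
            np.asarray(self.incident_index, dtype=complex), (n_wl,)
        ).copy()
        self.exit_index = np.broadcast_to(
            np.asarray(self.exit_index, dtype=complex), (n_wl,)
        ).copy()
        if np.any(self.indices.imag < -1e-12):
            raise InvalidParameterError("layer indices must have Im(n) >= 0")

    @property
    def n_layers(self) -> int:
        return self.thicknesses.size

    def reversed(self) -> "OpticalStack":
        """Stack traversed from the exit side (media swapped)."""
        return OpticalStack(
            self.wavelengths,
            self.thicknesses[::-1].copy(),
            self.indices[::-1].copy(),
            self.exit_index.copy(),
            self.incident_index.copy(),
        )


def _cos_theta(n: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """cos(theta) in a medium of index n for transverse invariant
    alpha = n0 sin(theta0), branch with Im(n cos(theta)) >= 0."""
    c = np.sqrt(1.0 - (alpha / n) ** 2 + 0j)
    nc = n * c
    flip = (nc.imag < -1e-15) | ((np.abs(nc.imag) <= 1e-15) & (nc.real < 0))
    return np.where(flip, -c, c)


def _rt_one_pol(stack: OpticalStack, alpha: np.ndarray, pol: str):
    wl = stack.wavelengths
    n0, ns = stack.incident_index, stack.exit_index
    c0 = _cos_theta(n0, alpha)
    cs = _cos_theta(ns, alpha)
    if pol == "s":
        eta0, etas = n0 * c0, ns * cs
    else:
        eta0, etas = n0 / c0, ns / cs

    # accumulate [B; C] = M_1 ... M_L [1; eta_exit]
    B = np.ones_like(wl, dtype=complex)
    C = etas.astype(complex).copy()
    two_pi = 2.0 * np.pi
    for ell in range(stack.n_layers - 1, -1, -1):
        n = stack.indices[ell]
        c = _cos_theta(n, alpha)
        delta = two_pi / wl * n * c * stack.thicknesses[ell]
        eta = n * c if pol == "s" else n / c
        cosd = np.cos(delta)
        sind = np.sin(delta)
        # off-diagonal signs follow the n + ik, exp(-i*omega*t) convention
        B, C = cosd * B - 1j * sind / eta * C, -1j * eta * sind * B + cosd * C

    denom = eta0 * B + C
    r = (eta0 * B - C) / denom
    R = np.abs(r) ** 2
    T = 4.0 * eta0.real * etas.real / np.abs(denom) ** 2
    return R, T


def compute_reflectance_transmittance(stack: OpticalStack,
                                      angle_of_incidence: float = 0.0,
                                      polarization: str = "unpolarized"):
    """Reflectance and transmittance arrays on the stack's wavelength grid."""
    if not 0 <= angle_of_incidence < 90:
        raise InvalidParameterError("angle of incidence must be in [0, 90) degrees")
    if polarization not in POLARIZATIONS:
        raise InvalidParameterError(
            f"polarization must be one of {POLARIZATIONS}, got {polarization!r}"
        )
    theta0 = np.deg2rad(angle_of_incidence)
    alpha = stack.incident_index * np.sin(theta0)
    if polarization == "unpolarized":
        Rs, Ts = _rt_one_pol(stack, alpha, "s")
        Rp, Tp = _rt_one_pol(stack, alpha, "p")
        R, T = 0.5 * (Rs + Rp), 0.5 * (Ts + Tp)
    else:
        R, T = _rt_one_pol(stack, alpha, polarization)
    return R, T


def compute_reflectance(stack: OpticalStack, angle_of_incidence: float = 0.0,
                        polarization: str = "unpolarized") -> Spectrum:
    """Reflectance spectrum of a layered stack.

    Unpolarized light is the mean of the s and p reflectances. The result
    is clipped to [0, 1]; violations beyond 1e-9 raise, as they indicate a
    broken stack rather than round-off.
    """
    R, _ = compute_reflectance_transmittance(stack, angle_of_incidence, polarization)
    if R.min() < -1e-9 or R.max() > 1 + 1e-9:
        raise InvalidParameterError(
            f"reflectance outside [0, 1]: min {R.min():.3g}, max {R.max():.3g}"
        )
    return Spectrum(stack.wavelengths.copy(), np.clip(R, 0.0, 1.0), kind="reflectance")


def _medium_index(design: GifDesign, materials: MaterialSet,
                  wavelengths: np.ndarray) -> np.ndarray:
    if materials.medium is not None:
        return materials.medium.index(wavelengths)
    return np.full(wavelengths.shape, complex(design.medium_index))


def stack_from_profile(profile: CompositionProfile, design: GifDesign,
                       materials: MaterialSet,
                       wavelengths: np.ndarray) -> OpticalStack:
    """Mix every layer of a composition profile into an optical stack.

    Each layer's effective permittivity comes from the Bruggeman rule
    applied to (host, drug, medium); layers sharing a composition are
    mixed once (a rugate stack has only ``layers_per_period`` distinct
    compositions, so this dominates nothing).
    """
    wl = np.asarray(wavelengths, dtype=float)
    eps_host = materials.host.permittivity(wl)
    eps_drug = materials.drug.permittivity(wl)
    eps_medium = _medium_index(design, materials, wl) ** 2

    cache: dict = {}
    thicknesses = np.empty(len(profile))
    indices = np.empty((len(profile), wl.size), dtype=complex)
    for i, layer in enumerate(profile):
        thicknesses[i] = layer.thickness
        key = (round(layer.f_host, 12), round(layer.f_drug, 12),
               round(layer.f_medium, 12))
        if key not in cache:
            if layer.f_host == 1.0:
                n_eff = _sqrt_passive(eps_host)
            elif layer.f_drug == 1.0:
                n_eff = _sqrt_passive(eps_drug)
            else:
                eps_eff = bruggeman_mix(
                    [layer.f_host, layer.f_drug, layer.f_medium],
                    [eps_host, eps_drug, eps_medium],
                )
                n_eff = _sqrt_passive(np.asarray(eps_eff, dtype=complex))
            cache[key] = n_eff
        indices[i] = cache[key]

    n_medium = _medium_index(design, materials, wl)
    return OpticalStack(wl, thicknesses, indices, n_medium, n_medium)


def simulate_gif_spectrum(design: GifDesign, materials: MaterialSet,
                          wavelengths=None, angle: float = 0.0,
                          polarization: str = "unpolarized") -> Spectrum:
    """Forward-model the reflectance spectrum of a two-stack NAA-GIF.

    Builds the discretized composition profile, converts each layer to an
    effective complex index, and runs the transfer-matrix computation with
    the release medium on both sides (free-standing membrane, no
    substrate). The spectrum exhibits one stopband per rugate stack, near
    the Bragg wavelengths 2 * n_eff * Lambda.
    """
    wl = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths, float)
    profile = build_composition_profile(design)
    stack = stack_from_profile(profile, design, materials, wl)
    return compute_reflectance(stack, angle, polarization)


def bragg_wavelengths(design: GifDesign, materials: MaterialSet,
                      n_iter: int = 8) -> tuple:
    """First-order Bragg positions (2 n_eff Lambda) of the two stopbands.

    n_eff is the Bruggeman index of the period-average composition,
    evaluated self-consistently at the Bragg wavelength itself (fixed-point
    iteration, since the host is dispersive). Used as an independent
    sanity oracle for the band positions of the full simulation.
    """
    fractions = [design.f_host_avg, design.f_drug,
                 1.0 - design.f_host_avg - design.f_drug]
    out = []
    for period in (design.period_top, design.period_bottom):
        lam = 2.0 * 1.6 * period  # rough seed
        for _ in range(n_iter):
            grid = np.array([lam * 0.999, lam, lam * 1.001])
            eps = [materials.host.permittivity(grid)[1],
                   materials.drug.permittivity(grid)[1],
                   _medium_index(design, materials, grid)[1] ** 2]
            n_eff = _sqrt_passive(np.asarray(bruggeman_mix(fractions, eps))).real
            lam = 2.0 * float(n_eff) * period
        out.append(lam)
    return tuple(out)
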