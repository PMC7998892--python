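"""Optical material models and effective-medium mixing.

Three material classes cover the composite: the alumina host (real, weakly
dispersive Cauchy law), the aqueous or gaseous pore medium (constant index),
and the cargo molecule (Lorentz oscillator with an absorption band placed
inside the signal stopband). The porous composite's effective permittivity
is obtained with the Bruggeman effective-medium approximation, solved as a
polynomial root problem with a physical-admissibility filter.

Sign conventions follow the exp(-i*omega*t) time convention: passive
materials have Im(epsilon) >= 0 and Im(n) = k >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import (
    InvalidParameterError,
    NumericalFailureError,
    RangeError,
    StructuralError,
)

__all__ = [
    "LorentzOscillatorParams",
    "MaterialTable",
    "Material",
    "lorentz_index",
    "alumina_index",
    "bruggeman_mix",
    "default_materials",
    "MaterialSet",
    "DEFAULT_DRUG_PARAMS",
    "ALUMINA_CAUCHY_A",
    "ALUMINA_CAUCHY_B",
]

# Cauchy coefficients n(lambda) = A + B/lambda^2 for anodic alumina:
# ~1.67 at 400 nm falling to ~1.61 at 900 nm, around the handbook value
# of ~1.66 for the compact oxide in the mid-visible.
ALUMINA_CAUCHY_A = 1.59
ALUMINA_CAUCHY_B = 1.4e4  # nm^2

_ALUMINA_RANGE = (300.0, 1000.0)


@dataclass(frozen=True)
class LorentzOscillatorParams:
    """Single-oscillator Lorentz model for an absorbing molecule.

    epsilon(omega) = eps_inf + strength * omega0^2 /
                     (omega0^2 - omega^2 - i*gamma*omega)

    with omega0 = 2*pi*c / resonance_wavelength. The damping is specified
    as a wavelength-equivalent linewidth (nm): gamma = omega0 * damping /
    resonance_wavelength, which makes the absorption band's full width in
    wavelength approximately equal to ``damping``.

    Attributes
    ----------
    eps_inf : float
        High-frequency (background) permittivity, >= 1.
    resonance_wavelength : float
        Resonance position lambda0 in nm.
    strength : float
        Dimensionless oscillator strength (0 disables absorption).
    damping : float
        Linewidth in nm (same length units as the resonance), > 0.
    """

    eps_inf: float = 1.96
    resonance_wavelength: float = 530.0
    strength: float = 0.05
    damping: float = 90.0

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise InvalidParameterError("eps_inf must be >= 1")
        if self.resonance_wavelength <= 0:
            raise InvalidParameterError("resonance_wavelength must be positive")
        if self.strength < 0:
            raise InvalidParameterError("strength must be non-negative")
        if self.damping <= 0:
            raise InvalidParameterError("damping must be positive")

    def permittivity(self, wavelengths) -> np.ndarray:
        """Complex relative permittivity on a wavelength grid (nm)."""
        wl = _check_grid(wavelengths)
        # omega/omega0 = lambda0/lambda; gamma/omega0 = damping/lambda0
        x = self.resonance_wavelength / wl
        g = self.damping / self.resonance_wavelength
        eps = self.eps_inf + self.strength / (1.0 - x * x - 1j * g * x)
        return eps


#: Default cargo-molecule model: absorption band centred in the signal
#: stopband (530 nm), background index sqrt(1.96) = 1.4 typical of an
#: organic dye film, linewidth ~90 nm.
DEFAULT_DRUG_PARAMS = LorentzOscillatorParams()


@dataclass
class MaterialTable:
    """Complex refractive index sampled on a wavelength grid."""

    wavelengths: np.ndarray
    index: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths)
        self.index = np.asarray(self.index, dtype=complex)
        if self.index.shape != self.wavelengths.shape:
            raise StructuralError("index and wavelengths shapes differ")
        if np.any(self.index.imag < -1e-12):
            raise InvalidParameterError(
                f"negative extinction coefficient in material {self.label!r}"
            )

    @property
    def n(self) -> np.ndarray:
        return self.index.real

    @property
    def k(self) -> np.ndarray:
        return self.index.imag


def _check_grid(wavelengths) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise InvalidParameterError("wavelength grid must be a non-empty 1-D array")
    if np.any(np.diff(wl) <= 0):
        raise InvalidParameterError("wavelength grid must be strictly increasing")
    if np.any(wl <= 0):
        raise InvalidParameterError("wavelengths must be positive")
    return wl


def _sqrt_passive(eps: np.ndarray) -> np.ndarray:
    """Principal square root with non-negative imaginary part (passive medium)."""
    n = np.sqrt(eps.astype(complex))
    flip = n.imag < 0
    return np.where(flip, -n, n)


def lorentz_index(params: LorentzOscillatorParams, wavelengths) -> MaterialTable:
    """Complex refractive index of a Lorentz-oscillator material.

    The extinction coefficient k peaks within a few nm of the resonance
    wavelength for moderate damping; far above the resonance the
    permittivity approaches the static limit eps_inf + strength.
    """
    wl = _check_grid(wavelengths)
    index = _sqrt_passive(params.permittivity(wl))
    return MaterialTable(wl, index, label="lorentz")


def alumina_index(wavelengths, *, constant: float | None = None) -> MaterialTable:
    """Refractive index of the anodic alumina host (lossless in the visible).

    By default a two-term Cauchy law n = A + B/lambda^2 with coefficients
    tuned to anodic alumina; pass ``constant`` to override with a fixed
    index (e.g. 1.66). Supported grid: 300-1000 nm.
    """
    wl = _check_grid(wavelengths)
    if wl[0] < _ALUMINA_RANGE[0] or wl[-1] > _ALUMINA_RANGE[1]:
        raise RangeError(
            f"alumina dispersion is only supported on "
            f"{_ALUMINA_RANGE[0]:.0f}-{_ALUMINA_RANGE[1]:.0f} nm"
        )
    if constant is not None:
        n = np.full_like(wl, float(constant))
    else:
        n = ALUMINA_CAUCHY_A + ALUMINA_CAUCHY_B / wl**2
    return MaterialTable(wl, n.astype(complex), label="alumina")


# ---------------------------------------------------------------------------
# Bruggeman effective-medium mixing
# ---------------------------------------------------------------------------

_FRACTION_TOL = 1e-9
_RESIDUAL_TOL = 1e-10


def _bruggeman_poly(fractions: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Coefficients (ascending in x) of the polynomial form of the
    Bruggeman equation sum_i f_i (eps_i - x) prod_{j!=i} (eps_j + 2x) = 0.

    ``eps`` has shape (..., n); the result has shape (..., n+1).
    """
    n = eps.shape[-1]
    shape = eps.shape[:-1]
    coeffs = np.zeros(shape + (n + 1,), dtype=complex)
    for i in range(n):
        # start with f_i * (eps_i - x): ascending [f_i*eps_i, -f_i]
        term = np.zeros(shape + (n + 1,), dtype=complex)
        term[..., 0] = fractions[i] * eps[..., i]
        term[..., 1] = -fractions[i]
        deg = 1
        for j in range(n):
            if j == i:
                continue
            # multiply by (eps_j + 2x)
            new = np.zeros_like(term)
            new[..., : deg + 1] += term[..., : deg + 1] * eps[..., j][..., None]
            new[..., 1 : deg + 2] += 2.0 * term[..., : deg + 1]
            term = new
            deg += 1
        coeffs += term
    return coeffs


def _roots_batched(coeffs: np.ndarray) -> np.ndarray:
    """Roots of polynomials with ascending coefficients, batched over
    leading axes, via companion-matrix eigenvalues."""
    n = coeffs.shape[-1] - 1
    lead = coeffs[..., -1]
    monic = coeffs[..., :-1] / lead[..., None]
    comp = np.zeros(coeffs.shape[:-1] + (n, n), dtype=complex)
    idx = np.arange(n - 1)
    comp[..., idx + 1, idx] = 1.0
    comp[..., :, -1] = -monic
    return np.linalg.eigvals(comp)


def _bruggeman_residual(x: np.ndarray, fractions: np.ndarray,
                        eps: np.ndarray) -> np.ndarray:
    terms = fractions * (eps - x[..., None]) / (eps + 2.0 * x[..., None])
    return terms.sum(axis=-1)


def bruggeman_mix(fractions: Sequence[float], permittivities,
                  *, residual_tol: float = _RESIDUAL_TOL):
    """Effective permittivity of a composite by the Bruggeman rule.

    Solves sum_i f_i (eps_i - eps_eff) / (eps_i + 2 eps_eff) = 0 for the
    physically admissible root: positive real part, non-negative imaginary
    part, and (for tie-breaking among admissible roots) the largest real
    part. The root is polished by Newton iteration so that the residual of
    the mixing equation is below ``residual_tol``.

    Parameters
    ----------
    fractions : sequence of float
        Volume fractions, summing to 1 within 1e-9; at least 2 components.
    permittivities : sequence of complex scalars or arrays
        One (possibly wavelength-resolved) complex permittivity per
        component; arrays are broadcast against each other.

    Returns
    -------
    complex or ndarray of complex
        Effective permittivity, scalar if all inputs were scalars.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise InvalidParameterError("need at least 2 components")
    if np.any(f < -_FRACTION_TOL):
        raise InvalidParameterError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > _FRACTION_TOL:
        raise InvalidParameterError(
            f"fractions sum to {f.sum():.12g}, not 1"
        )
    eps_list = [np.asarray(e, dtype=complex) for e in permittivities]
    if len(eps_list) != f.size:
        raise InvalidParameterError("fractions and permittivities lengths differ")
    scalar_input = all(e.ndim == 0 for e in eps_list)
    shape = np.broadcast_shapes(*(e.shape for e in eps_list))
    eps = np.stack([np.broadcast_to(e, shape) for e in eps_list], axis=-1)

    coeffs = _bruggeman_poly(f, eps)
    roots = _roots_batched(coeffs)

    scale = np.abs(eps).max(axis=-1)
    # physical root: passive (Im >= 0) and not on the non-positive real
    # axis; the spurious roots near -eps_j/2 always have Im <= 0 for
    # passive components, so this filter removes exactly those.
    tol = 1e-9 * scale[..., None]
    admissible = (roots.imag > -tol) & ((roots.real > 0) | (roots.imag > tol))
    score = np.where(admissible, roots.real, -np.inf)
    if np.any(~admissible.any(axis=-1)):
        raise NumericalFailureError(
            "no physically admissible Bruggeman root found; "
            f"roots = {roots[~admissible.any(axis=-1)][:5]}"
        )
    pick = np.argmax(score, axis=-1)
    x = np.take_along_axis(roots, pick[..., None], axis=-1)[..., 0]

    # Newton polish on the rational form; F'(x) = -3 sum f_i eps_i/(eps_i+2x)^2
    for _ in range(4):
        res = _bruggeman_residual(x, f, eps)
        dres = -3.0 * (f * eps / (eps + 2.0 * x[..., None]) ** 2).sum(axis=-1)
        step = np.where(np.abs(dres) > 0, res / dres, 0.0)
        x = x - step

    # passive medium: clamp round-off-negative imaginary parts to zero
    x = np.where(np.abs(x.imag) < 1e-12 * np.maximum(scale, 1.0), x.real + 0j, x)
    if np.any(x.imag < 0):
        raise NumericalFailureError("Bruggeman root with negative imaginary part")

    res = np.abs(_bruggeman_residual(x, f, eps))
    if np.any(res > residual_tol):
        raise NumericalFailureError(
            f"Bruggeman residual {res.max():.3e} exceeds {residual_tol:.1e}"
        )
    if scalar_input:
        return complex(x[()])
    return x


def effective_index(fractions, permittivities) -> np.ndarray:
    """Effective complex refractive index sqrt(eps_eff) with Im >= 0."""
    eps_eff = bruggeman_mix(fractions, permittivities)
    return _sqrt_passive(np.asarray(eps_eff, dtype=complex))


# ---------------------------------------------------------------------------
# Material objects for the forward simulator
# ---------------------------------------------------------------------------


@dataclass
class Material:
    """A named wavelength-to-complex-index mapping."""

    label: str
    _index_fn: Callable[[np.ndarray], np.ndarray]

    def index(self, wavelengths) -> np.ndarray:
        wl = _check_grid(wavelengths)
        idx = np.asarray(self._index_fn(wl), dtype=complex)
        if np.any(idx.imag < -1e-12):
            raise InvalidParameterError(
                f"material {self.label!r} produced negative extinction"
            )
        return idx

    def permittivity(self, wavelengths) -> np.ndarray:
        return self.index(wavelengths) ** 2

    def sample(self, wavelengths) -> MaterialTable:
        wl = _check_grid(wavelengths)
        return MaterialTable(wl, self.index(wl), label=self.label)

    @classmethod
    def constant(cls, n: float, k: float = 0.0, label: str = "constant") -> "Material":
        if n <= 0 or k < 0:
            raise InvalidParameterError("need n > 0 and k >= 0")
        value = complex(n, k)
        return cls(label, lambda wl: np.full(wl.shape, value))

    @classmethod
    def cauchy(cls, a: float, b: float, label: str = "cauchy") -> "Material":
        if a <= 0:
            raise InvalidParameterError("Cauchy A coefficient must be positive")
        return cls(label, lambda wl: (a + b / wl**2).astype(complex))

    @classmethod
    def alumina(cls, constant: float | None = None) -> "Material":
        return cls("alumina", lambda wl: alumina_index(wl, constant=constant).index)

    @classmethod
    def lorentz(cls, params: LorentzOscillatorParams | None = None,
                label: str = "lorentz") -> "Material":
        p = params if params is not None else DEFAULT_DRUG_PARAMS
        return cls(label, lambda wl: _sqrt_passive(p.permittivity(wl)))

    @classmethod
    def from_table(cls, wavelengths, n, k=None, label: str = "table") -> "Material":
        wl = _check_grid(wavelengths)
        n = np.asarray(n, dtype=float)
        k = np.zeros_like(n) if k is None else np.asarray(k, dtype=float)
        if n.shape != wl.shape or k.shape != wl.shape:
            raise StructuralError("table columns must share the wavelength grid")
        if np.any(k < 0):
            raise InvalidParameterError("tabulated k must be non-negative")

        def interp(grid: np.ndarray) -> np.ndarray:
            if grid[0] < wl[0] or grid[-1] > wl[-1]:
                raise RangeError(
                    f"requested grid extends beyond the tabulated range "
                    f"{wl[0]:.0f}-{wl[-1]:.0f} nm"
                )
            return np.interp(grid, wl, n) + 1j * np.interp(grid, wl, k)

        return cls(label, interp)


@dataclass
class MaterialSet:
    """Host, cargo and pore-medium materials for the GIF forward model.

    If ``medium`` is None, the constant ``medium_index`` of the design in
    use supplies the pore medium (so air/water switches need no new set).
    """

    host: Material
    drug: Material
    medium: Material | None = None


def default_materials(drug_params: LorentzOscillatorParams | None = None) -> MaterialSet:
    """Cauchy alumina host plus Lorentz-oscillator cargo molecule."""
    return MaterialSet(
        host=Material.alumina(),
        drug=Material.lorentz(drug_params),
        medium=None,
    )
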