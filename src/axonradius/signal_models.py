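"""Closed-form diffusion signal models for restricted diffusion in cylinders.

The models here describe the perpendicular signal attenuation of water
restricted inside an impermeable cylinder of radius ``r`` under a pulsed
gradient spin echo (PGSE) experiment, and the zeroth- and second-order
rotationally invariant spherical harmonic (RISH) forward models built on top
of them:

* :func:`neumann_perp` — long-pulse (``delta >> r**2/D0``) limit, where the
  log-attenuation is linear in ``r**4`` with slope ``kappa``,
* :func:`vangelderen_perp` — Gaussian-phase-approximation Bessel-root series,
  valid for general pulse timings,
* :func:`sm_forward` / :func:`sv_forward` — spherical-mean and
  spherical-variance signals of a dispersed-stick voxel in the high-b regime.

Internal unit system: micrometre (length), millisecond (time), mT/m
(gradient amplitude).  b-values are in ms/um^2; diffusivities in um^2/ms.
All conversions happen once, at module level, through the gyromagnetic
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "GYROMAGNETIC_RATIO",
    "PulsedGradient",
    "TissueParams",
    "ModelRegimeError",
    "compute_bvalue",
    "gradient_for_bvalue",
    "kappa",
    "neumann_perp",
    "neumann_regime_ok",
    "vangelderen_perp",
    "vangelderen_sphere",
    "erf_regime_ok",
    "axon_kernel",
    "sm_forward",
    "sv_forward",
    "sm_prefactor",
    "sv_prefactor",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GYROMAGNETIC_RATIO = 2.6752e8

#: gamma in internal units: rad ms^-1 um^-1 per (mT/m).
#: 1 (mT/m)*um = 1e-9 T and 1 s = 1e3 ms, hence the 1e-12 factor.
_GAMMA = GYROMAGNETIC_RATIO * 1e-12

#: bD_par below which the erf(sqrt(b*Dpar)) ~ 1 approximation is doubtful.
ERF_REGIME_MIN_BDPAR = 6.0

#: Neumann long-pulse regime requires delta >= this multiple of r^2/D0.
NEUMANN_REGIME_FACTOR = 10.0

#: The second-order RISH factor (2*b*Dpar - 3) changes sign here.
SV_FACTOR_MIN_BDPAR = 1.5


class ModelRegimeError(ValueError):
    """Raised when a forward model is evaluated outside its validity regime."""


@dataclass(frozen=True)
class PulsedGradient:
    """One PGSE condition: rectangular gradient pair.

    Parameters
    ----------
    g : float
        Gradient amplitude in mT/m. Must be >= 0.
    delta : float
        Pulse duration in ms. Must satisfy ``0 < delta <= Delta``.
    Delta : float
        Pulse separation (leading edge to leading edge) in ms.
    direction : array-like of shape (3,), optional
        Unit gradient direction. ``None`` for shell-level parameters where
        only (g, delta, Delta) matter.
    """

    g: float
    delta: float
    Delta: float
    direction: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError(f"gradient amplitude must be >= 0, got {self.g}")
        if not (0 < self.delta <= self.Delta):
            raise ValueError(
                f"need 0 < delta <= Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            if d.shape != (3,):
                raise ValueError("direction must be a 3-vector")
            if abs(np.linalg.norm(d) - 1.0) > 1e-8:
                raise ValueError("direction must be unit-norm within 1e-8")
            object.__setattr__(self, "direction", tuple(d))

    @property
    def bvalue(self) -> float:
        """b-value of this condition in ms/um^2."""
        return compute_bvalue(self)

    def with_amplitude(self, g: float) -> "PulsedGradient":
        """Same timings, different amplitude."""
        return PulsedGradient(g=g, delta=self.delta, Delta=self.Delta,
                              direction=self.direction)


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth generative parameters of a dispersed-cylinder voxel.

    f : intracellular signal fraction, in [0, 1].
    Dpar : intracellular parallel (axial) diffusivity, um^2/ms.
    p2 : intracellular coherence index, the second Legendre moment of the
        fiber orientation distribution (0 = isotropic, 1 = aligned).
    D0 : intrinsic diffusivity of the axoplasm, um^2/ms.
    r : cylinder radius, um.
    """

    f: float
    Dpar: float
    p2: float
    D0: float
    r: float

    def __post_init__(self) -> None:
        if not 0 <= self.f <= 1:
            raise ValueError(f"f must be in [0,1], got {self.f}")
        if self.D0 <= 0:
            raise ValueError(f"D0 must be > 0, got {self.D0}")
        if self.Dpar < 0 or self.Dpar > self.D0 + 1e-12:
            raise ValueError(f"need 0 <= Dpar <= D0, got Dpar={self.Dpar}, D0={self.D0}")
        if not 0 <= self.p2 <= 1:
            raise ValueError(f"p2 must be in [0,1], got {self.p2}")
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")


def compute_bvalue(grad: PulsedGradient) -> float:
    """PGSE b-value ``(gamma*g*delta)**2 * (Delta - delta/3)`` in ms/um^2."""
    q = _GAMMA * grad.g * grad.delta  # rad/um
    return q * q * (grad.Delta - grad.delta / 3.0)


def gradient_for_bvalue(b: float, delta: float, Delta: float,
                        direction=None) -> PulsedGradient:
    """Invert the b-value formula for the amplitude at fixed timings."""
    if b < 0:
        raise ValueError("b must be >= 0")
    g = np.sqrt(b / (Delta - delta / 3.0)) / (_GAMMA * delta)
    return PulsedGradient(g=float(g), delta=delta, Delta=Delta, direction=direction)


def kappa(g: float, delta: float, D0: float) -> float:
    """Attenuation constant per r^4: ``7 * gamma^2 * g^2 * delta / (48 * D0)``.

    Units: um^-4, so that ``kappa * r**4`` is dimensionless with r in um.
    The Neumann perpendicular attenuation is ``exp(-kappa * r**4)``.
    """
    if D0 <= 0:
        raise ValueError(f"D0 must be > 0, got {D0}")
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    return 7.0 * (_GAMMA * g) ** 2 * delta / (48.0 * D0)


def neumann_perp(r, grad: PulsedGradient, D0: float):
    """Neumann long-pulse perpendicular attenuation ``exp(-kappa * r**4)``.

    Valid for ``delta >> r**2 / D0`` (see :func:`neumann_regime_ok`); the
    value is computed regardless of regime.
    """
    r = np.asarray(r, dtype=float)
    out = np.exp(-kappa(grad.g, grad.delta, D0) * r ** 4)
    return out if out.ndim else float(out)


def neumann_regime_ok(r, delta: float, D0: float):
    """True where the long-pulse condition ``delta >= 10 * r**2 / D0`` holds."""
    r = np.asarray(r, dtype=float)
    ok = delta >= NEUMANN_REGIME_FACTOR * r ** 2 / D0
    return ok if ok.ndim else bool(ok)


def _vg_exponent_unit_g(r, delta: float, Delta: float, D0: float,
                        n_terms: int = 20, geometry: str = "cylinder"):
    """Gaussian-phase log-attenuation divided by (gamma*g)^2.

    Bessel-root series of the perpendicular PGSE attenuation for an
    impermeable cylinder (roots of J1') or sphere (roots of j1').  Returns
    the positive exponent ``E`` such that ``S = exp(-(gamma*g)**2 * E)``.
    """
    r = np.asarray(r, dtype=float)
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if geometry == "cylinder":
        roots = special.jnp_zeros(1, n_terms)  # J1'(x) = 0
        denom_shift = 1.0
    elif geometry == "sphere":
        roots = _sphere_bessel_prime_roots(n_terms)  # j1'(x) = 0
        denom_shift = 2.0
    else:  # pragma: no cover - internal
        raise ValueError(f"unknown geometry {geometry!r}")

    rr = r[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        a = roots / rr  # um^-1
        da2 = D0 * a * a
        terms = (
            2.0 * da2 * delta
            - 2.0
            + 2.0 * np.exp(-da2 * delta)
            + 2.0 * np.exp(-da2 * Delta)
            - np.exp(-da2 * (Delta - delta))
            - np.exp(-da2 * (Delta + delta))
        ) / (D0 ** 2 * a ** 6 * (roots ** 2 - denom_shift))
    total = np.sum(terms, axis=-1)
    total = np.where(r > 0, total, 0.0)
    # flag slowly converging truncations: compare the last retained term
    last = np.abs(np.where(r > 0, terms[..., -1], 0.0))
    if np.any(last > 1e-9 * np.maximum(np.abs(total), 1e-300)):
        warnings.warn(
            "Gaussian-phase series truncation above 1e-9 relative tolerance; "
            "increase n_terms",
            RuntimeWarning,
            stacklevel=3,
        )
    return 2.0 * total


_J1P_SPHERE_ROOTS_CACHE: dict[int, np.ndarray] = {}


def _sphere_bessel_prime_roots(n: int) -> np.ndarray:
    """First ``n`` positive roots of the derivative of the spherical Bessel j1."""
    if n in _J1P_SPHERE_ROOTS_CACHE:
        return _J1P_SPHERE_ROOTS_CACHE[n]

    def j1p(x):
        return special.spherical_jn(1, x, derivative=True)

    roots = []
    # roots approach k*pi + ~0.5pi spacing; bracket-scan is robust and cheap
    x0, dx = 1.0, 0.05
    x = x0
    from scipy.optimize import brentq

    while len(roots) < n:
        if j1p(x) * j1p(x + dx) < 0:
            roots.append(brentq(j1p, x, x + dx))
        x += dx
    out = np.asarray(roots)
    _J1P_SPHERE_ROOTS_CACHE[n] = out
    return out


def vangelderen_perp(r, grad: PulsedGradient, D0: float, n_terms: int = 20):
    """Van Gelderen PGSE perpendicular attenuation of an impermeable cylinder.

    Gaussian-phase approximation as a series over the roots of J1'.
    Converges to :func:`neumann_perp` as ``delta * D0 / r**2 -> inf``.
    """
    exponent = _vg_exponent_unit_g(r, grad.delta, grad.Delta, D0,
                                   n_terms=n_terms, geometry="cylinder")
    out = np.exp(-((_GAMMA * grad.g) ** 2) * np.asarray(exponent))
    return out if out.ndim else float(out)


def vangelderen_sphere(r, grad: PulsedGradient, D0: float, n_terms: int = 20):
    """Gaussian-phase PGSE attenuation of an impermeable sphere of radius r."""
    exponent = _vg_exponent_unit_g(r, grad.delta, grad.Delta, D0,
                                   n_terms=n_terms, geometry="sphere")
    out = np.exp(-((_GAMMA * grad.g) ** 2) * np.asarray(exponent))
    return out if out.ndim else float(out)


def erf_regime_ok(b: float, Dpar: float) -> bool:
    """True when ``b * Dpar`` is large enough that erf(sqrt(b*Dpar)) ~ 1."""
    return b * Dpar >= ERF_REGIME_MIN_BDPAR


def _perp_attenuation(r, grad: PulsedGradient, D0: float, model: str):
    if model == "neumann":
        return neumann_perp(r, grad, D0)
    if model == "vangelderen":
        return vangelderen_perp(r, grad, D0)
    raise ValueError(f"model must be 'neumann' or 'vangelderen', got {model!r}")


def axon_kernel(grad: PulsedGradient, cos_psi, params: TissueParams,
                model: str = "neumann"):
    """Directional signal of a cylinder at angle psi to the gradient.

    ``f * exp(-b * Dpar * cos_psi**2) * S_perp(r | g*sin(psi), delta)``:
    axial Gaussian decay times perpendicular restricted attenuation with the
    gradient projected onto the plane normal to the cylinder axis.  This is
    the exact kernel used to synthesize directional signals numerically.
    """
    cos_psi = np.asarray(cos_psi, dtype=float)
    if np.any(np.abs(cos_psi) > 1 + 1e-12):
        raise ValueError("cos_psi must lie in [-1, 1]")
    cos2 = np.clip(cos_psi, -1.0, 1.0) ** 2
    sin2 = 1.0 - cos2
    b = compute_bvalue(grad)
    if model == "neumann":
        # kappa scales with g^2, so projecting g -> g*sin(psi) multiplies the
        # exponent by sin^2(psi)
        perp = np.exp(-kappa(grad.g, grad.delta, params.D0) * sin2 * params.r ** 4)
    elif model == "vangelderen":
        e_unit = _vg_exponent_unit_g(params.r, grad.delta, grad.Delta, params.D0)
        perp = np.exp(-((_GAMMA * grad.g) ** 2) * sin2 * e_unit)
    else:
        raise ValueError(f"model must be 'neumann' or 'vangelderen', got {model!r}")
    out = params.f * np.exp(-b * params.Dpar * cos2) * perp
    return out if out.ndim else float(out)


def sm_prefactor(f: float, Dpar: float) -> float:
    """High-b spherical-mean prefactor ``beta = f * sqrt(pi / (4 * Dpar))``."""
    if Dpar <= 0:
        raise ValueError("Dpar must be > 0")
    return f * np.sqrt(np.pi / (4.0 * Dpar))


def sv_prefactor(f: float, Dpar: float) -> float:
    """High-b spherical-variance prefactor ``f * sqrt(pi) / (8 * Dpar**1.5)``."""
    if Dpar <= 0:
        raise ValueError("Dpar must be > 0")
    return f * np.sqrt(np.pi) / (8.0 * Dpar ** 1.5)


def sm_forward(grad: PulsedGradient, params: TissueParams,
               model: str = "neumann"):
    """Spherical-mean signal of a dispersed restricted-cylinder voxel.

    ``SM(b) = beta * S_perp(r) / sqrt(b)`` with ``beta = f*sqrt(pi/(4*Dpar))``,
    valid in the high-b regime where erf(sqrt(b*Dpar)) ~ 1.  Independent of
    the orientation distribution; the two-shell ratio is independent of f
    and Dpar.
    """
    b = compute_bvalue(grad)
    if b <= 0:
        raise ValueError("sm_forward requires b > 0")
    perp = _perp_attenuation(params.r, grad, params.D0, model)
    return sm_prefactor(params.f, params.Dpar) * perp / np.sqrt(b)


def sv_forward(grad: PulsedGradient, params: TissueParams,
               model: str = "neumann"):
    """Spherical-variance (second-order RISH) signal of a dispersed voxel.

    ``SV(b) = p2 * f * sqrt(pi)/8 * Dpar**-1.5 * (2*b*Dpar - 3)
              * S_perp(r) / b**1.5``

    This is the exact second-order Legendre projection of the stick kernel
    in the erf ~ 1 regime, and the exact algebraic counterpart of the
    two-shell inversion in :mod:`axonradius.estimators`.  The factor
    ``(2*b*Dpar - 3)`` changes sign at ``b*Dpar = 3/2``; evaluation below
    that point raises :class:`ModelRegimeError`.
    """
    b = compute_bvalue(grad)
    if b <= 0:
        raise ValueError("sv_forward requires b > 0")
    t = b * params.Dpar
    if t <= SV_FACTOR_MIN_BDPAR:
        raise ModelRegimeError(
            f"sv_forward requires b*Dpar > 3/2, got {t:.3g}"
        )
    perp = _perp_attenuation(params.r, grad, params.D0, model)
    return (params.p2 * sv_prefactor(params.f, params.Dpar)
            * (2.0 * t - 3.0) * perp / b ** 1.5)
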