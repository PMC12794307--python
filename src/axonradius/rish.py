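"""Spherical-harmonic fitting and rotationally invariant (RISH) features.

Per b-shell, the directional signal is decomposed in a real, even-order,
symmetric SH basis (default Lmax=6).  Coefficients are estimated either by
ordinary least squares or by a maximum-likelihood fit under a Rician noise
model with known sigma.  The zeroth- and second-order RISH features are

    S_l = ||c_l||_2 / sqrt(4*pi*(2l+1))

normalized by the non-diffusion-weighted signal; with this scale convention
S_0 equals the spherical mean of the signal, and S_2 (the "spherical
variance") is the exact counterpart of the second-order forward model in
:mod:`axonradius.signal_models`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .signal_models import PulsedGradient

__all__ = [
    "ShellData",
    "RishFeatures",
    "sh_orders",
    "sh_design_matrix",
    "fit_sh_ls",
    "fit_sh_ml",
    "rish_features",
    "shell_rish",
    "sv_bias_probe",
    "group_shells",
    "compute_rish_volumes",
]


def sh_orders(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs of the even-order symmetric basis up to lmax."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be a non-negative even integer")
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def n_coeffs(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def sh_design_matrix(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real even-order SH design matrix, rows = directions, columns = (l, m).

    Real basis from the complex orthonormal Y_l^m:
    m = 0 -> Y_l^0; m > 0 -> sqrt(2) * Re(Y_l^m); m < 0 -> sqrt(2) * Im(Y_l^|m|).
    """
    directions = np.asarray(directions, dtype=float)
    if directions.ndim != 2 or directions.shape[1] != 3:
        raise ValueError("directions must be (N, 3)")
    norms = np.linalg.norm(directions, axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        directions = directions / norms[:, None]
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    cols = []
    for l, m in sh_orders(lmax):
        y = special.sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * y.real)
        else:
            cols.append(np.sqrt(2.0) * y.imag)
    return np.stack(cols, axis=1)


@dataclass
class ShellData:
    """All measurements of one b-shell."""

    b: float
    grad: PulsedGradient
    directions: np.ndarray
    signals: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.directions.shape != (self.signals.shape[0], 3):
            raise ValueError("directions and signals are inconsistent")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative magnitudes")


@dataclass
class RishFeatures:
    """Normalized RISH features of one shell.

    ``sm`` and ``sv`` may be scalars (one voxel/segment) or arrays (maps).
    """

    b: float
    sm: np.ndarray | float
    sv: np.ndarray | float
    sh_coeffs: np.ndarray | None = None
    s0_ref: float = 1.0
    grad: PulsedGradient | None = None


def fit_sh_ls(directions: np.ndarray, signals: np.ndarray, lmax: int = 6) -> np.ndarray:
    """Ordinary least-squares SH coefficients."""
    design = sh_design_matrix(directions, lmax)
    _check_rank(design)
    coeffs, *_ = np.linalg.lstsq(design, np.asarray(signals, float), rcond=None)
    return coeffs


def _check_rank(design: np.ndarray) -> None:
    if design.shape[0] < design.shape[1]:
        raise ValueError(
            f"need at least {design.shape[1]} directions for this Lmax, "
            f"got {design.shape[0]}"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient SH design matrix (bad direction set)")


def _rician_nll_and_grad(coeffs, design, x, sigma):
    nu = design @ coeffs
    nu = np.maximum(nu, 1e-12)  # Rician location must stay positive
    s2 = sigma * sigma
    z = x * nu / s2
    # log I0(z) = z + log(ive(0, z)) is stable for large z
    log_i0 = z + np.log(special.ive(0, z))
    nll = np.sum(nu * nu / (2.0 * s2) - log_i0)
    ratio = special.ive(1, z) / special.ive(0, z)
    dnll_dnu = nu / s2 - (x / s2) * ratio
    grad = design.T @ dnll_dnu
    return nll, grad


def fit_sh_ml(shell: ShellData, lmax: int = 6) -> np.ndarray:
    """Maximum-likelihood SH coefficients under a Rician noise model.

    The noise level ``shell.sigma`` is known and fixed.  Optimization starts
    from the least-squares solution; on failure to converge the least-squares
    coefficients are returned with a warning.
    """
    if shell.sigma <= 0:
        raise ValueError("shell.sigma must be > 0 for the Rician ML fit")
    design = sh_design_matrix(shell.directions, lmax)
    _check_rank(design)
    c0, *_ = np.linalg.lstsq(design, shell.signals, rcond=None)
    res = optimize.minimize(
        _rician_nll_and_grad,
        c0,
        args=(design, shell.signals, shell.sigma),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not res.success and not np.all(np.isfinite(res.x)):
        warnings.warn("Rician ML fit did not converge; falling back to least squares",
                      RuntimeWarning)
        return c0
    return res.x


def _block_norms(sh_coeffs: np.ndarray, lmax: int) -> dict[int, float]:
    orders = sh_orders(lmax)
    out = {}
    ls = np.array([l for l, _ in orders])
    for l in range(0, lmax + 1, 2):
        block = np.asarray(sh_coeffs)[..., ls == l]
        out[l] = np.linalg.norm(block, axis=-1)
    return out


def rish_features(sh_coeffs: np.ndarray, s0_ref: float, b: float = 0.0,
                  grad: PulsedGradient | None = None) -> RishFeatures:
    """Normalized zeroth/second-order RISH features from SH coefficients.

    ``S_l = ||c_l|| / sqrt(4*pi*(2l+1)) / s0_ref``, so that ``sm`` equals the
    spherical mean of the signal divided by the b=0 reference.  Both features
    are invariant to rotations of the direction frame.
    """
    if s0_ref <= 0:
        raise ValueError("s0_ref must be > 0")
    sh_coeffs = np.asarray(sh_coeffs, dtype=float)
    ncoef = sh_coeffs.shape[-1]
    lmax = _lmax_from_ncoef(ncoef)
    norms = _block_norms(sh_coeffs, lmax)
    sm = norms[0] / np.sqrt(4.0 * np.pi) / s0_ref
    if lmax >= 2:
        sv = norms[2] / np.sqrt(4.0 * np.pi * 5.0) / s0_ref
    else:
        sv = np.zeros_like(sm)
    if np.ndim(sm) == 0:
        sm, sv = float(sm), float(sv)
    return RishFeatures(b=b, sm=sm, sv=sv, sh_coeffs=sh_coeffs,
                        s0_ref=s0_ref, grad=grad)


def _lmax_from_ncoef(ncoef: int) -> int:
    lmax = 0
    while n_coeffs(lmax) < ncoef:
        lmax += 2
    if n_coeffs(lmax) != ncoef:
        raise ValueError(f"{ncoef} is not a valid even-order SH coefficient count")
    return lmax


def shell_rish(shell: ShellData, s0_ref: float, lmax: int = 6,
               method: str = "ml") -> RishFeatures:
    """Fit one shell and extract its normalized RISH features."""
    if method == "ml":
        coeffs = fit_sh_ml(shell, lmax)
    elif method == "ls":
        coeffs = fit_sh_ls(shell.directions, shell.signals, lmax)
    else:
        raise ValueError(f"method must be 'ml' or 'ls', got {method!r}")
    return rish_features(coeffs, s0_ref, b=shell.b, grad=shell.grad)


def sv_bias_probe(sv_true: float, sigma_coeff: float, n_repeats: int = 10_000,
                  seed: int = 0) -> float:
    """Monte Carlo expectation of the norm of 5 noisy l=2 coefficients.

    The norm of a Gaussian-perturbed coefficient vector follows a noncentral
    chi law with 5 degrees of freedom, so the expectation exceeds ``sv_true``
    whenever ``sigma_coeff > 0`` — the positive SV bias mechanism at low SNR.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if sigma_coeff == 0:
        return float(sv_true)
    rng = np.random.default_rng(seed)
    mean = np.zeros(5)
    mean[0] = sv_true
    draws = mean + sigma_coeff * rng.standard_normal((n_repeats, 5))
    return float(np.mean(np.linalg.norm(draws, axis=1)))


def group_shells(bvals: np.ndarray, tol: float = 0.25) -> dict[float, np.ndarray]:
    """Group b-values (ms/um^2) into shells.

    Values are rounded to the nearest 0.1 ms/um^2 and merged when within
    ``tol`` of an existing shell center.  Returns {shell_b: indices}.
    """
    bvals = np.asarray(bvals, dtype=float)
    centers: list[float] = []
    assign = np.full(bvals.shape, -1, dtype=int)
    for i, b in enumerate(bvals):
        b_round = round(b, 1)
        for k, c in enumerate(centers):
            if abs(b_round - c) <= tol:
                assign[i] = k
                break
        else:
            centers.append(b_round)
            assign[i] = len(centers) - 1
    return {centers[k]: np.flatnonzero(assign == k)
            for k in np.argsort(centers)}


def compute_rish_volumes(dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray,
                         sigma, grads: dict[float, PulsedGradient] | None = None,
                         lmax: int = 6, method: str = "ml",
                         shell_tol: float = 0.25, b0_max: float = 0.05,
                         mask: np.ndarray | None = None):
    """Per-shell SM/SV maps from a 4-D DWI array.

    Parameters
    ----------
    dwi : (X, Y, Z, N) signal magnitudes.
    bvals : (N,) in ms/um^2.
    bvecs : (N, 3) unit directions (normalized here if needed).
    sigma : scalar noise level or (X, Y, Z) map.
    grads : optional {shell_b: PulsedGradient}; only needed downstream for
        radius estimation, stored into the returned features.

    Returns
    -------
    s0 : (X, Y, Z) mean b=0 signal.
    features : {shell_b: RishFeatures with array-valued sm/sv}.
    """
    dwi = np.asarray(dwi, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    shells = group_shells(bvals, tol=shell_tol)
    b0_idx = np.concatenate([idx for b, idx in shells.items() if b <= b0_max]) \
        if any(b <= b0_max for b in shells) else None
    if b0_idx is None or b0_idx.size == 0:
        raise ValueError("no b=0 volumes found; cannot normalize RISH features")
    s0 = dwi[..., b0_idx].mean(axis=-1)
    spatial = dwi.shape[:3]
    if mask is None:
        mask = s0 > 0
    sigma_map = np.broadcast_to(np.asarray(sigma, dtype=float), spatial)

    features: dict[float, RishFeatures] = {}
    for b, idx in shells.items():
        if b <= b0_max:
            continue
        dirs = bvecs[idx]
        nrm = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(nrm - 1) > 1e-3):
            warnings.warn("non-unit bvec rows normalized", RuntimeWarning)
        dirs = dirs / np.maximum(nrm, 1e-12)[:, None]
        grad = grads.get(b) if grads else None
        sm = np.full(spatial, np.nan)
        sv = np.full(spatial, np.nan)
        design = sh_design_matrix(dirs, lmax)
        _check_rank(design)
        for vox in np.ndindex(spatial):
            if not mask[vox]:
                continue
            sig = dwi[vox][idx]
            if method == "ml":
                shell = ShellData(b=b, grad=grad, directions=dirs, signals=sig,
                                  sigma=float(sigma_map[vox]))
                coeffs = fit_sh_ml(shell, lmax)
            else:
                coeffs, *_ = np.linalg.lstsq(design, sig, rcond=None)
            feats = rish_features(coeffs, float(s0[vox]))
            sm[vox], sv[vox] = feats.sm, feats.sv
        features[b] = RishFeatures(b=b, sm=sm, sv=sv, sh_coeffs=None,
                                   s0_ref=1.0, grad=grad)
    return s0, features
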