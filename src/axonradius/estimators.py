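"""Closed-form log-linear and nonlinear estimators of the effective MR radius.

In the high-b regime the log of the (scaled) spherical-mean signal is linear
in r^4 with slope -kappa, where kappa = 7*gamma^2*g^2*delta/(48*D0).  With
exactly two shells:

    SM path:  r^4 = log( sqrt(b1)*SM1 / (sqrt(b2)*SM2) ) / (kappa2 - kappa1)

    SV path:  r^4 = [ log( b1^1.5 * (2*b2*Dpar - 3) * SV1 )
                     - log( b2^1.5 * (2*b1*Dpar - 3) * SV2 ) ]
                   / (kappa2 - kappa1)

Both are the exact algebraic inverses of the forward models in
:mod:`axonradius.signal_models`; the orientation/fraction prefactors cancel
in the ratio.  More than two shells are handled by weighted linear
regression of the log-transformed feature on kappa.  A nonlinear
least-squares reference estimator (Neumann or Van Gelderen kernel) is also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import signal_models as sm_mod
from .rish import RishFeatures
from .signal_models import (
    PulsedGradient,
    TissueParams,
    SV_FACTOR_MIN_BDPAR,
    compute_bvalue,
    kappa,
    neumann_regime_ok,
)

__all__ = [
    "RadiusEstimate",
    "loglinear_radius_sm",
    "loglinear_radius_sv",
    "loglinear_radius_multi",
    "nonlinear_radius",
    "diffusivity_sweep",
]


@dataclass
class RadiusEstimate:
    """Effective MR radius estimate along one or both RISH paths.

    ``r4_*`` keeps the raw fourth-power value (possibly negative under
    noise); ``r_*`` is ``max(r4, 0)**0.25``.  ``flags`` maps names to boolean
    arrays: ``negative_r4``, ``invalid_input``, ``regime``.
    """

    r4_sm: np.ndarray | float | None = None
    r_sm: np.ndarray | float | None = None
    r4_sv: np.ndarray | float | None = None
    r_sv: np.ndarray | float | None = None
    dpar_used: float | np.ndarray | None = None
    d0_used: float | None = None
    flags: dict = field(default_factory=dict)


def _clip_quartic_root(r4):
    r4 = np.asarray(r4, dtype=float)
    r = np.power(np.clip(r4, 0.0, None), 0.25)
    return r if r.ndim else float(r)


def _as_float(x):
    x = np.asarray(x, dtype=float)
    return x if x.ndim else float(x)


def _kappas(grads, D0):
    return [kappa(g.g, g.delta, D0) for g in grads]


def loglinear_radius_sm(f1: RishFeatures, f2: RishFeatures,
                        grads: tuple[PulsedGradient, PulsedGradient],
                        D0: float) -> RadiusEstimate:
    """Two-shell closed-form effective MR radius from spherical means.

    Exact algebraic inverse of :func:`axonradius.signal_models.sm_forward`.
    Non-positive SM values yield NaN with the ``invalid_input`` flag set;
    negative r^4 is kept raw and reported as r = 0 with ``negative_r4`` set.
    """
    g1, g2 = grads
    k1, k2 = _kappas(grads, D0)
    if np.isclose(k1, k2):
        raise ValueError("degenerate design: both shells have equal kappa")
    b1 = f1.b if f1.b > 0 else compute_bvalue(g1)
    b2 = f2.b if f2.b > 0 else compute_bvalue(g2)
    sm1 = np.asarray(f1.sm, dtype=float)
    sm2 = np.asarray(f2.sm, dtype=float)
    invalid = ~((sm1 > 0) & (sm2 > 0) & np.isfinite(sm1) & np.isfinite(sm2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r4 = np.log((np.sqrt(b1) * sm1) / (np.sqrt(b2) * sm2)) / (k2 - k1)
    r4 = np.where(invalid, np.nan, r4)
    r = _clip_quartic_root(np.nan_to_num(r4, nan=0.0))
    r = np.where(invalid, np.nan, r)
    negative = np.where(invalid, False, r4 < 0)
    regime = ~neumann_regime_ok(np.where(np.isfinite(r), r, 0.0),
                                min(g1.delta, g2.delta), D0)
    return RadiusEstimate(
        r4_sm=_as_float(r4), r_sm=_as_float(r), d0_used=D0,
        flags={"negative_r4": negative if negative.ndim else bool(negative),
               "invalid_input": invalid if invalid.ndim else bool(invalid),
               "regime": regime if np.ndim(regime) else bool(regime)},
    )


def loglinear_radius_sv(f1: RishFeatures, f2: RishFeatures,
                        grads: tuple[PulsedGradient, PulsedGradient],
                        D0: float, Dpar) -> RadiusEstimate:
    """Two-shell closed-form effective MR radius from spherical variances.

    Exact algebraic inverse of :func:`axonradius.signal_models.sv_forward`;
    note the cross-pairing of the ``(2*b*Dpar - 3)`` factors between shells.
    ``Dpar`` may be a scalar or a per-voxel map broadcastable against the
    feature arrays.
    """
    g1, g2 = grads
    k1, k2 = _kappas(grads, D0)
    if np.isclose(k1, k2):
        raise ValueError("degenerate design: both shells have equal kappa")
    b1 = f1.b if f1.b > 0 else compute_bvalue(g1)
    b2 = f2.b if f2.b > 0 else compute_bvalue(g2)
    Dpar = np.asarray(Dpar, dtype=float)
    if np.any(Dpar <= 0):
        raise ValueError("Dpar must be > 0")
    t1, t2 = b1 * Dpar, b2 * Dpar
    if np.any(t1 <= SV_FACTOR_MIN_BDPAR) or np.any(t2 <= SV_FACTOR_MIN_BDPAR):
        raise sm_mod.ModelRegimeError(
            "SV inversion requires b*Dpar > 3/2 on both shells")
    sv1 = np.asarray(f1.sv, dtype=float)
    sv2 = np.asarray(f2.sv, dtype=float)
    invalid = ~((sv1 > 0) & (sv2 > 0) & np.isfinite(sv1) & np.isfinite(sv2))
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (np.log(b1 ** 1.5 * (2.0 * t2 - 3.0) * sv1)
               - np.log(b2 ** 1.5 * (2.0 * t1 - 3.0) * sv2))
        r4 = num / (k2 - k1)
    r4 = np.where(invalid, np.nan, r4)
    r = _clip_quartic_root(np.nan_to_num(r4, nan=0.0))
    r = np.where(invalid, np.nan, r)
    negative = np.where(invalid, False, r4 < 0)
    regime = ~neumann_regime_ok(np.where(np.isfinite(r), r, 0.0),
                                min(g1.delta, g2.delta), D0)
    return RadiusEstimate(
        r4_sv=_as_float(r4), r_sv=_as_float(r),
        dpar_used=Dpar if Dpar.ndim else float(Dpar), d0_used=D0,
        flags={"negative_r4": negative if negative.ndim else bool(negative),
               "invalid_input": invalid if invalid.ndim else bool(invalid),
               "regime": regime if np.ndim(regime) else bool(regime)},
    )


def loglinear_radius_multi(features: list[RishFeatures],
                           grads: list[PulsedGradient], D0: float,
                           order: str = "sm", Dpar: float | None = None,
                           weights=None) -> RadiusEstimate:
    """Log-linear estimate from two or more shells.

    Weighted linear regression of the log-transformed feature on kappa;
    the slope is -r^4.  With exactly two shells this reduces to the
    closed-form two-shell estimators.
    """
    if len(features) < 2 or len(features) != len(grads):
        raise ValueError("need >= 2 shells with matching gradients")
    ks = np.array(_kappas(grads, D0))
    if np.ptp(ks) == 0:
        raise ValueError("degenerate design: all shells have equal kappa")
    bs = np.array([f.b if f.b > 0 else compute_bvalue(g)
                   for f, g in zip(features, grads)])
    if order == "sm":
        vals = np.array([np.asarray(f.sm, float) for f in features])
        y = np.log(np.sqrt(bs) * vals.T).T
    elif order == "sv":
        if Dpar is None or Dpar <= 0:
            raise ValueError("SV path requires Dpar > 0")
        t = bs * Dpar
        if np.any(t <= SV_FACTOR_MIN_BDPAR):
            raise sm_mod.ModelRegimeError(
                "SV inversion requires b*Dpar > 3/2 on all shells")
        vals = np.array([np.asarray(f.sv, float) for f in features])
        y = np.log((bs ** 1.5 / (2.0 * t - 3.0)) * vals.T).T
    else:
        raise ValueError(f"order must be 'sm' or 'sv', got {order!r}")
    w = np.ones_like(ks) if weights is None else np.asarray(weights, float)
    # weighted straight-line fit y = a - kappa * r4, vectorized over voxels
    sw = w.sum()
    kbar = (w * ks).sum() / sw
    ybar = np.tensordot(w, y, axes=(0, 0)) / sw
    denom = (w * (ks - kbar) ** 2).sum()
    slope = np.tensordot(w * (ks - kbar), y, axes=(0, 0)) / denom
    r4 = -slope
    est = RadiusEstimate(d0_used=D0, dpar_used=Dpar)
    if order == "sm":
        est.r4_sm, est.r_sm = _as_float(r4), _clip_quartic_root(r4)
    else:
        est.r4_sv, est.r_sv = _as_float(r4), _clip_quartic_root(r4)
    est.flags = {"negative_r4": np.asarray(r4) < 0}
    return est


def _forward_shape(r: float, grad: PulsedGradient, D0: float, Dpar: float,
                   model: str, order: str) -> float:
    """Forward model without the orientation/fraction prefactor."""
    b = compute_bvalue(grad)
    perp = sm_mod._perp_attenuation(r, grad, D0, model)
    if order == "sm":
        return perp / np.sqrt(b)
    t = b * Dpar
    return (2.0 * t - 3.0) * perp / b ** 1.5


def nonlinear_radius(features: list[RishFeatures], grads: list[PulsedGradient],
                     D0: float, Dpar: float | None = None,
                     model: str = "neumann", order: str = "sm") -> RadiusEstimate:
    """Nonlinear least-squares reference estimator of (prefactor, r).

    Fits ``amp * shape(r; b_i)`` to the per-shell feature values with the
    Neumann or Van Gelderen perpendicular kernel; multi-start over
    r0 in {0.5, 2, 4} um, bounded r in [0, 10] um.
    """
    if len(features) < 2 or len(features) != len(grads):
        raise ValueError("need >= 2 shells with matching gradients")
    if order == "sv" and (Dpar is None or Dpar <= 0):
        raise ValueError("SV path requires Dpar > 0")
    obs = np.array([float(np.asarray(f.sm if order == "sm" else f.sv))
                    for f in features])
    if np.any(~np.isfinite(obs)) or np.any(obs <= 0):
        est = RadiusEstimate(d0_used=D0, dpar_used=Dpar,
                             flags={"invalid_input": True})
        return est

    def residuals(theta):
        log_amp, r = theta
        pred = np.array([_forward_shape(r, g, D0, Dpar, model, order)
                         for g in grads])
        return np.exp(log_amp) * pred - obs

    best = None
    for r0 in (0.5, 2.0, 4.0):
        shape0 = _forward_shape(r0, grads[0], D0, Dpar, model, order)
        amp0 = max(obs[0] / shape0, 1e-12)
        try:
            res = optimize.least_squares(
                residuals, x0=[np.log(amp0), r0],
                bounds=([-50.0, 0.0], [50.0, 10.0]), xtol=1e-14, ftol=1e-14,
                gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    est = RadiusEstimate(d0_used=D0, dpar_used=Dpar)
    if best is None:
        est.flags = {"converged": False}
        return est
    r = float(best.x[1])
    if order == "sm":
        est.r_sm, est.r4_sm = r, r ** 4
    else:
        est.r_sv, est.r4_sv = r, r ** 4
    est.flags = {"converged": bool(best.success)}
    return est


def diffusivity_sweep(sm_pairs: np.ndarray, sv_pairs: np.ndarray,
                      grads: tuple[PulsedGradient, PulsedGradient],
                      D0_grid, Dpar_grid) -> np.ndarray:
    """Mean (r_sm - r_sv) over voxels for each (D0, Dpar) cell.

    ``sm_pairs`` and ``sv_pairs`` are (N, 2) arrays of features at the two
    shells.  Returns an array of shape (len(D0_grid), len(Dpar_grid)).  The
    sensitivity of the SM-SV radius difference to the assumed diffusivities
    is dominated by Dpar (the SM path does not depend on it at all).
    """
    sm_pairs = np.atleast_2d(np.asarray(sm_pairs, dtype=float))
    sv_pairs = np.atleast_2d(np.asarray(sv_pairs, dtype=float))
    if sm_pairs.size == 0 or sv_pairs.size == 0:
        raise ValueError("empty input")
    if sm_pairs.shape != sv_pairs.shape or sm_pairs.shape[1] != 2:
        raise ValueError("sm_pairs and sv_pairs must both be (N, 2)")
    D0_grid = np.asarray(D0_grid, dtype=float)
    Dpar_grid = np.asarray(Dpar_grid, dtype=float)
    if np.any(D0_grid <= 0) or np.any(Dpar_grid <= 0):
        raise ValueError("diffusivity grids must be strictly positive")
    b1, b2 = compute_bvalue(grads[0]), compute_bvalue(grads[1])
    out = np.empty((D0_grid.size, Dpar_grid.size))
    for i, d0 in enumerate(D0_grid):
        fsm1 = RishFeatures(b=b1, sm=sm_pairs[:, 0], sv=sv_pairs[:, 0])
        fsm2 = RishFeatures(b=b2, sm=sm_pairs[:, 1], sv=sv_pairs[:, 1])
        est_sm = loglinear_radius_sm(fsm1, fsm2, grads, d0)
        for j, dpar in enumerate(Dpar_grid):
            est_sv = loglinear_radius_sv(fsm1, fsm2, grads, d0, dpar)
            out[i, j] = np.nanmean(np.asarray(est_sm.r_sm)
                                   - np.asarray(est_sv.r_sv))
    return out
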