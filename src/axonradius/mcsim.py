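"""Monte Carlo spin-walker diffusion simulation in axon/glia substrates.

Walkers take fixed-length, uniformly oriented off-lattice steps (default
0.40 um) inside impermeable geometries built from spheres and cylinders;
membrane collisions are handled by specular reflection of the residual
step.  The time step is tied to the step length through the Einstein
relation ``dt = step**2 / (6 * D0)``.  PGSE signals are synthesized by
accruing the spin phase under an ideal rectangular bipolar gradient
waveform discretized at dt.

The glia-mixture experiment combines an analytic dispersed-cylinder axon
compartment with Monte Carlo glia signals at varying signal fractions and
pushes the mixed signal through the RISH + radius-estimation pipeline to
quantify the bias of the SM- and SV-derived effective radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from . import signal_models as sm_mod
from .rish import RishFeatures, fit_sh_ls, rish_features
from .signal_models import PulsedGradient, TissueParams, axon_kernel, compute_bvalue

__all__ = [
    "Substrate",
    "WalkerEnsemble",
    "cylinder_substrate",
    "sphere_substrate",
    "glia_substrate",
    "substrate_from_swc",
    "seed_walkers",
    "walk",
    "pgse_signal",
    "discrete_bvalue",
    "pgse_phase_integrals",
    "signals_from_phase_integrals",
    "simulate_pgse",
    "watson_concentration",
    "watson_odf_weights",
    "dispersed_cylinder_signal",
    "glia_mixture_experiment",
]

#: fixed off-lattice step length in um
DEFAULT_STEP = 0.40

_CONTAIN_TOL = 1e-7
_EXIT_EPS = 1e-6
_MAX_BOUNCES = 10


# ---------------------------------------------------------------------------
# substrates
# ---------------------------------------------------------------------------

@dataclass
class Substrate:
    """Watertight union of spheres and (possibly infinite) cylinders.

    ``spheres``: (S, 4) rows [cx, cy, cz, R].
    ``cylinders``: (C, 8) rows [bx, by, bz, ax, ay, az, R, L]; the axis is a
    unit vector, L may be inf (periodic caps: only the radial boundary
    reflects and seeding uses ``seed_halflength`` along the axis).
    """

    kind: str
    spheres: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    cylinders: np.ndarray = field(default_factory=lambda: np.zeros((0, 8)))
    seed_halflength: float = 20.0

    def __post_init__(self) -> None:
        self.spheres = np.atleast_2d(np.asarray(self.spheres, dtype=float))
        self.cylinders = np.atleast_2d(np.asarray(self.cylinders, dtype=float))
        if self.spheres.size and self.spheres.shape[1] != 4:
            raise ValueError("spheres must be (S, 4)")
        if self.cylinders.size and self.cylinders.shape[1] != 8:
            raise ValueError("cylinders must be (C, 8)")
        if self.spheres.size and np.any(self.spheres[:, 3] <= 0):
            raise ValueError("sphere radii must be > 0")
        if self.cylinders.size:
            if np.any(self.cylinders[:, 6] <= 0):
                raise ValueError("cylinder radii must be > 0")
            norms = np.linalg.norm(self.cylinders[:, 3:6], axis=1)
            if np.any(np.abs(norms - 1) > 1e-8):
                raise ValueError("cylinder axes must be unit-norm")
        if self.spheres.shape[0] + self.cylinders.shape[0] == 0:
            raise ValueError("substrate must contain at least one primitive")

    # -- geometry queries ---------------------------------------------------

    def contains(self, points: np.ndarray, tol: float = _CONTAIN_TOL) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.zeros(points.shape[0], dtype=bool)
        for c in self.spheres:
            d2 = np.sum((points - c[:3]) ** 2, axis=1)
            inside |= d2 <= (c[3] + tol) ** 2
        for c in self.cylinders:
            base, axis, R, L = c[:3], c[3:6], c[6], c[7]
            w = points - base
            h = w @ axis
            rad2 = np.sum(w * w, axis=1) - h * h
            ok = rad2 <= (R + tol) ** 2
            if np.isfinite(L):
                ok &= (h >= -tol) & (h <= L + tol)
            inside |= ok
        return inside

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = [], []
        for c in self.spheres:
            los.append(c[:3] - c[3])
            his.append(c[:3] + c[3])
        for c in self.cylinders:
            base, axis, R, L = c[:3], c[3:6], c[6], c[7]
            half = self.seed_halflength
            p0 = base if np.isfinite(L) else base - axis * half
            p1 = base + axis * (L if np.isfinite(L) else half)
            pad = R * np.sqrt(np.clip(1 - axis ** 2, 0, 1)) + 1e-12
            # loose but safe: pad by full radius
            los.append(np.minimum(p0, p1) - R)
            his.append(np.maximum(p0, p1) + R)
        return np.min(los, axis=0), np.max(his, axis=0)

    def rotated(self, rot: np.ndarray) -> "Substrate":
        """Substrate rotated by the 3x3 rotation matrix ``rot``."""
        sph = self.spheres.copy()
        if sph.size:
            sph[:, :3] = sph[:, :3] @ rot.T
        cyl = self.cylinders.copy()
        if cyl.size:
            cyl[:, :3] = cyl[:, :3] @ rot.T
            cyl[:, 3:6] = cyl[:, 3:6] @ rot.T
        return Substrate(kind=self.kind, spheres=sph, cylinders=cyl,
                         seed_halflength=self.seed_halflength)

    @property
    def min_feature(self) -> float:
        vals = []
        if self.spheres.size:
            vals.append(self.spheres[:, 3].min())
        if self.cylinders.size:
            vals.append(self.cylinders[:, 6].min())
        return float(min(vals))


def cylinder_substrate(radius: float, axis=(0.0, 0.0, 1.0),
                       length: float = np.inf,
                       seed_halflength: float = 20.0) -> Substrate:
    """Single impermeable cylinder; infinite length by default."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    base = np.zeros(3) if not np.isfinite(length) else -axis * length / 2.0
    row = np.concatenate([base, axis, [radius, length]])
    return Substrate(kind="cylinder", cylinders=row[None, :],
                     seed_halflength=seed_halflength)


def sphere_substrate(radius: float, center=(0.0, 0.0, 0.0)) -> Substrate:
    """Single impermeable sphere."""
    row = np.concatenate([np.asarray(center, float), [radius]])
    return Substrate(kind="sphere", spheres=row[None, :])


def glia_substrate(soma_radius: float = 5.0, n_processes: int = 20,
                   process_radius=(1.0, 2.0), process_length: float = 30.0,
                   seed: int = 0, process_p2: float = 0.0) -> Substrate:
    """Parametric glia stand-in: soma sphere + dispersed cylindrical processes.

    Process orientations are drawn at random (deterministic given the seed):
    isotropically by default, or from a Watson distribution about the z axis
    with second Legendre moment ``process_p2`` to mimic glial processes that
    partially align with a surrounding fiber bundle, as observed for white
    matter glia.  A finite cell retains residual orientational anisotropy
    either way.  Radii are drawn uniformly in ``process_radius``.  With
    ``soma_radius = 0`` (process-only glia) the processes are spatially
    disjoint compartments — without a soma there is no structure connecting
    them, so walkers must not exchange between differently oriented
    processes.
    """
    rng = np.random.default_rng(seed)
    spheres = np.zeros((0, 4))
    if soma_radius > 0:
        spheres = np.array([[0.0, 0.0, 0.0, soma_radius]])
    rows = []
    if n_processes > 0:
        if process_p2 > 0:
            dirs = _watson_unit_vectors(rng, n_processes,
                                        watson_concentration(process_p2))
        else:
            dirs = _random_unit_vectors(rng, n_processes)
        lo, hi = process_radius
        radii = rng.uniform(lo, hi, size=n_processes)
        # disjoint lattice placement for soma-free processes; process_length
        # may be inf (periodic caps: radial restriction only)
        extent = process_length if np.isfinite(process_length) else 80.0
        spacing = extent + 2.0 * hi + 4.0
        side = int(np.ceil(n_processes ** (1.0 / 3.0)))
        for k, (d, r) in enumerate(zip(dirs, radii)):
            if soma_radius > 0:
                base = d * (0.9 * soma_radius)
            elif np.isfinite(process_length):
                center = spacing * (np.array([k % side, (k // side) % side,
                                              k // side ** 2]) - (side - 1) / 2.0)
                base = center - d * (process_length / 2.0)
            else:
                base = spacing * (np.array([k % side, (k // side) % side,
                                            k // side ** 2]) - (side - 1) / 2.0)
            rows.append(np.concatenate([base, d, [r, process_length]]))
    cylinders = np.array(rows) if rows else np.zeros((0, 8))
    return Substrate(kind="glia", spheres=spheres, cylinders=cylinders)


def substrate_from_swc(source, scale: float = 1.0) -> Substrate:
    """Build a glia substrate from an SWC morphology (neuromorpho dialect).

    Soma nodes (type 1) become spheres; every child node becomes a cylinder
    from its parent's coordinate to its own, with the child's radius.
    ``source`` is a path or a string containing SWC text.
    """
    if isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        idx, typ = int(parts[0]), int(parts[1])
        xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])]) * scale
        radius = float(parts[5]) * scale
        parent = int(parts[6])
        nodes[idx] = (typ, xyz, radius, parent)
    spheres, cylinders = [], []
    for idx, (typ, xyz, radius, parent) in nodes.items():
        if typ == 1 and parent == -1:
            spheres.append(np.concatenate([xyz, [radius]]))
            continue
        if parent == -1 or parent not in nodes:
            spheres.append(np.concatenate([xyz, [radius]]))
            continue
        p_xyz = nodes[parent][1]
        seg = xyz - p_xyz
        length = np.linalg.norm(seg)
        if length < 1e-9:
            spheres.append(np.concatenate([xyz, [radius]]))
            continue
        axis = seg / length
        cylinders.append(np.concatenate([p_xyz, axis, [radius, length]]))
    return Substrate(
        kind="glia",
        spheres=np.array(spheres) if spheres else np.zeros((0, 4)),
        cylinders=np.array(cylinders) if cylinders else np.zeros((0, 8)),
    )


# ---------------------------------------------------------------------------
# walkers
# ---------------------------------------------------------------------------

@dataclass
class WalkerEnsemble:
    n_walkers: int
    step: float
    positions: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.n_walkers, 3):
            raise ValueError("positions must be (n_walkers, 3)")


def seed_walkers(substrate: Substrate, n: int, seed: int,
                 step: float = DEFAULT_STEP) -> WalkerEnsemble:
    """Rejection-sampled uniform walker positions inside the substrate."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = substrate.bounding_box()
    out = np.empty((0, 3))
    tried = 0
    while out.shape[0] < n:
        batch = max(4 * (n - out.shape[0]), 1024)
        cand = rng.uniform(lo, hi, size=(batch, 3))
        keep = cand[substrate.contains(cand, tol=0.0)]
        tried += batch
        out = np.vstack([out, keep])
        if tried >= 2000 and out.shape[0] / tried < 1e-4:
            raise ValueError(
                "rejection-sampling acceptance rate below 1e-4; check geometry")
    if step > substrate.min_feature / 2.0:
        import warnings

        warnings.warn("step exceeds half the smallest geometric feature",
                      RuntimeWarning)
    return WalkerEnsemble(n_walkers=n, step=step, positions=out[:n], seed=seed)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _watson_unit_vectors(rng: np.random.Generator, n: int,
                         kappa_w: float) -> np.ndarray:
    """Watson-distributed axes about z, by rejection on cos(theta)."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        z = rng.uniform(-1.0, 1.0, size=4 * n)
        keep = rng.uniform(0.0, 1.0, size=4 * n) < np.exp(kappa_w * (z * z - 1.0))
        z = z[keep][: n - filled]
        phi = rng.uniform(0.0, 2.0 * np.pi, size=z.size)
        s = np.sqrt(1.0 - z * z)
        out[filled:filled + z.size] = np.stack(
            [s * np.cos(phi), s * np.sin(phi), z], axis=1)
        filled += z.size
    return out


def _segment_candidates(p0: np.ndarray, d: np.ndarray, substrate: Substrate):
    """Boundary-crossing parameters t in (0, 1] along p0 + t*d per primitive.

    Returns (ts, kinds, prim) with ts shape (m, K): kinds 0=sphere,
    1=cylinder side, 2=cap at h=0, 3=cap at h=L; non-crossings are +inf.
    """
    m = p0.shape[0]
    ts, kinds, prims = [], [], []

    def push(t, kind, prim):
        ts.append(t)
        kinds.append(kind)
        prims.append(prim)

    for si, c in enumerate(substrate.spheres):
        w = p0 - c[:3]
        a = np.sum(d * d, axis=1)
        bq = 2.0 * np.sum(w * d, axis=1)
        cq = np.sum(w * w, axis=1) - c[3] ** 2
        disc = bq * bq - 4.0 * a * cq
        sq = np.sqrt(np.clip(disc, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-bq - sq) / (2.0 * a)
            t2 = (-bq + sq) / (2.0 * a)
        bad = disc <= 0
        t1 = np.where(bad, np.inf, t1)
        t2 = np.where(bad, np.inf, t2)
        push(t1, 0, si)
        push(t2, 0, si)

    for ci, c in enumerate(substrate.cylinders):
        base, axis, R, L = c[:3], c[3:6], c[6], c[7]
        w = p0 - base
        h0 = w @ axis
        hd = d @ axis
        wp = w - h0[:, None] * axis
        dp = d - hd[:, None] * axis
        a = np.sum(dp * dp, axis=1)
        bq = 2.0 * np.sum(wp * dp, axis=1)
        cq = np.sum(wp * wp, axis=1) - R ** 2
        disc = bq * bq - 4.0 * a * cq
        sq = np.sqrt(np.clip(disc, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-bq - sq) / (2.0 * a)
            t2 = (-bq + sq) / (2.0 * a)
        bad = (disc <= 0) | (a < 1e-300)
        t1 = np.where(bad, np.inf, t1)
        t2 = np.where(bad, np.inf, t2)
        push(t1, 1, ci)
        push(t2, 1, ci)
        if np.isfinite(L):
            with np.errstate(divide="ignore", invalid="ignore"):
                tc0 = np.where(np.abs(hd) > 1e-300, (0.0 - h0) / hd, np.inf)
                tcL = np.where(np.abs(hd) > 1e-300, (L - h0) / hd, np.inf)
            push(tc0, 2, ci)
            push(tcL, 3, ci)

    ts = np.stack(ts, axis=1)
    ts = np.where((ts > _EXIT_EPS) & (ts <= 1.0 + _EXIT_EPS), ts, np.inf)
    return ts, np.asarray(kinds), np.asarray(prims)


def _exit_normal(x: np.ndarray, kind: int, prim: int,
                 substrate: Substrate) -> np.ndarray:
    if kind == 0:
        c = substrate.spheres[prim]
        n = x - c[:3]
        return n / np.linalg.norm(n, axis=-1, keepdims=True)
    c = substrate.cylinders[prim]
    base, axis = c[:3], c[3:6]
    if kind == 1:
        w = x - base
        h = w @ axis
        n = w - h[..., None] * axis
        return n / np.maximum(np.linalg.norm(n, axis=-1, keepdims=True), 1e-300)
    if kind == 2:
        return np.broadcast_to(-axis, x.shape).copy()
    return np.broadcast_to(axis, x.shape).copy()


def _reflect_move(pos: np.ndarray, disp: np.ndarray,
                  substrate: Substrate) -> np.ndarray:
    """Advance walkers by disp with specular reflection at the union boundary."""
    new = pos + disp
    outside = ~substrate.contains(new)
    if not np.any(outside):
        return new
    idx = np.flatnonzero(outside)
    p = pos[idx].copy()
    d = disp[idx].copy()
    active = np.arange(idx.size)
    for _ in range(_MAX_BOUNCES):
        if active.size == 0:
            break
        ts, kinds, prims = _segment_candidates(p[active], d[active], substrate)
        order = np.argsort(ts, axis=1)
        ts_sorted = np.take_along_axis(ts, order, axis=1)
        resolved_t = np.full(active.size, np.nan)
        resolved_cand = np.full(active.size, -1, dtype=int)
        pending = np.arange(active.size)
        for col in range(ts_sorted.shape[1]):
            if pending.size == 0:
                break
            tcol = ts_sorted[pending, col]
            finite = np.isfinite(tcol)
            if not np.any(finite):
                break
            sel = pending[finite]
            tsel = tcol[finite]
            pts_after = p[active[sel]] + (tsel + _EXIT_EPS)[:, None] * d[active[sel]]
            pts_before = p[active[sel]] + (tsel - _EXIT_EPS)[:, None] * d[active[sel]]
            is_exit = (~substrate.contains(pts_after)) & substrate.contains(pts_before)
            hit = sel[is_exit]
            resolved_t[hit] = tsel[is_exit]
            resolved_cand[hit] = order[hit, col]
            pending = np.setdiff1d(pending, hit, assume_unique=True)
        # walkers with no resolvable exit: cancel the move (stay put)
        unresolved = np.isnan(resolved_t)
        if np.any(unresolved):
            stay = active[unresolved]
            d[stay] = 0.0
        act2 = active[~unresolved]
        if act2.size:
            t_star = resolved_t[~unresolved]
            cand = resolved_cand[~unresolved]
            x_star = p[act2] + t_star[:, None] * d[act2]
            normals = np.empty_like(x_star)
            key = kinds[cand] * 1000 + prims[cand]
            for uk in np.unique(key):
                mask = key == uk
                kind, prim = int(uk // 1000), int(uk % 1000)
                normals[mask] = _exit_normal(x_star[mask], kind, prim, substrate)
            v_rem = (1.0 - t_star)[:, None] * d[act2]
            v_ref = v_rem - 2.0 * np.sum(v_rem * normals, axis=1)[:, None] * normals
            p[act2] = x_star - 1e-7 * normals
            d[act2] = v_ref
        else:
            d[active] = 0.0
        endpoint = p[active] + d[active]
        still_out = ~substrate.contains(endpoint)
        done = active[~still_out]
        p[done] = endpoint[~still_out]
        d[done] = 0.0
        active = active[still_out]
    if active.size:
        # residual escapers after max bounces: drop the remaining displacement
        d[active] = 0.0
    new[idx] = p + d
    # final safety clamp: never leave the union
    bad = ~substrate.contains(new[idx])
    if np.any(bad):
        new[idx[bad]] = pos[idx[bad]]
    return new


def walk(ensemble: WalkerEnsemble, substrate: Substrate | None, D0: float,
         duration: float, dt: float | None = None) -> np.ndarray:
    """Simulate the random walk; returns trajectories (n_steps+1, n, 3).

    ``dt`` defaults to ``step**2 / (6 * D0)`` (Einstein relation for the
    fixed step length); if given it must match that value.  ``substrate``
    None means unrestricted diffusion.  Deterministic given the ensemble
    seed.  Trajectories are float32 to bound memory.
    """
    if D0 <= 0:
        raise ValueError("D0 must be > 0")
    dt_nat = ensemble.step ** 2 / (6.0 * D0)
    if dt is None:
        dt = dt_nat
    elif abs(dt - dt_nat) > 1e-9 * dt_nat:
        raise ValueError(
            f"dt must equal step**2/(6*D0) = {dt_nat:.6g} ms for fixed-length steps")
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(ensemble.seed + 1)
    pos = ensemble.positions.copy()
    traj = np.empty((n_steps + 1, ensemble.n_walkers, 3), dtype=np.float32)
    traj[0] = pos
    for i in range(n_steps):
        disp = ensemble.step * _random_unit_vectors(rng, ensemble.n_walkers)
        pos = pos + disp if substrate is None else _reflect_move(pos, disp, substrate)
        traj[i + 1] = pos
    return traj


# ---------------------------------------------------------------------------
# PGSE signal synthesis
# ---------------------------------------------------------------------------

def _pulse_windows(delta: float, Delta: float, dt: float,
                   n_samples: int) -> np.ndarray:
    """Waveform sign f_i at sample times i*dt (ideal rectangular PGSE)."""
    n_d = int(round(delta / dt))
    n_D = int(round(Delta / dt))
    if n_D + n_d > n_samples:
        raise ValueError("trajectory shorter than Delta + delta")
    f = np.zeros(n_samples)
    f[:n_d] = 1.0
    f[n_D:n_D + n_d] = -1.0
    return f


def discrete_bvalue(grad: PulsedGradient, dt: float,
                    n_samples: int | None = None) -> float:
    """b-value of the discretized rectangular waveform used in phase accrual.

    Matches the variance of the accumulated phase for Gaussian diffusion, so
    free-diffusion Monte Carlo signals are compared against
    ``exp(-discrete_bvalue * D0)`` without discretization bias.
    """
    if n_samples is None:
        n_samples = int(round((grad.Delta + grad.delta) / dt)) + 1
    f = _pulse_windows(grad.delta, grad.Delta, dt, n_samples)
    tails = np.cumsum(f[::-1])[::-1]  # T_k = sum_{i >= k} f_i
    gamma_g = sm_mod._GAMMA * grad.g
    return float(gamma_g ** 2 * dt ** 3 * np.sum(tails[1:] ** 2))


def pgse_signal(trajectories: np.ndarray, grads: list[PulsedGradient],
                dt: float) -> np.ndarray:
    """Per-gradient signals from stored trajectories.

    Phase: ``phi = gamma * g * sum_t f(t) * (u . x(t)) * dt`` with the
    bipolar rectangular waveform; signal = mean over walkers of cos(phi).
    """
    traj = np.asarray(trajectories)
    n_samples = traj.shape[0]
    cache: dict[tuple[float, float], np.ndarray] = {}
    out = np.empty(len(grads))
    for k, grad in enumerate(grads):
        key = (grad.delta, grad.Delta)
        if key not in cache:
            f = _pulse_windows(grad.delta, grad.Delta, dt, n_samples)
            nz = np.flatnonzero(f)
            acc = np.tensordot(f[nz], traj[nz].astype(np.float64), axes=(0, 0)) * dt
            cache[key] = acc  # (n, 3) integral of f(t) x(t) dt
        if grad.direction is None:
            raise ValueError("pgse_signal requires gradients with directions")
        phi = sm_mod._GAMMA * grad.g * (cache[key] @ np.asarray(grad.direction))
        out[k] = np.mean(np.cos(phi))
    return out


def pgse_phase_integrals(substrate: Substrate | None, n_walkers: int,
                         D0: float, delta: float, Delta: float, seed: int,
                         step: float = DEFAULT_STEP) -> tuple[np.ndarray, float]:
    """Walk online and accumulate ``A = sum_t f(t) x(t) dt`` per walker.

    Memory-light alternative to storing trajectories: any gradient amplitude
    and direction sharing these timings derives its phase as
    ``phi = gamma * g * (A . u)``.  Returns (A, dt).
    """
    if substrate is None:
        ens = WalkerEnsemble(n_walkers=n_walkers, step=step,
                             positions=np.zeros((n_walkers, 3)), seed=seed)
    else:
        ens = seed_walkers(substrate, n_walkers, seed, step=step)
    dt = step ** 2 / (6.0 * D0)
    n_steps = int(round((Delta + delta) / dt))
    f = _pulse_windows(delta, Delta, dt, n_steps + 1)
    rng = np.random.default_rng(ens.seed + 1)
    pos = ens.positions.copy()
    acc = np.zeros((n_walkers, 3))
    if f[0]:
        acc += f[0] * pos * dt
    for i in range(n_steps):
        disp = step * _random_unit_vectors(rng, n_walkers)
        pos = pos + disp if substrate is None else _reflect_move(pos, disp, substrate)
        if f[i + 1]:
            acc += f[i + 1] * pos * dt
    return acc, dt


def signals_from_phase_integrals(acc: np.ndarray,
                                 grads: list[PulsedGradient]) -> np.ndarray:
    """Per-gradient mean cos(phase) from accumulated phase integrals."""
    out = np.empty(len(grads))
    for k, grad in enumerate(grads):
        phi = sm_mod._GAMMA * grad.g * (acc @ np.asarray(grad.direction))
        out[k] = np.mean(np.cos(phi))
    return out


def simulate_pgse(substrate: Substrate | None, grads: list[PulsedGradient],
                  n_walkers: int, D0: float, seed: int,
                  step: float = DEFAULT_STEP,
                  return_se: bool = False):
    """Monte Carlo PGSE signals for a list of gradients with shared timings."""
    timings = {(g.delta, g.Delta) for g in grads}
    if len(timings) != 1:
        raise ValueError("simulate_pgse requires gradients with shared timings")
    (delta, Delta), = timings
    acc, _ = pgse_phase_integrals(substrate, n_walkers, D0, delta, Delta,
                                  seed, step=step)
    sig = signals_from_phase_integrals(acc, grads)
    if not return_se:
        return sig
    se = np.empty(len(grads))
    for k, grad in enumerate(grads):
        phi = sm_mod._GAMMA * grad.g * (acc @ np.asarray(grad.direction))
        se[k] = np.std(np.cos(phi)) / np.sqrt(n_walkers)
    return sig, se


# ---------------------------------------------------------------------------
# dispersed analytic axon compartment (Watson ODF)
# ---------------------------------------------------------------------------

def _watson_p2(kappa_w: float) -> float:
    if kappa_w == 0:
        return 0.0
    # factor out exp(kappa_w) for numerical stability at large concentration
    num = integrate.quad(
        lambda x: 0.5 * (3 * x * x - 1) * np.exp(kappa_w * (x * x - 1.0)),
        0.0, 1.0)[0]
    den = integrate.quad(lambda x: np.exp(kappa_w * (x * x - 1.0)), 0.0, 1.0)[0]
    return num / den


def watson_concentration(p2: float) -> float:
    """Watson concentration whose orientation distribution has this p2."""
    if not 0 <= p2 < 1:
        raise ValueError("p2 must be in [0, 1) for a Watson ODF")
    if p2 == 0:
        return 0.0
    return optimize.brentq(lambda k: _watson_p2(k) - p2, 1e-6, 2000.0)


def watson_odf_weights(grid: np.ndarray, mu: np.ndarray,
                       kappa_w: float) -> np.ndarray:
    """Self-normalized Watson ODF weights on a quadrature grid."""
    w = np.exp(kappa_w * (grid @ mu) ** 2)
    return w / w.sum()


def dispersed_cylinder_signal(r: float, params: TissueParams,
                              grads: list[PulsedGradient],
                              directions: np.ndarray,
                              mu=(0.0, 0.0, 1.0),
                              model: str = "neumann",
                              n_grid: int = 2000) -> np.ndarray:
    """Directional signals of a Watson-dispersed set of restricted cylinders.

    The Watson concentration is matched so that the ODF's second Legendre
    moment equals ``params.p2``; the directional axon kernel is averaged over
    the ODF by quadrature on a spherical-Fibonacci grid.  Shape:
    (len(grads), n_directions).
    """
    from .synth import uniform_directions  # lazy to avoid import cycle

    if r != params.r:
        params = TissueParams(f=params.f, Dpar=params.Dpar, p2=params.p2,
                              D0=params.D0, r=r)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if params.p2 >= 1.0 - 1e-12:
        out = np.stack([
            axon_kernel(g.with_amplitude(g.g), directions @ mu, params, model=model)
            for g in grads])
        return out
    kappa_w = watson_concentration(params.p2)
    grid = uniform_directions(n_grid, seed=0)
    weights = watson_odf_weights(grid, mu, kappa_w)
    cosine = directions @ grid.T  # (n_dir, n_grid)
    out = np.empty((len(grads), directions.shape[0]))
    for k, g in enumerate(grads):
        kern = axon_kernel(g, cosine, params, model=model)
        out[k] = kern @ weights
    return out


# ---------------------------------------------------------------------------
# glia-fraction experiment
# ---------------------------------------------------------------------------

def glia_mixture_experiment(axon_r: float, glia_substrates: list[Substrate],
                            fractions, protocol=None, seed: int = 0,
                            n_walkers: int = 10_000, D0: float = 2.5,
                            p2: float = 0.7, lmax: int = 6,
                            model: str = "neumann",
                            step: float = DEFAULT_STEP,
                            shell_bs=(6.0, 30.0),
                            n_se_groups: int = 8) -> pd.DataFrame:
    """Bias of SM/SV effective radii versus glia signal fraction.

    Axonal signal: analytic Watson-dispersed restricted cylinders
    (coherence ``p2``).  Glia signal: Monte Carlo walkers inside each
    substrate, averaged across substrates.  Per fraction f_g the total
    signal ``(1 - f_g) * axon + f_g * glia`` is decomposed per shell and
    both log-linear estimators are applied with ``Dpar = D0``.

    Returns a DataFrame with columns fraction, r_sm, r_sv, se_sm, se_sv.
    """
    from .synth import paper_protocol

    fractions = np.atleast_1d(np.asarray(fractions, dtype=float))
    if np.any((fractions < 0) | (fractions >= 1)):
        raise ValueError("fractions must lie in [0, 1)")
    if protocol is None:
        protocol = paper_protocol()
    shells = [s for s in protocol.shells if any(np.isclose(s.b, b) for b in shell_bs)]
    if len(shells) != 2:
        raise ValueError("protocol must contain exactly the two requested shells")
    params = TissueParams(f=1.0, Dpar=D0, p2=p2, D0=D0, r=axon_r)

    axon, glia, grads = {}, {}, {}
    groups: dict[float, np.ndarray] = {}
    for shell in shells:
        dirs = shell.directions
        grads[shell.b] = shell.grad
        axon[shell.b] = dispersed_cylinder_signal(
            axon_r, params, [shell.grad], dirs, model=model)[0]
        if fractions.max() > 0 and glia_substrates:
            per_sub = []
            per_sub_groups = []
            for si, sub in enumerate(glia_substrates):
                acc, _ = pgse_phase_integrals(sub, n_walkers, D0,
                                              shell.grad.delta, shell.grad.Delta,
                                              seed + 101 * si, step=step)
                cosphi = np.cos(sm_mod._GAMMA * shell.grad.g
                                * (acc @ dirs.T))  # (n_walkers, n_dirs)
                per_sub.append(cosphi.mean(axis=0))
                splits = np.array_split(cosphi, n_se_groups, axis=0)
                per_sub_groups.append(np.stack([s.mean(axis=0) for s in splits]))
            glia[shell.b] = np.mean(per_sub, axis=0)
            groups[shell.b] = np.mean(per_sub_groups, axis=0)
        else:
            glia[shell.b] = np.zeros(len(dirs))
            groups[shell.b] = np.zeros((n_se_groups, len(dirs)))

    def radii_for(glia_signals: dict[float, np.ndarray], f_g: float):
        feats = []
        for shell in shells:
            mix = (1.0 - f_g) * axon[shell.b] + f_g * glia_signals[shell.b]
            coeffs = fit_sh_ls(shell.directions, mix, lmax=lmax)
            feats.append(rish_features(coeffs, s0_ref=1.0, b=shell.b,
                                       grad=shell.grad))
        from .estimators import loglinear_radius_sm, loglinear_radius_sv

        pair = (grads[shells[0].b], grads[shells[1].b])
        est_sm = loglinear_radius_sm(feats[0], feats[1], pair, D0)
        est_sv = loglinear_radius_sv(feats[0], feats[1], pair, D0, D0)
        return float(np.asarray(est_sm.r_sm)), float(np.asarray(est_sv.r_sv))

    rows = []
    for f_g in fractions:
        r_sm, r_sv = radii_for(glia, f_g)
        if f_g > 0:
            grp = np.array([
                radii_for({b: groups[b][k] for b in groups}, f_g)
                for k in range(n_se_groups)])
            se_sm = float(np.nanstd(grp[:, 0]) / np.sqrt(n_se_groups))
            se_sv = float(np.nanstd(grp[:, 1]) / np.sqrt(n_se_groups))
        else:
            se_sm = se_sv = 0.0
        rows.append({"fraction": f_g, "r_sm": r_sm, "r_sv": r_sv,
                     "se_sm": se_sm, "se_sv": se_sv})
    return pd.DataFrame(rows)
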