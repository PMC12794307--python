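"""Synthetic acquisition and phantom generation.

Emulates a strong-gradient multi-shell PGSE protocol (five shells at
b = 0.5/1/2.5/6/30 ms/um^2 with 30/30/30/120/240 uniform directions,
Delta/delta = 30/15 ms, maximum gradient 273 mT/m) and voxel signals from
Watson-dispersed restricted cylinders plus optional glia-like compartments,
under Rician magnitude noise.  Everything is deterministic given the seeds,
so the full pipeline (synthesize -> RISH -> estimate) is testable without
any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .signal_models import (
    PulsedGradient,
    TissueParams,
    compute_bvalue,
    gradient_for_bvalue,
    vangelderen_sphere,
)

__all__ = [
    "ShellSpec",
    "ProtocolSpec",
    "PhantomSpec",
    "paper_protocol",
    "uniform_directions",
    "add_rician_noise",
    "synthesize_voxel",
    "default_phantom",
    "synthesize_phantom",
    "save_phantom",
]

#: default protocol constants
PROTOCOL_BVALUES = (0.5, 1.0, 2.5, 6.0, 30.0)
PROTOCOL_NDIRS = (30, 30, 30, 120, 240)
PROTOCOL_DELTA = 15.0  # pulse duration, ms
PROTOCOL_DELTA_SEP = 30.0  # pulse separation, ms
PROTOCOL_N_B0 = 23


@dataclass
class ShellSpec:
    b: float
    n_directions: int
    grad: PulsedGradient
    directions: np.ndarray = None

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.b > 0 and self.n_directions < 6:
            raise ValueError("fitted shells need at least 6 directions")
        if self.directions is None:
            self.directions = uniform_directions(self.n_directions,
                                                 seed=int(round(10 * self.b)))
        self.directions = np.asarray(self.directions, dtype=float)


@dataclass
class ProtocolSpec:
    shells: list[ShellSpec]
    n_b0: int = PROTOCOL_N_B0

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + sum(s.n_directions for s in self.shells)


def paper_protocol(delta: float = PROTOCOL_DELTA,
                   Delta: float = PROTOCOL_DELTA_SEP) -> ProtocolSpec:
    """The five-shell strong-gradient protocol.

    Gradient amplitudes are back-computed from the shell b-values at the
    fixed timings; the strongest shell (b = 30 ms/um^2) lands at 273 mT/m.
    """
    shells = []
    for b, n in zip(PROTOCOL_BVALUES, PROTOCOL_NDIRS):
        grad = gradient_for_bvalue(b, delta, Delta)
        shells.append(ShellSpec(b=b, n_directions=n, grad=grad))
    return ProtocolSpec(shells=shells, n_b0=PROTOCOL_N_B0)


def uniform_directions(n: int, seed: int = 0) -> np.ndarray:
    """Deterministic near-uniform unit vectors (spherical Fibonacci set).

    The set is rotated by a seed-derived random rotation so that different
    seeds give different (but equally uniform) frames.  Directions are
    antipodally unique; for even-order SH fitting the hemisphere convention
    is irrelevant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    rng = np.random.default_rng(seed)
    # random rotation: QR of a Gaussian matrix with sign fix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return pts @ q.T


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex signal plus 2-channel Gaussian noise."""
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


@dataclass
class PhantomSpec:
    """Grid phantom: per-voxel tissue parameters and glia mixing."""

    shape: tuple[int, int, int]
    radius: np.ndarray        # (X, Y, Z) cylinder radius, um
    glia_fraction: np.ndarray  # (X, Y, Z) in [0, 1)
    glia_kind: np.ndarray      # (X, Y, Z) of {"none", "process", "sphere"}
    f: float = 1.0
    Dpar: float = 2.5
    p2: float = 0.7
    D0: float = 2.5
    snr: float = 50.0
    seed: int = 0
    process_radius: float = 1.5
    sphere_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be > 0")
        for name in ("radius", "glia_fraction", "glia_kind"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != tuple(self.shape):
                raise ValueError(f"{name} does not match phantom shape")
        if np.any((self.glia_fraction < 0) | (self.glia_fraction >= 1)):
            raise ValueError("glia fractions must lie in [0, 1)")


def default_phantom(snr: float = 50.0, seed: int = 0) -> PhantomSpec:
    """10 x 10 x 3 grid: radius 1..5 um by glia fraction 0..0.5 by glia kind."""
    shape = (10, 10, 3)
    r = np.linspace(1.0, 5.0, 10)[:, None, None] * np.ones(shape)
    fg = np.linspace(0.0, 0.5, 10)[None, :, None] * np.ones(shape)
    kind = np.empty(shape, dtype=object)
    kind[:, :, 0] = "none"
    kind[:, :, 1] = "process"
    kind[:, :, 2] = "sphere"
    fg[:, :, 0] = 0.0
    return PhantomSpec(shape=shape, radius=r, glia_fraction=fg, glia_kind=kind,
                       snr=snr, seed=seed)


def _glia_attenuation(kind: str, phantom: PhantomSpec, shell, model="neumann"):
    """Per-direction glia compartment attenuation on one shell."""
    from .mcsim import dispersed_cylinder_signal  # lazy to avoid import cycle

    if kind == "process":
        params = TissueParams(f=1.0, Dpar=phantom.D0, p2=0.0, D0=phantom.D0,
                              r=phantom.process_radius)
        return dispersed_cylinder_signal(phantom.process_radius, params,
                                         [shell.grad], shell.directions,
                                         model=model)[0]
    if kind == "sphere":
        val = vangelderen_sphere(phantom.sphere_radius, shell.grad, phantom.D0)
        return np.full(shell.n_directions, val)
    raise ValueError(f"unknown glia kind {kind!r}")


def synthesize_voxel(params: TissueParams, protocol: ProtocolSpec,
                     seed: int, snr: float = np.inf,
                     glia_fraction: float = 0.0, glia_kind: str = "none",
                     model: str = "neumann", phantom: PhantomSpec | None = None):
    """Noisy multi-shell signals of one voxel.

    Noiseless per-direction mixture of the dispersed-cylinder axon
    compartment and an optional glia compartment, then Rician noise with
    ``sigma = 1/snr`` (signals are normalized so the b=0 signal is 1).

    Returns (shell_data, b0_signals) where shell_data is a list of
    :class:`axonradius.rish.ShellData`.
    """
    from .mcsim import dispersed_cylinder_signal
    from .rish import ShellData

    rng = np.random.default_rng(seed)
    sigma = 0.0 if np.isinf(snr) else 1.0 / snr
    shells_out = []
    for shell in protocol.shells:
        axon = dispersed_cylinder_signal(params.r, params, [shell.grad],
                                         shell.directions, model=model)[0]
        if glia_fraction > 0 and glia_kind != "none":
            if phantom is None:
                phantom = default_phantom()
            glia = _glia_attenuation(glia_kind, phantom, shell, model=model)
            clean = (1.0 - glia_fraction) * axon + glia_fraction * glia
        else:
            clean = axon
        noisy = add_rician_noise(clean, sigma, rng)
        shells_out.append(ShellData(b=shell.b, grad=shell.grad,
                                    directions=shell.directions,
                                    signals=noisy, sigma=max(sigma, 1e-12)))
    b0 = add_rician_noise(np.ones(protocol.n_b0), sigma, rng)
    return shells_out, b0


def synthesize_phantom(phantom: PhantomSpec, protocol: ProtocolSpec | None = None,
                       model: str = "neumann"):
    """4-D DWI array + gradient table for a grid phantom.

    Returns (dwi, bvals, bvecs, truth) with dwi of shape
    phantom.shape + (n_volumes,), bvals in ms/um^2, bvecs (N, 3), and a
    ground-truth dict (JSON-serializable).
    """
    if protocol is None:
        protocol = paper_protocol()
    from .mcsim import dispersed_cylinder_signal

    bvals = [0.0] * protocol.n_b0
    bvecs = [np.zeros(3)] * protocol.n_b0
    for shell in protocol.shells:
        bvals.extend([shell.b] * shell.n_directions)
        bvecs.extend(list(shell.directions))
    bvals = np.asarray(bvals)
    bvecs = np.asarray(bvecs)

    rng = np.random.default_rng(phantom.seed)
    sigma = 1.0 / phantom.snr
    dwi = np.empty(tuple(phantom.shape) + (bvals.size,))

    # cache noiseless compartment signals per unique (radius, kind)
    axon_cache: dict[float, list[np.ndarray]] = {}
    glia_cache: dict[str, list[np.ndarray]] = {}

    def axon_for(r: float):
        if r not in axon_cache:
            params = TissueParams(f=phantom.f, Dpar=phantom.Dpar, p2=phantom.p2,
                                  D0=phantom.D0, r=r)
            axon_cache[r] = [dispersed_cylinder_signal(r, params, [s.grad],
                                                       s.directions, model=model)[0]
                             for s in protocol.shells]
        return axon_cache[r]

    def glia_for(kind: str):
        if kind not in glia_cache:
            glia_cache[kind] = [_glia_attenuation(kind, phantom, s, model=model)
                                for s in protocol.shells]
        return glia_cache[kind]

    for vox in np.ndindex(tuple(phantom.shape)):
        r = float(phantom.radius[vox])
        fg = float(phantom.glia_fraction[vox])
        kind = str(phantom.glia_kind[vox])
        per_shell = axon_for(r)
        clean = [np.ones(protocol.n_b0)]
        for k, shell in enumerate(protocol.shells):
            sig = per_shell[k]
            if fg > 0 and kind != "none":
                sig = (1.0 - fg) * sig + fg * glia_for(kind)[k]
            clean.append(sig)
        clean = np.concatenate(clean)
        dwi[vox] = add_rician_noise(clean, sigma, rng)

    truth = {
        "radius": np.asarray(phantom.radius).tolist(),
        "glia_fraction": np.asarray(phantom.glia_fraction).tolist(),
        "glia_kind": np.asarray(phantom.glia_kind).astype(str).tolist(),
        "f": phantom.f, "Dpar": phantom.Dpar, "p2": phantom.p2,
        "D0": phantom.D0, "snr": phantom.snr, "seed": phantom.seed,
        "sigma": sigma,
        "shells": [{"b": s.b, "n_directions": s.n_directions, "g": s.grad.g,
                    "delta": s.grad.delta, "Delta": s.grad.Delta}
                   for s in protocol.shells],
    }
    return dwi, bvals, bvecs, truth


def save_phantom(prefix: str, dwi: np.ndarray, bvals: np.ndarray,
                 bvecs: np.ndarray, truth: dict) -> dict[str, str]:
    """Write NIfTI + FSL bval/bvec (s/mm^2 convention) + JSON sidecar."""
    import nibabel as nib

    paths = {
        "dwi": f"{prefix}_dwi.nii.gz",
        "bval": f"{prefix}.bval",
        "bvec": f"{prefix}.bvec",
        "truth": f"{prefix}_truth.json",
    }
    img = nib.Nifti1Image(np.asarray(dwi, dtype=np.float32), affine=np.eye(4))
    nib.save(img, paths["dwi"])
    np.savetxt(paths["bval"], (np.asarray(bvals) * 1000.0)[None, :], fmt="%.1f")
    np.savetxt(paths["bvec"], np.asarray(bvecs).T, fmt="%.8f")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
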