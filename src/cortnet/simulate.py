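"""Stochastic simulation of cortical-column networks in the complexified state.

The second-order neural-mass equations for each population,

    dp_i/dt = -omega_i^2 q_i + eps*omega_i^2 sum_j s_ij S(q_j)
              + p_scale*omega_i^2 sum_j p_ij P(p_j/omega_j),
    dq_i/dt = p_i,

become a single first-order complex equation under z = q + i p/omega:

    dz_i/dt = -i omega_i z_i + i eps omega_i sum_j s_ij S((z_j+z_j*)/2)
              + i p_scale omega_i sum_j p_ij P((z_j-z_j*)/2i),

so free oscillation is rigid clockwise rotation of z and the amplitude
R = |z| and phase phi = arg z are immediate.  Extrinsic coupling between
homologous layers of different columns enters as i*h*D(Im z_driver) with
the normalized linear drive kernel D(y) = -2y/R_s, which puts h directly
in amplitude-per-time (drift-rate) units (see :mod:`cortnet.reduction`).

Integration is fixed-step Euler–Maruyama with additive complex Gaussian
noise; each trial of a batch draws its noise from its own spawned
generator so any single trial is reproducible in isolation.
"""

from __future__ import annotations

import numpy as np

from .reduction import limit_cycle_amplitudes
from .specs import NetworkSpec, SimConfig, Trajectory

__all__ = [
    "complexify",
    "decomplexify",
    "network_rhs",
    "simulate",
    "simulate_batch",
    "clamp_phase",
    "amplitude_phase",
    "BlowUpError",
    "resolve_r_s_ref",
]


class BlowUpError(RuntimeError):
    """Raised when the integration diverges past the configured bound."""

    def __init__(self, t: float, max_abs: float):
        self.t = t
        self.max_abs = max_abs
        super().__init__(
            f"simulation blew up at t={t:.6g} (max |z| = {max_abs:.3g})"
        )


def complexify(q: float | np.ndarray, p: float | np.ndarray,
               omega: float | np.ndarray) -> complex | np.ndarray:
    """Combine current and potential variables into z = q + i p/omega."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0) or not np.isfinite(omega).all():
        raise ValueError("omega must be finite and > 0")
    z = np.asarray(q, dtype=float) + 1j * np.asarray(p, dtype=float) / omega
    return complex(z) if np.ndim(z) == 0 else z

def decomplexify(z: complex | np.ndarray,
                 omega: float | np.ndarray) -> tuple:
    """Recover (q, p) = (Re z, omega * Im z) exactly."""
    z = np.asarray(z, dtype=complex)
    q, p = z.real, np.asarray(omega, dtype=float) * z.imag
    if z.ndim == 0:
        return float(q), float(p)
    return q, p


def resolve_r_s_ref(net: NetworkSpec) -> float:
    """Reference limit-cycle amplitude normalizing the extrinsic drive."""
    if net.r_s_ref is not None:
        return float(net.r_s_ref)
    cycles = limit_cycle_amplitudes(net.columns[0].kernel)
    if cycles.size == 0:
        if np.any(net.h != 0):
            raise ValueError(
                "network has extrinsic coupling but the kernel admits no "
                "limit cycle; set r_s_ref explicitly"
            )
        return 1.0
    return float(cycles[-1])


def network_rhs(z: np.ndarray, net: NetworkSpec,
                r_s_ref: float | None = None) -> np.ndarray:
    """Complexified drift dz/dt for state ``z`` of shape (..., n_cols, n_layers)."""
    z = np.asarray(z, dtype=complex)
    squeeze = False
    if z.ndim == 2:
        z = z[None]
        squeeze = True
    if z.shape[-2:] != (net.n_columns, net.n_layers):
        raise ValueError(
            f"state must have shape (..., {net.n_columns}, {net.n_layers}), "
            f"got {z.shape}"
        )
    if r_s_ref is None:
        r_s_ref = resolve_r_s_ref(net)

    dz = np.empty_like(z)
    for c, col in enumerate(net.columns):
        zc = z[:, c, :]                      # (batch, n_layers)
        om = col.omegas[None, :]
        out = -1j * om * zc
        if col.eps != 0.0:
            Sq = col.kernel.S(zc.real)
            out = out + 1j * col.eps * om * (Sq @ col.s_mat.T)
        if col.p_scale != 0.0:
            Pp = col.kernel.P(zc.imag)
            out = out + 1j * col.p_scale * om * (Pp @ col.p_mat.T)
        dz[:, c, :] = out
    if np.any(net.h != 0):
        drive = -2.0 * z.imag / r_s_ref      # D(Im z), (batch, n_cols, n_layers)
        dz += 1j * np.einsum("lck,bkl->bcl", net.h, drive)
    return dz[0] if squeeze else dz


def clamp_phase(z: np.ndarray, driver_col: int, driven_col: int,
                delta_phi: float) -> np.ndarray:
    """Reset the driven column's phase to (driver phase - delta_phi) per layer.

    Amplitudes are untouched; applying the clamp twice equals applying it
    once.  Phase convention: phi = arg z, delta_phi = phi_driver -
    phi_driven.
    """
    z = np.asarray(z, dtype=complex).copy()
    n_cols = z.shape[-2]
    for idx in (driver_col, driven_col):
        if not 0 <= idx < n_cols:
            raise IndexError(f"column index {idx} out of range for {n_cols} columns")
    drv = z[..., driver_col, :]
    target = np.where(np.abs(drv) > 0, np.angle(drv), 0.0) - delta_phi
    z[..., driven_col, :] = np.abs(z[..., driven_col, :]) * np.exp(1j * target)
    return z


def _integrate(
    net: NetworkSpec,
    cfg: SimConfig,
    z0: np.ndarray,
    rngs: list[np.random.Generator],
    clamp: tuple[int, int, float] | None = None,
    noise_chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama on a batch of initial states; returns (times, z_rec)."""
    z = np.array(z0, dtype=complex)          # (batch, n_cols, n_layers)
    batch = z.shape[0]
    n_steps = cfg.n_steps
    rec_idx = np.arange(0, n_steps + 1, cfg.record_stride)
    z_rec = np.empty((batch, rec_idx.size) + z.shape[1:], dtype=complex)
    times = rec_idx * cfg.dt
    r_s_ref = resolve_r_s_ref(net)
    sqrt_dt = np.sqrt(cfg.dt)

    if clamp is not None:
        z = clamp_phase(z, *clamp)
    z_rec[:, 0] = z
    rec_ptr = 1
    noise_buf = None
    buf_pos = 0
    for step in range(1, n_steps + 1):
        dz = network_rhs(z, net, r_s_ref)
        z = z + cfg.dt * dz
        if cfg.noise_sigma > 0.0:
            if noise_buf is None or buf_pos >= noise_buf.shape[1]:
                m = min(noise_chunk, n_steps - step + 1)
                noise_buf = np.empty((batch, m) + z.shape[1:], dtype=complex)
                for b, rng in enumerate(rngs):
                    re = rng.standard_normal((m,) + z.shape[1:])
                    im = rng.standard_normal((m,) + z.shape[1:])
                    noise_buf[b] = re + 1j * im
                buf_pos = 0
            z = z + cfg.noise_sigma * sqrt_dt * noise_buf[:, buf_pos]
            buf_pos += 1
        if clamp is not None:
            z = clamp_phase(z, *clamp)
        max_abs = np.abs(z).max()
        if not np.isfinite(max_abs) or max_abs > cfg.blowup:
            raise BlowUpError(step * cfg.dt, float(max_abs))
        if rec_ptr < rec_idx.size and step == rec_idx[rec_ptr]:
            z_rec[:, rec_ptr] = z
            rec_ptr += 1
    return times, z_rec


def simulate(
    net: NetworkSpec,
    cfg: SimConfig,
    initial: np.ndarray,
    clamp: tuple[int, int, float] | None = None,
) -> Trajectory:
    """Integrate one realization of the network; deterministic given cfg.seed.

    ``initial`` has shape (n_columns, n_layers).  With ``clamp =
    (driver_col, driven_col, delta_phi)`` the driven column's phase is
    pinned to the driver's at every step (the fixed-lag numerical
    experiment); with ``noise_sigma = 0`` the scheme reduces to
    deterministic Euler.
    """
    z0 = np.asarray(initial, dtype=complex)
    if z0.shape != (net.n_columns, net.n_layers):
        raise ValueError(
            f"initial must have shape ({net.n_columns}, {net.n_layers}), got {z0.shape}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    times, z_rec = _integrate(net, cfg, z0[None], [rng], clamp)
    return Trajectory(times, z_rec[0])


def simulate_batch(
    net: NetworkSpec,
    cfg: SimConfig,
    initial: np.ndarray,
    n_trials: int,
    clamp: tuple[int, int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``n_trials`` independent noise realizations.

    ``initial`` is either one state of shape (n_cols, n_layers), shared
    by every trial, or a per-trial batch of shape (n_trials, n_cols,
    n_layers).  Returns ``(times, z)`` with z of shape (n_trials,
    n_times, n_cols, n_layers).  Trial k's noise comes from child k of
    ``SeedSequence(cfg.seed)``, so any single trial can be reproduced
    alone.
    """
    z0 = np.asarray(initial, dtype=complex)
    children = np.random.SeedSequence(cfg.seed).spawn(n_trials)
    rngs = [np.random.default_rng(s) for s in children]
    if z0.ndim == 2:
        z0 = np.broadcast_to(z0, (n_trials,) + z0.shape)
    elif z0.shape[0] != n_trials:
        raise ValueError("per-trial initial must have n_trials leading entries")
    return _integrate(net, cfg, z0, rngs, clamp)


def amplitude_phase(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Polar decomposition (R, phi) of a trajectory; phi = 0 at z = 0 by convention."""
    R = np.abs(traj.z)
    phi = np.where(R > 0, np.angle(traj.z), 0.0)
    return R, phi


def write_trajectory_text(traj: Trajectory, path) -> None:
    """Delimited-text trajectory (time, Re/Im per population) at 17 significant digits."""
    n_cols, n_layers = traj.n_columns, traj.n_layers
    header = ["time"]
    for c in range(n_cols):
        for l in range(n_layers):
            header += [f"re_c{c}_l{l}", f"im_c{c}_l{l}"]
    flat = traj.z.reshape(traj.z.shape[0], -1)
    data = np.empty((flat.shape[0], 1 + 2 * flat.shape[1]))
    data[:, 0] = traj.times
    data[:, 1::2] = flat.real
    data[:, 2::2] = flat.imag
    np.savetxt(path, data, delimiter="\t", fmt="%.17g",
               header="\t".join(header), comments="")


def read_trajectory_text(path, n_columns: int, n_layers: int) -> Trajectory:
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    times = data[:, 0]
    z = (data[:, 1::2] + 1j * data[:, 2::2]).reshape(-1, n_columns, n_layers)
    return Trajectory(times, z)


def write_trajectory_npz(traj: Trajectory, path) -> None:
    """Compact binary container for large runs (lossless)."""
    np.savez_compressed(path, times=traj.times, z=traj.z)


def read_trajectory_npz(path) -> Trajectory:
    with np.load(path) as d:
        return Trajectory(d["times"], d["z"])
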