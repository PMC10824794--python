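"""Network and simulation specifications for cortical-column models.

A *column* is an ordered set of neural-mass populations (layers) with
intrinsic potential-to-current (S) and current-to-current (P) coupling.
A *network* is a set of columns with identical layer structure joined by
extrinsic coupling between homologous layers; interactions between
different layer types only enter the perturbation series at second order,
so homologous coupling is the only extrinsic pathway represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec

__all__ = [
    "PopulationSpec",
    "ColumnSpec",
    "NetworkSpec",
    "SimConfig",
    "Trajectory",
]


@dataclass(frozen=True)
class PopulationSpec:
    """A single neural-mass population with intrinsic angular frequency omega (rad/time)."""

    omega: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.omega) or self.omega <= 0:
            raise ValueError(f"omega must be finite and > 0, got {self.omega}")


@dataclass(frozen=True)
class ColumnSpec:
    """One cortical column: populations plus intrinsic S/P coupling.

    ``s_mat``/``p_mat`` are square matrices over the column's populations;
    entries may be positive or negative (synaptic interactions can raise or
    lower the membrane potential). ``eps`` scales the S-coupling and
    ``p_scale`` the P-coupling (the overall coupling strengths of the
    perturbative expansion).
    """

    populations: tuple[PopulationSpec, ...]
    s_mat: np.ndarray
    p_mat: np.ndarray
    eps: float = 0.0
    p_scale: float = 0.0
    kernel: KernelSpec = field(default_factory=KernelSpec)

    def __post_init__(self) -> None:
        n = len(self.populations)
        if n == 0:
            raise ValueError("a column needs at least one population")
        s = np.asarray(self.s_mat, dtype=float)
        p = np.asarray(self.p_mat, dtype=float)
        if s.shape != (n, n) or p.shape != (n, n):
            raise ValueError(
                f"s_mat and p_mat must be {n}x{n}, got {s.shape} and {p.shape}"
            )
        object.__setattr__(self, "s_mat", s)
        object.__setattr__(self, "p_mat", p)
        if self.eps < 0 or self.p_scale < 0:
            raise ValueError("eps and p_scale must be >= 0")

    @property
    def n_layers(self) -> int:
        return len(self.populations)

    @property
    def omegas(self) -> np.ndarray:
        return np.array([p.omega for p in self.populations])


@dataclass(frozen=True)
class NetworkSpec:
    """Columns with identical layer structure plus extrinsic homologous coupling.

    ``h`` has shape ``(n_layers, n_columns, n_columns)``; ``h[l, j, k]`` is
    the coupling from column ``k`` onto column ``j`` at layer ``l``, in
    amplitude-per-time (drift-rate) units: a driver sitting on its limit
    cycle drifts the driven column's mean amplitude at exactly
    ``-h*cos(delta_phi)`` per unit time. The extrinsic drive is a
    normalized linear current-to-current kernel ``D(y) = -2 y / r_s_ref``
    (see :mod:`cortnet.reduction` for the normalization argument).

    If ``cascading`` is set, the directed graph of nonzero ``h`` entries
    must be acyclic: regions recruited later in a seizure do not project
    back onto regions recruited earlier.
    """

    columns: tuple[ColumnSpec, ...]
    h: np.ndarray | None = None
    cascading: bool = False
    r_s_ref: float | None = None

    def __post_init__(self) -> None:
        if len(self.columns) == 0:
            raise ValueError("network needs at least one column")
        n_layers = self.columns[0].n_layers
        for c in self.columns:
            if c.n_layers != n_layers:
                raise ValueError("all columns must have the same number of layers")
        n_cols = len(self.columns)
        if self.h is None:
            h = np.zeros((n_layers, n_cols, n_cols))
        else:
            h = np.asarray(self.h, dtype=float)
            if h.shape == (n_cols, n_cols) and n_layers == 1:
                h = h[None, :, :]
            if h.shape != (n_layers, n_cols, n_cols):
                raise ValueError(
                    f"h must have shape ({n_layers}, {n_cols}, {n_cols}), got {h.shape}"
                )
        if np.any(np.abs(np.diagonal(h, axis1=1, axis2=2)) > 0):
            raise ValueError("h carries extrinsic coupling only: diagonal must be 0")
        object.__setattr__(self, "h", h)
        if self.cascading:
            adj = np.any(h != 0.0, axis=0)  # adj[j, k]: k -> j
            if _has_cycle(adj.T):
                raise ValueError(
                    "cascading network must be acyclic in its column-pair graph"
                )

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_layers(self) -> int:
        return self.columns[0].n_layers

    @property
    def n_total(self) -> int:
        return self.n_columns * self.n_layers


def _has_cycle(adj: np.ndarray) -> bool:
    """Cycle check on adjacency ``adj[k, j]`` meaning an edge k -> j (DFS colouring)."""
    n = adj.shape[0]
    color = np.zeros(n, dtype=int)  # 0 white, 1 grey, 2 black

    def visit(u: int) -> bool:
        color[u] = 1
        for v in np.nonzero(adj[u])[0]:
            if color[v] == 1:
                return True
            if color[v] == 0 and visit(v):
                return True
        color[u] = 2
        return False

    return any(color[u] == 0 and visit(u) for u in range(n))


@dataclass(frozen=True)
class SimConfig:
    """Stochastic-integration settings (fixed-step Euler–Maruyama).

    ``noise_sigma`` is the additive complex-noise amplitude per sqrt(time);
    noise enters on the current variable p (the imaginary part of z),
    scaled into z units. ``blowup`` aborts integration when any |z|
    exceeds it, naming the first offending time.
    """

    dt: float
    t_end: float
    noise_sigma: float = 0.0
    seed: int = 0
    record_stride: int = 1
    blowup: float = 1.0e6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed complexified network state.

    ``z`` has shape ``(n_times, n_columns, n_layers)``. The original
    neural-mass variables are recovered as ``q = Re z`` and
    ``p = omega * Im z``.
    """

    times: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if t.ndim != 1 or z.ndim != 3 or z.shape[0] != t.shape[0]:
            raise ValueError("times must be 1-D and z (n_times, n_columns, n_layers)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(z).all():
            raise ValueError("trajectory contains non-finite samples")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "z", z)

    @property
    def n_columns(self) -> int:
        return self.z.shape[1]

    @property
    def n_layers(self) -> int:
        return self.z.shape[2]
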