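"""Adiabatic (cycle-averaged) reduction of the neural-mass dynamics.

Averaging the complexified equations of motion over one oscillation period
removes the fast rotation and leaves a slow flow for the amplitude
``R = |z|`` of each population.  At first order in the coupling only the
current-to-current (P) kernel survives the average, giving

    dR/dt = omega * p_scale * p_ii * f(R),

where ``f(R)`` is the first-harmonic (resonant) content of the kernel
driven by a sinusoid of amplitude R:

    f(R) = (1/2pi) \\int_0^{2pi} sin(psi) P(R sin(psi)) dpsi.

For the odd-quintic default kernel this is available in closed form,

    f(R) = -c1*R/2 + (3*c3/8)*R**3 - (5*c5/16)*R**5,

whose positive roots are the unstable (R_u) and stable (R_s) limit-cycle
amplitudes of the original oscillator; the root at 0 is the resting fixed
point.  A monotonic (linear) P-kernel has a single stable root at 0 and no
limit cycle at all.

Two coupled columns share one reduced field per layer.  The extrinsic
drive between homologous layers is gated by the phase lag ``delta_phi``
through ``cos(delta_phi)`` and scales with the *driver's* amplitude:

    dR_1/dt = rate_1 * f(R_1) - h_12 * cos(delta_phi) * R_2 / R_s.

The normalization ``A(R) = R / R_s`` (so ``A(R_s) = 1``) is the cycle
average of the network's linear extrinsic drive kernel and makes the drift
of the driven amplitude exactly ``-h*cos(delta_phi)`` when the driver sits
on its limit cycle — the calibration that the downstream propagation model
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize

from .kernels import KernelSpec

__all__ = [
    "cycle_average_pkernel",
    "AmplitudeFlowModel",
    "StationarySet",
    "find_stationary_amplitudes",
    "limit_cycle_amplitudes",
    "coupled_amplitude_field",
    "enumerate_attractors_2d",
    "basin_attractors",
    "trapping_potential",
    "PhasePortrait2D",
]

#: roots with |d(rate f)/dR| below this are flagged degenerate, not classified
DEGENERATE_TOL = 1.0e-8


def _f_closed_form(kernel: KernelSpec, R: np.ndarray) -> np.ndarray:
    c1, c3, c5 = kernel.p_coeffs
    R2 = R * R
    return R * (-c1 / 2.0 + R2 * (3.0 * c3 / 8.0 - 5.0 * c5 / 16.0 * R2))


def cycle_average_pkernel(
    kernel: KernelSpec, R: float | np.ndarray, method: str = "closed_form"
) -> float | np.ndarray:
    """Cycle-averaged amplitude flow f(R) of a P-kernel.

    ``method='closed_form'`` uses the polynomial average (valid while the
    kernel input ``R`` stays inside the saturation bound); ``'quadrature'``
    evaluates the defining integral numerically and honours saturation.
    The two agree to better than 1e-10 inside the saturation range.
    """
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr < 0):
        raise ValueError("amplitude R must be >= 0")
    if method == "closed_form":
        out = _f_closed_form(kernel, R_arr)
    elif method == "quadrature":
        def integrand(psi: float, r: float) -> float:
            return np.sin(psi) * kernel.P(r * np.sin(psi))

        flat = R_arr.ravel()
        vals = np.empty(flat.shape)
        for i, r in enumerate(flat):
            val, _ = integrate.quad(integrand, 0.0, 2.0 * np.pi, args=(r,),
                                    epsabs=1e-13, epsrel=1e-13, limit=200)
            vals[i] = val / (2.0 * np.pi)
        out = vals.reshape(R_arr.shape)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out if np.ndim(R) else float(out)


def limit_cycle_amplitudes(kernel: KernelSpec) -> np.ndarray:
    """Positive roots of f(R) in ascending order (limit-cycle amplitudes).

    For the default kernel this returns ``[R_u, R_s] = [sqrt(2), 2]``.
    """
    c1, c3, c5 = kernel.p_coeffs
    # f(R)/R = -c1/2 + (3 c3/8) x - (5 c5/16) x^2 with x = R^2
    coeffs = [-5.0 * c5 / 16.0, 3.0 * c3 / 8.0, -c1 / 2.0]
    if c5 == 0.0:
        coeffs = coeffs[1:]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-12].real
    x = np.sort(real[real > 0])
    return np.sqrt(x)


@dataclass(frozen=True)
class AmplitudeFlowModel:
    """Reduced 1-D amplitude flow of one population (layer) of a column.

    ``rate = omega * p_scale * p_self`` multiplies ``f(R)``; it is the
    reduced intrinsic self-coupling (the g of the two-column analysis).
    ``h_ext`` is the reduced extrinsic coupling onto this population from
    its homologous partner, in amplitude-per-time units.
    """

    kernel: KernelSpec = field(default_factory=KernelSpec)
    omega: float = 2.0 * np.pi
    p_scale: float = 1.0
    p_self: float = 1.0
    h_ext: float = 0.0

    @property
    def rate(self) -> float:
        return self.omega * self.p_scale * self.p_self

    @property
    def g_self(self) -> float:
        """Alias for the reduced intrinsic self-coupling rate."""
        return self.rate

    def f(self, R: float | np.ndarray) -> float | np.ndarray:
        # odd polynomial extension: root finders may probe slightly past R = 0
        return _f_closed_form(self.kernel, np.asarray(R, dtype=float))

    def dR_dt(self, R: float | np.ndarray) -> float | np.ndarray:
        return self.rate * self.f(R)


@dataclass(frozen=True)
class StationarySet:
    """Roots of the 1-D reduced flow with stability and interpretation labels.

    ``stability[i]`` is 'stable', 'unstable' or 'degenerate';
    ``interpretation[i]`` is 'fixed-point-at-zero' for the root at the
    origin (a fixed point of the original model) and 'limit-cycle'
    otherwise.  ``degenerate`` is set when the whole flow vanishes
    (rate = 0: every amplitude is stationary).
    """

    amplitudes: np.ndarray
    stability: tuple[str, ...]
    interpretation: tuple[str, ...]
    degenerate: bool = False

    def stable_limit_cycles(self) -> np.ndarray:
        return np.array(
            [a for a, s, i in zip(self.amplitudes, self.stability, self.interpretation)
             if s == "stable" and i == "limit-cycle"]
        )

    @property
    def R_s(self) -> float:
        """Largest stable limit-cycle amplitude."""
        cycles = self.stable_limit_cycles()
        if cycles.size == 0:
            raise ValueError("flow has no stable limit cycle")
        return float(cycles[-1])

    @property
    def R_u(self) -> float:
        """Smallest unstable limit-cycle amplitude."""
        unstable = [a for a, s, i in zip(self.amplitudes, self.stability,
                                         self.interpretation)
                    if s == "unstable" and i == "limit-cycle"]
        if not unstable:
            raise ValueError("flow has no unstable limit cycle")
        return float(unstable[0])


def find_stationary_amplitudes(
    flow: AmplitudeFlowModel, r_max: float | None = None
) -> StationarySet:
    """All stationary amplitudes of ``rate * f(R)`` on [0, r_max] with stability.

    Stability is the sign of the derivative of the flow at the root
    (negative -> stable).  Roots where the derivative magnitude falls
    below ``DEGENERATE_TOL`` are flagged 'degenerate' and left
    unclassified.
    """
    if flow.rate == 0.0:
        return StationarySet(
            amplitudes=np.array([0.0]),
            stability=("degenerate",),
            interpretation=("fixed-point-at-zero",),
            degenerate=True,
        )
    positive = limit_cycle_amplitudes(flow.kernel)
    if r_max is None:
        r_max = 1.5 * positive[-1] if positive.size else 1.0
    roots = np.concatenate([[0.0], positive[positive <= r_max]])

    eps = 1e-7 * max(r_max, 1.0)
    labels = []
    for r in roots:
        lo = max(r - eps, 0.0)
        deriv = (flow.dR_dt(r + eps) - flow.dR_dt(lo)) / (r + eps - lo)
        if abs(deriv) < DEGENERATE_TOL:
            labels.append("degenerate")
        else:
            labels.append("stable" if deriv < 0 else "unstable")
    interp = tuple(
        "fixed-point-at-zero" if r == 0.0 else "limit-cycle" for r in roots
    )
    return StationarySet(roots, tuple(labels), interp)


def coupled_amplitude_field(
    R1: float | np.ndarray,
    R2: float | np.ndarray,
    flow1: AmplitudeFlowModel,
    flow2: AmplitudeFlowModel,
    delta_phi: float = 0.0,
    r_s_ref: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduced amplitude field of one layer of two coupled columns.

    Returns ``(dR1/dt, dR2/dt)`` where each column follows its intrinsic
    flow plus the phase-gated extrinsic drive from the other column's
    amplitude.  At ``h_ext = 0`` (either side) or ``delta_phi = pi/2`` the
    cross term vanishes and the field factorizes into independent 1-D
    flows.
    """
    if r_s_ref is None:
        cycles = limit_cycle_amplitudes(flow1.kernel)
        if cycles.size == 0:
            raise ValueError("r_s_ref required when the kernel has no limit cycle")
        r_s_ref = float(cycles[-1])
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    gate = np.cos(delta_phi)
    dR1 = flow1.dR_dt(R1) - flow1.h_ext * gate * R2 / r_s_ref
    dR2 = flow2.dR_dt(R2) - flow2.h_ext * gate * R1 / r_s_ref
    return dR1, dR2


Field2D = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def enumerate_attractors_2d(
    field: Field2D,
    r_max: float,
    seed_grid: int = 31,
    refine_tol: float = 1.0e-9,
) -> list[tuple[np.ndarray, str]]:
    """Stationary points of a 2-D amplitude field with Jacobian stability.

    Root candidates are seeded from a regular grid over [0, r_max]^2 and
    refined with a damped Newton (hybr) solve; converged solutions are
    deduplicated within a tolerance proportional to ``r_max`` and
    classified by the real parts of the Jacobian eigenvalues (all
    negative -> 'stable', any positive -> 'unstable', otherwise
    'degenerate').  Non-converged seeds are dropped.
    """

    def fvec(x: np.ndarray) -> np.ndarray:
        d1, d2 = field(np.array(x[0]), np.array(x[1]))
        return np.array([float(d1), float(d2)])

    grid = np.linspace(0.0, r_max, seed_grid)
    found: list[np.ndarray] = []
    dedup = 1e-6 * max(r_max, 1.0)
    for a in grid:
        for b in grid:
            sol = optimize.root(fvec, np.array([a, b]), method="hybr",
                                options={"xtol": refine_tol})
            if not sol.success:
                continue
            x = sol.x
            if not (-dedup <= x[0] <= r_max + dedup and -dedup <= x[1] <= r_max + dedup):
                continue
            if np.linalg.norm(fvec(x)) > 1e-8:
                continue
            x = np.clip(x, 0.0, None)
            if not any(np.linalg.norm(x - y) < dedup * 10 for y in found):
                found.append(x)

    out: list[tuple[np.ndarray, str]] = []
    eps = 1e-6 * max(r_max, 1.0)
    for x in sorted(found, key=lambda p: (p[0], p[1])):
        J = np.empty((2, 2))
        for j in range(2):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] = max(xm[j] - eps, x[j] - eps)  # may cross 0; field is smooth
            J[:, j] = (fvec(xp) - fvec(xm)) / (xp[j] - xm[j])
        re = np.linalg.eigvals(J).real
        if np.all(re < -DEGENERATE_TOL):
            label = "stable"
        elif np.any(re > DEGENERATE_TOL):
            label = "unstable"
        else:
            label = "degenerate"
        out.append((x, label))
    return out


def basin_attractors(
    field: Field2D,
    r_max: float,
    grid_n: int = 21,
    t_max: float = 400.0,
    dt: float = 0.02,
    cluster_tol: float | None = None,
) -> list[np.ndarray]:
    """Distinct attracting states reached from a grid of initial conditions.

    Integrates the field forward (explicit Euler, amplitudes clipped to
    stay nonnegative — the flow lives on the closed quadrant) from a
    ``grid_n x grid_n`` lattice over [0, r_max]^2 and clusters the final
    states.  Unlike :func:`enumerate_attractors_2d` this also finds
    attractors pinned to the R = 0 boundary, where the unconstrained field
    need not vanish.
    """
    if cluster_tol is None:
        cluster_tol = 0.05 * r_max
    g = np.linspace(0.0, r_max, grid_n)
    R1, R2 = np.meshgrid(g, g)
    R1, R2 = R1.ravel().copy(), R2.ravel().copy()
    n_steps = int(round(t_max / dt))
    for _ in range(n_steps):
        d1, d2 = field(R1, R2)
        R1 = np.clip(R1 + dt * np.asarray(d1), 0.0, None)
        R2 = np.clip(R2 + dt * np.asarray(d2), 0.0, None)
    ends = np.column_stack([R1, R2])
    attractors: list[np.ndarray] = []
    counts: list[int] = []
    for p in ends:
        for i, a in enumerate(attractors):
            if np.linalg.norm(p - a) < cluster_tol:
                # running mean keeps cluster centres tight
                attractors[i] = (a * counts[i] + p) / (counts[i] + 1)
                counts[i] += 1
                break
        else:
            attractors.append(p.copy())
            counts.append(1)
    return sorted(attractors, key=lambda p: (p[0], p[1]))


def trapping_potential(
    field: Field2D,
    R2_fixed: float,
    r_grid: np.ndarray,
) -> np.ndarray:
    """Potential V(R1) = -int_0^{R1} dR1'/dt (R1', R2_fixed) dR1'.

    Tabulated on ``r_grid`` by cumulative trapezoid; local minima of V are
    the stable points of the flow restricted to the transition corridor
    R2 = R2_fixed (the driver held on its limit cycle).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    d1, _ = field(r_grid, np.full_like(r_grid, R2_fixed))
    return -integrate.cumulative_trapezoid(np.asarray(d1), r_grid, initial=0.0)


@dataclass(frozen=True)
class PhasePortrait2D:
    """Sampled 2-D amplitude vector field at a fixed phase lag."""

    R1: np.ndarray
    R2: np.ndarray
    dR1: np.ndarray
    dR2: np.ndarray
    delta_phi: float

    @classmethod
    def sample(
        cls,
        field: Field2D,
        r_max: float,
        n: int = 41,
        delta_phi: float = 0.0,
    ) -> "PhasePortrait2D":
        g = np.linspace(0.0, r_max, n)
        R1, R2 = np.meshgrid(g, g)
        d1, d2 = field(R1, R2)
        return cls(R1, R2, np.asarray(d1), np.asarray(d2), delta_phi)
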