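"""Synaptic coupling kernels for convolution-based neural-mass models.

Two kernel families appear in the equations of motion of a neural-mass
population:

* the **S-kernel** (potential-to-current coupling), odd and *positive* near
  zero — at first order in the coupling it only shifts the phase lag per
  oscillation cycle and leaves the amplitude flow untouched;
* the **P-kernel** (current-to-current coupling), odd and *negative* near
  zero — it is the kernel that shapes the cycle-averaged amplitude flow and
  hence decides whether limit cycles exist and whether they are stable.

The default P-kernel is the simplest odd polynomial whose cycle-averaged
flow has the bistable root pattern {0 stable, R_u unstable, R_s stable}:
``P(y) = -c1*y + c3*y**3 - c5*y**5`` with ``(c1, c3, c5) = (1, 1, 0.2)``.
With those defaults the reduced flow has its unstable amplitude at
``R_u = sqrt(2)`` and its stable limit-cycle amplitude at ``R_s = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelSpec", "DEFAULT_P_COEFFS"]

DEFAULT_P_COEFFS: tuple[float, float, float] = (1.0, 1.0, 0.2)


@dataclass(frozen=True)
class KernelSpec:
    """Parameterization of the S- and P-type synaptic kernels.

    Parameters
    ----------
    s_gain:
        Slope of the S-kernel at the origin (dimensionless, > 0). The
        S-kernel itself is ``S(x) = tanh(s_gain * x)``, a saturating odd
        sigmoid that is positive close to 0.
    p_coeffs:
        Coefficients ``(c1, c3, c5)`` of the odd-polynomial P-kernel
        ``P(y) = -c1*y + c3*y**3 - c5*y**5``. ``c1 > 0`` so the kernel is
        negative close to 0, as current-to-current synaptic coupling
        requires.
    saturation:
        Symmetric clip bound applied to kernel *inputs*, keeping both
        kernels bounded on unbounded state excursions.
    """

    s_gain: float = 1.0
    p_coeffs: tuple[float, float, float] = field(default=DEFAULT_P_COEFFS)
    saturation: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.s_gain) or self.s_gain <= 0:
            raise ValueError(f"s_gain must be finite and > 0, got {self.s_gain}")
        c1, c3, c5 = self.p_coeffs
        if not np.isfinite([c1, c3, c5]).all():
            raise ValueError(f"p_coeffs must be finite, got {self.p_coeffs}")
        if c1 <= 0:
            raise ValueError(
                f"c1 must be > 0 (P-kernel slope negative at the origin), got {c1}"
            )
        if self.saturation <= 0:
            raise ValueError(f"saturation must be > 0, got {self.saturation}")

    # Both kernels are odd by construction: S via tanh, P via odd powers.

    def S(self, x: np.ndarray | float) -> np.ndarray | float:
        """Potential-to-current kernel, ``tanh(s_gain * x)`` on the clipped input."""
        x = np.clip(x, -self.saturation, self.saturation)
        return np.tanh(self.s_gain * x)

    def P(self, y: np.ndarray | float) -> np.ndarray | float:
        """Current-to-current kernel, ``-c1*y + c3*y^3 - c5*y^5`` on the clipped input."""
        y = np.clip(y, -self.saturation, self.saturation)
        c1, c3, c5 = self.p_coeffs
        y2 = y * y
        return y * (-c1 + y2 * (c3 - c5 * y2))
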