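"""The weak-coupling phase dynamics of two columns is the Kuramoto model.

Pins the phase lag between two mutually coupled columns at a range of
values, releases, and regresses the measured lag velocity on sin(lag).
The sine law holds with high goodness of fit and the fitted constant
matches the reduced-theory prediction 2h/R_s.
"""

import numpy as np

from cortnet import SimConfig, fit_kuramoto_constant
from cortnet import ColumnSpec, NetworkSpec, PopulationSpec

OMEGA, H = 2 * np.pi, -0.05

col = ColumnSpec(populations=(PopulationSpec(OMEGA),),
                 s_mat=np.zeros((1, 1)), p_mat=np.ones((1, 1)), p_scale=0.05)
h_mat = np.zeros((1, 2, 2))
h_mat[0, 0, 1] = h_mat[0, 1, 0] = H
net = NetworkSpec(columns=(col, col), h=h_mat)

cfg = SimConfig(dt=1e-4, t_end=1.0, noise_sigma=0.0, seed=7)
lags = np.linspace(0.3, 2.8, 8)
fit = fit_kuramoto_constant(net, lags, cfg, t_settle=3.0, t_measure=0.5)

print(f"{'lag':>6} {'sin(lag)':>9} {'d(lag)/dt':>10}")
for lag, d in zip(fit.lags, fit.dphi_dt):
    print(f"{lag:6.2f} {np.sin(lag):9.3f} {d:10.4f}")
print(f"\nfitted constant C = {fit.C_hat:.4f} "
      f"(reduced theory: 2h/R_s = {2 * H / 2.0:.4f})")
print(f"goodness of fit R^2 = {fit.r_squared:.3f}")
print("\nC < 0 means excitatory coupling synchronizes the columns"
      "\n(the lag relaxes to 0), closing the loop with the phase gate of"
      "\nexample 03: synchronized columns recruit each other fastest.")
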