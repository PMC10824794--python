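"""Phase portraits and trapping potentials of two coupled columns.

Builds the cycle-averaged amplitude field for one layer of two columns,
counts its stationary points in the decoupled and weakly coupled cases,
and shows how the phase lag between the columns tilts the trapping
potential — the phase-dependent ("dynamic") component of connectivity.
"""

import numpy as np

from cortnet import (AmplitudeFlowModel, basin_attractors,
                     coupled_amplitude_field, enumerate_attractors_2d,
                     trapping_potential)

flow0 = AmplitudeFlowModel(omega=2 * np.pi, p_scale=0.05)

# decoupled: the 2-D flow is a product of two bistable 1-D flows
decoupled = lambda a, b: coupled_amplitude_field(a, b, flow0, flow0)
pts = enumerate_attractors_2d(decoupled, r_max=3.0)
labels = [s for _, s in pts]
print(f"decoupled field: {len(pts)} stationary points "
      f"({labels.count('stable')} stable, {labels.count('unstable')} unstable)")

# weak extrinsic coupling preserves the attractor structure
flow_h = AmplitudeFlowModel(omega=2 * np.pi, p_scale=0.05, h_ext=-0.05)
coupled = lambda a, b: coupled_amplitude_field(a, b, flow_h, flow_h, delta_phi=0.0)
att = basin_attractors(coupled, r_max=3.0)
print(f"weakly coupled columns: {len(att)} attracting states:")
for a in att:
    print(f"  (R1, R2) = ({a[0]:.2f}, {a[1]:.2f})")

# the trapping potential along the transition corridor R2 = R_s
grid = np.linspace(0.0, 3.0, 601)
stronger = AmplitudeFlowModel(omega=2 * np.pi, p_scale=0.05, h_ext=-0.1)
for lag in (0.0, np.pi):
    field = lambda a, b: coupled_amplitude_field(a, b, stronger, stronger,
                                                 delta_phi=lag)
    V = trapping_potential(field, R2_fixed=2.0, r_grid=grid)
    print(f"phase lag {lag:.2f}: potential minimum at R1 = "
          f"{grid[np.argmin(V)]:.2f}")

print("\nAt lag 0 the global minimum sits at the joint-seizure state"
      "\n(R1 near R_s); at lag pi it sits at rest (R1 = 0): the same"
      "\nanatomical coupling is gated on or off by the phase relation.")
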