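"""Phase-gated state transitions: the drift relation and gating curves.

Clamps the phase lag between a driver column (on its limit cycle) and a
driven column, and shows (a) the driven column's mean amplitude drifts
at exactly -h cos(lag), and (b) transitions to the high-amplitude state
only happen when the gate cos(lag) has the right sign for the coupling.
"""

import numpy as np

from cortnet.propagation import measure_drift_slope, transition_fraction

H = -0.2  # excitatory coupling (negative: the P-kernel is negative near 0)

print("drift of the driven column's mean amplitude (200 trials each):")
print(f"{'lag':>8} {'measured':>10} {'-h cos':>8} {'MC s.e.':>8}")
for lag in (0.0, np.pi / 3, np.pi / 2, 2 * np.pi / 3, np.pi):
    slope, se = measure_drift_slope(H, lag, n_trials=200, seed=42)
    print(f"{lag:8.3f} {slope:10.4f} {-H * np.cos(lag):8.4f} {se:8.4f}")

print("\ntransition fraction within 15 time units (20 trials each):")
print(f"{'coupling':>9} {'lag 0':>7} {'lag pi':>7}")
for h in (H, -H, 0.0):
    f0 = transition_fraction(h, 0.0, n_trials=20, seed=3)
    fpi = transition_fraction(h, np.pi, n_trials=20, seed=3)
    print(f"{h:9.2f} {f0:7.2f} {fpi:7.2f}")

print("\nNegative (excitatory) coupling recruits the driven column at"
      "\nsmall lags and not at lag pi; positive coupling reverses the"
      "\ngate; zero coupling never recruits on this horizon.")
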