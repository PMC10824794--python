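"""Seizure propagation on a 5-node cascade and connectivity inversion.

Simulates Monte-Carlo seizure spread through a seeded cascading network,
summarizes the per-node onset-time distributions, inverts the analytic
drift forward model for the connectivity log-gains with variational
Laplace, and sweeps the connection gain to show its effect on total
propagation time.
"""

import numpy as np

from cortnet import (PriorSpec, SimConfig, gain_sweep, invert_cascade,
                     make_demo_network, onset_statistics,
                     predict_onset_times, simulate_cascade)

N_TRIALS, SEED = 200, 0

casc, _ = make_demo_network(seed=SEED)
print("true connectivity h (row j <- column k):")
print(np.round(casc.h, 3))

cfg = SimConfig(dt=1e-3, t_end=20.0, noise_sigma=0.05, seed=SEED,
                record_stride=20)
table = simulate_cascade(casc, cfg, N_TRIALS)
stats = onset_statistics(table)
pred = predict_onset_times(casc)
print(f"\nonset-time summaries over {N_TRIALS} trials vs drift-model prediction:")
print(f"{'node':>5} {'mean':>7} {'sd':>6} {'predicted':>10}")
for j in range(casc.n_nodes):
    print(f"{j:5d} {stats.loc[j, 'mean']:7.3f} {stats.loc[j, 'sd']:6.3f} "
          f"{pred[j]:10.3f}")

links = [(j, k) for j, k in zip(*np.nonzero(casc.h))]
theta_true = np.log(-casc.h[tuple(np.array(links).T)])
rng = np.random.default_rng(123)
prior = PriorSpec(theta_true + rng.normal(0, 0.5, len(links)),
                  0.25 * np.eye(len(links)))
observed = [j for j in range(casc.n_nodes) if j != casc.onset_node]
res = invert_cascade(casc, stats["mean"].to_numpy()[observed],
                     stats["sd"].to_numpy()[observed], prior, links,
                     n_trials=N_TRIALS)
print(f"\ninversion converged: {res.converged}; free-energy trace "
      f"{np.round(res.free_energy_trace, 2)}")
print(f"prior  log-gain error (l2): "
      f"{np.linalg.norm(prior.theta_mean - theta_true):.3f}")
print(f"posterior log-gain error : "
      f"{np.linalg.norm(res.theta_post_mean - theta_true):.3f}")

sweep = gain_sweep(casc, [0.25, 0.5, 1.0, 2.0, 4.0])
print("\nconnection-gain sweep (predicted total propagation time):")
print(sweep.to_string(index=False))
print("\nThe posterior connectivity is closer to the generating network"
      "\nthan the prior, and weakening every connection (gain < 1) slows"
      "\nseizure spread — the virtual-disconnection prediction.")
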