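"""Seeded fixture generation: the 5-node cascade demonstration network.

The demo emulates the canonical cascade experiment: one seizure-onset
node, cascading excitatory (negative-h) connections onto later nodes,
link strengths drawn from a seeded range wide enough that the expected
onsets are well separated and strictly increasing along the node order.
"""

from __future__ import annotations

import numpy as np

from .kernels import KernelSpec
from .propagation import CascadeNetwork, predict_onset_times
from .specs import NetworkSpec

__all__ = ["make_demo_network"]


def make_demo_network(
    n_nodes: int = 5,
    seed: int = 0,
    h_range: tuple[float, float] = (0.4, 0.9),
    extra_parent_prob: float = 0.5,
    min_gap: float = 0.75,
    omega: float = 2.0 * np.pi,
    p_scale: float = 0.01,
    kernel: KernelSpec | None = None,
    max_draws: int = 1000,
) -> tuple[CascadeNetwork, NetworkSpec]:
    """Build a seeded cascading demo network and its full neural-mass spec.

    Node 0 is the onset node; every later node receives a link from its
    predecessor and, with probability ``extra_parent_prob``, one more
    link from a random earlier node.  Link magnitudes are uniform on
    ``h_range`` (entered with negative sign: excitatory convention).
    Candidate draws are rejected until the predicted onsets are strictly
    increasing along the node order with at least ``min_gap`` between
    consecutive onsets (well-separated recruitment), so the construction
    is deterministic given the seed.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    kernel = kernel or KernelSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5eed]))
    for _ in range(max_draws):
        h = np.zeros((n_nodes, n_nodes))
        for j in range(1, n_nodes):
            h[j, j - 1] = -rng.uniform(*h_range)
            if j > 1 and rng.random() < extra_parent_prob:
                k = rng.integers(0, j - 1)
                h[j, k] = -rng.uniform(*h_range)
        casc = CascadeNetwork(h=h, onset_node=0, omega=omega,
                              p_scale=p_scale, kernel=kernel)
        T = predict_onset_times(casc)
        if np.isfinite(T).all() and np.all(np.diff(T) >= min_gap):
            return casc, casc.to_network_spec()
    raise RuntimeError("could not draw a strictly ordered cascade network")
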