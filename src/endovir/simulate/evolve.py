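"""Simulation of lifestyle evolution and per-branch event counts."""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import dendropy
import numpy as np

from ..glm import BranchObservation
from ..mk import FlatTree, build_rate_matrix, flatten_tree, _edge_probabilities


def evolve_lifestyles(
    tree: dendropy.Tree | FlatTree,
    mk_rates: Sequence[float],
    states: Sequence[str],
    root_state: str,
    seed: int = 0,
) -> tuple[FlatTree, np.ndarray, dict[str, str]]:
    """Evolve a discrete lifestyle down the tree under the Mk process.

    Every node receives exactly one state: the root gets *root_state*,
    each child is drawn from the transition probabilities over its branch
    length. Returns the flattened tree, the per-node state-index array and
    the tip-label -> state map.
    """
    if root_state not in states:
        raise ValueError(f"unknown root state {root_state!r}")
    k = len(states)
    flat = tree if isinstance(tree, FlatTree) else flatten_tree(tree)
    q = build_rate_matrix(np.asarray(mk_rates, dtype=float), k)
    p_edge = _edge_probabilities(q, flat.edge_length)
    rng = np.random.default_rng(seed)
    node_states = np.empty(flat.n_nodes, dtype=np.int64)
    node_states[flat.root] = states.index(root_state)
    for node in flat.preorder[1:]:
        parent_state = node_states[flat.parent[node]]
        node_states[node] = rng.choice(k, p=p_edge[node][parent_state])
    tip_map = {
        flat.leaf_labels[i]: states[node_states[i]] for i in flat.leaves
    }
    return flat, node_states, tip_map


def simulate_event_counts(
    flat: FlatTree,
    node_states: np.ndarray,
    states: Sequence[str],
    event_rates: Mapping[str, float],
    zero_inflation: float,
    dispersion: float,
    seed: int = 0,
    domestication_probs: Mapping[str, float] | None = None,
) -> list[BranchObservation]:
    """Draw per-branch endogenization-event counts.

    One record per branch (every non-root node heads one branch); the
    branch carries the state of the node it leads to, the expected count
    is rate(state) * branch length, and the count is zero-inflated
    negative-binomial with size *dispersion* (``inf`` gives the Poisson
    limit). Domesticated events are a binomial thinning of the events.
    """
    if not 0.0 <= zero_inflation <= 1.0:
        raise ValueError("zero_inflation must lie in [0, 1]")
    if not dispersion > 0:
        raise ValueError("dispersion (negative-binomial size) must be positive")
    rng = np.random.default_rng(seed)
    obs: list[BranchObservation] = []
    counter = 0
    for node in flat.preorder[1:]:
        counter += 1
        state = states[node_states[node]]
        length = float(flat.edge_length[node])
        mean = event_rates[state] * length
        if rng.uniform() < zero_inflation:
            count = 0
        elif math.isinf(dispersion):
            count = int(rng.poisson(mean))
        else:
            p = dispersion / (dispersion + mean) if mean > 0 else 1.0
            count = int(rng.negative_binomial(dispersion, p)) if mean > 0 else 0
        p_dom = (domestication_probs or {}).get(state, 0.0)
        devents = int(rng.binomial(count, p_dom)) if count else 0
        if node in flat.leaf_labels:
            branch_id = flat.leaf_labels[node]
        else:
            branch_id = f"branch_{counter:04d}"
        obs.append(
            BranchObservation(
                branch_id=branch_id,
                lifestyle=state,
                length=length,
                n_events=count,
                n_devents=devents,
                node_age=float(flat.node_age[flat.parent[node]]),
            )
        )
    return obs
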