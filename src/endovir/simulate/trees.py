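"""Dated species-tree simulation (constant-rate birth-death, forward in
time, conditioned on the number of extant tips)."""

from __future__ import annotations

import dendropy
import numpy as np

from .config import SimulationConfig, TreeModel


def expected_yule_root_age(n_species: int, birth_rate: float) -> float:
    """Expected time for a Yule process to grow from 2 to n lineages.

    The period with k lineages lasts Exp(k*lambda) and the simulation
    stops at the (unexecuted) event following the n-th birth, so the mean
    crown age of the simulator's pure-birth trees is
    (1/lambda) * sum_{k=2}^{n} 1/k.
    """
    return sum(1.0 / k for k in range(2, n_species + 1)) / birth_rate


def simulate_species_tree(
    config: SimulationConfig | None = None,
    n_species: int | None = None,
    birth_rate: float | None = None,
    death_rate: float | None = None,
    seed: int | None = None,
    max_restarts: int = 1000,
) -> dendropy.Tree:
    """Simulate an ultrametric dated species tree (branch lengths in My).

    The process starts at the crown split (two lineages at time 0) and
    runs forward until the n-th extant lineage is born; extinct lineages
    are pruned afterwards (the run restarts on total extinction). Leaf
    names are ``sp001``..``spNNN``.
    """
    if config is not None:
        config.validate()
        n = config.n_species
        birth = config.tree_model.birth_rate
        death = config.tree_model.death_rate
        seed = config.seed if seed is None else seed
    else:
        n = n_species
        birth = birth_rate
        death = death_rate or 0.0
    if n is None or n < 3:
        raise ValueError("need at least 3 species")
    TreeModel(birth_rate=birth, death_rate=death).validate()
    rng = np.random.default_rng(seed or 0)

    taxon_ns = dendropy.TaxonNamespace()
    for _ in range(max_restarts):
        tree = dendropy.Tree(taxon_namespace=taxon_ns)
        root = tree.seed_node
        root._time = 0.0
        # a lineage emanates from a tree node at a start time
        active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
        t = 0.0
        while active:
            k = len(active)
            t += rng.exponential(1.0 / (k * (birth + death)))
            idx = int(rng.integers(k))
            parent, t0 = active[idx]
            if rng.uniform() < birth / (birth + death):
                split = dendropy.Node()
                split._time = t
                parent.add_child(split)
                split.edge.length = t - t0
                active[idx] = (split, t)
                active.append((split, t))
                if len(active) == n:
                    break
            else:
                active.pop(idx)
        if len(active) == n:
            # stop at the time the next event would have happened, so the
            # youngest split keeps a positive terminal branch
            stop_time = t + rng.exponential(1.0 / (n * (birth + death)))
            break
    else:
        raise RuntimeError("birth-death simulation failed to reach target tip count")

    for i, (parent, t0) in enumerate(active):
        leaf = dendropy.Node()
        leaf._time = stop_time
        parent.add_child(leaf)
        leaf.edge.length = stop_time - t0
        leaf.taxon = taxon_ns.new_taxon(f"sp{i + 1:03d}")

    # prune split nodes whose descendants all went extinct, then collapse
    # the resulting unifurcations (their edge lengths are summed)
    changed = True
    while changed:
        changed = False
        for node in list(tree.leaf_node_iter()):
            if node.taxon is None and node.parent_node is not None:
                node.parent_node.remove_child(node)
                changed = True
    tree.suppress_unifurcations()
    seed_node = tree.seed_node
    if len(seed_node.child_nodes()) == 1:
        new_root = seed_node.child_nodes()[0]
        seed_node.remove_child(new_root)
        new_root.parent_node = None
        new_root.edge.length = None
        tree.seed_node = new_root
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.edge.length > 0:
            raise RuntimeError("non-positive branch length in simulation")
    return tree
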