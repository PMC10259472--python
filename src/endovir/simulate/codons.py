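"""Codon-alignment simulation under the GY94-style model.

Test bed for the selection machinery: sequences evolve along a tree under
a Markov codon process with known kappa and omega, so estimator recovery
and test calibration can be checked against the generating parameters.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np

from .. import codonmodel as cm


def simulate_codon_alignment(
    tree: dendropy.Tree | str,
    omega: float,
    kappa: float = 2.0,
    n_codons: int = 300,
    seed: int = 0,
) -> dict[str, str]:
    """Simulate a gap-free codon alignment along *tree*.

    Branch lengths are expected substitutions per codon. The root sequence
    is uniform over the 61 sense codons, so no internal stop codons can
    arise and the alignment length is 3 * n_codons by construction.
    """
    if omega <= 0 or kappa <= 0:
        raise ValueError("omega and kappa must be positive")
    if n_codons < 1:
        raise ValueError("need at least one codon")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    q = cm.rate_matrix(kappa, omega)
    root_seq = rng.integers(cm.N_CODONS, size=n_codons)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root_seq
        else:
            t = node.edge.length or 0.0
            parent_seq = states[id(node.parent_node)]
            if t == 0:
                seq = parent_seq.copy()
            else:
                p = cm.transition_probabilities(q, t)
                cdf = np.cumsum(p, axis=1)
                u = rng.uniform(size=len(parent_seq))
                seq = np.array(
                    [np.searchsorted(cdf[s], v) for s, v in zip(parent_seq, u)],
                    dtype=np.int64,
                )
            states[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"t{len(out) + 1}"
            out[label] = cm.decode_codon_indices(seq)
    return out


def pair_alignment(
    t1: float, t2: float, omega: float, kappa: float = 2.0, n_codons: int = 300,
    seed: int = 0, names: tuple[str, str] = ("seq1", "seq2"),
) -> tuple[dict[str, str], dendropy.Tree]:
    """Two-sequence alignment plus its two-branch tree."""
    newick = f"({names[0]}:{t1},{names[1]}:{t2});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    aln = simulate_codon_alignment(tree, omega=omega, kappa=kappa, n_codons=n_codons, seed=seed)
    return aln, tree
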