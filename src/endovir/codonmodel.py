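"""Codon substitution model (GY94-style) with equal codon frequencies.

Shared machinery for the dN/dS branch test and the codon-alignment
simulator: the 61 sense codons of the universal code, a rate matrix
parameterized by a transition/transversion ratio kappa and a
nonsynonymous/synonymous rate ratio omega, and transition probabilities
via symmetric eigendecomposition (the matrix is reversible under uniform
codon frequencies).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "TCAG"
_CODON_TABLE = {}
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_AMINO):
    _codon = BASES[_i // 16] + BASES[(_i // 4) % 4] + BASES[_i % 4]
    _CODON_TABLE[_codon] = _a

STOP_CODONS = tuple(c for c, a in _CODON_TABLE.items() if a == "*")
CODONS = tuple(c for c, a in sorted(_CODON_TABLE.items()) if a != "*")
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61
AMINO_OF = {c: a for c, a in _CODON_TABLE.items()}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate(codon: str) -> str:
    return _CODON_TABLE[codon.upper().replace("U", "T")]


@lru_cache(maxsize=None)
def _structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masks over codon pairs differing at exactly one position.

    Returns (is_single_change, is_transition, is_nonsynonymous) boolean
    matrices; pairs differing at 0 or >1 positions are False throughout.
    """
    ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros_like(ts)
    single = np.zeros_like(ts)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = diffs[0] in _TRANSITIONS
            nonsyn[i, j] = AMINO_OF[ci] != AMINO_OF[cj]
    return single, ts, nonsyn


def rate_matrix(kappa: float, omega: float, normalize: bool = True) -> np.ndarray:
    """GY94 rate matrix with uniform codon frequencies.

    Single-nucleotide changes only; rate kappa for transitions, 1 for
    transversions, multiplied by omega when the change is nonsynonymous.
    When *normalize* is set, the matrix is scaled so branch lengths are in
    expected substitutions per codon.
    """
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be positive")
    single, ts, nonsyn = _structure()
    q = np.where(single, np.where(ts, kappa, 1.0), 0.0)
    q = np.where(nonsyn, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        mean_rate = -np.mean(np.diag(q))
        q = q / mean_rate
    return q


def transition_probabilities(q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) via symmetric eigendecomposition (Q is symmetric here)."""
    if t < 0:
        raise ValueError("negative branch length")
    vals, vecs = np.linalg.eigh(q)
    p = (vecs * np.exp(vals * t)) @ vecs.T
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def encode_codon_sequence(seq: str) -> np.ndarray:
    """Codon string -> codon index array; gaps/ambiguity map to -1."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in CODON_INDEX:
            out[i // 3] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {i // 3}")
        else:
            out[i // 3] = -1
    return out


def decode_codon_indices(idx: np.ndarray) -> str:
    return "".join(CODONS[i] if i >= 0 else "---" for i in idx)
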