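"""Enrichment statistics for endogenization and domestication events.

Observed event counts per viral genomic structure (or per host lifestyle)
are compared against expectations derived from virus-abundance tables and
species-lifestyle frequencies: chi-square goodness of fit, strand-polarity
bias, 2xk Fisher exact tests with BH correction, and the one-sided
binomial test for shared domesticated genes between independent events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .confidence import bh_adjust

KNOWN_STRUCTURES = ("ssRNA(-)", "ssRNA(+)", "ssDNA", "dsRNA", "dsDNA")


@dataclass
class AbundanceTable:
    """Counts of virus species per genomic structure in the reference
    databases; 'unknown' is carried but excluded from expectations."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative abundance counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def known(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if k.lower() != "unknown"}


@dataclass
class LifestyleFrequencies:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            raise ValueError("empty lifestyle table")
        return {k: v / tot for k, v in self.counts.items()}


def expected_structure_distribution(table: AbundanceTable) -> dict[str, float]:
    """Expected proportions of events per genomic structure, from the
    relative abundance of virus species with known structure."""
    known = table.known
    total = sum(known.values())
    if total == 0:
        raise ValueError("no virus species with known genomic structure")
    return {k: v / total for k, v in known.items()}


def gof_chisq(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit chi-square; df = k - 1."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected categories are misaligned")
    total = obs.sum()
    if total <= 0:
        raise ValueError("no observations")
    exp = props / props.sum() * total
    if np.any((exp == 0) & (obs > 0)):
        raise ValueError("expected count of zero with positive observations")
    mask = exp > 0
    chi2 = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    df = int(mask.sum()) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def strand_bias_test(
    n_negative_events: int, n_positive_events: int, db_counts: tuple[int, int]
) -> tuple[float, float, float]:
    """Negative- vs positive-strand ssRNA bias against database proportions.

    *db_counts* = (negative-strand species, positive-strand species) in the
    reference databases. Returns (database negative proportion, chi2, p)
    for a 1-df goodness-of-fit of the observed event polarity counts.
    """
    db_neg, db_pos = db_counts
    if db_neg <= 0 or db_pos <= 0:
        raise ValueError("database counts must be positive for both polarities")
    if n_negative_events + n_positive_events == 0:
        raise ValueError("no ssRNA events observed")
    prop_db = db_neg / (db_neg + db_pos)
    chi2, _, p = gof_chisq(
        [n_negative_events, n_positive_events], [prop_db, 1.0 - prop_db]
    )
    return prop_db, chi2, p


def _round_preserving_total(values: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding to integers preserving the sum."""
    floors = np.floor(values)
    deficit = int(round(values.sum() - floors.sum()))
    order = np.argsort(-(values - floors), kind="stable")
    out = floors.astype(int)
    out[order[:deficit]] += 1
    return out


def fisher_exact_2xk(
    table: np.ndarray, max_enumeration: int = 2_000_000, seed: int = 0, n_mc: int = 100_000
) -> float:
    """Exact conditional test of independence for a 2 x k table.

    The p-value sums the multivariate-hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (the standard two-sided Fisher construction). For
    k <= small this enumerates the table space directly; when the space
    exceeds *max_enumeration* cells a Monte-Carlo estimate with a fixed
    seed is returned instead.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or np.any(t < 0):
        raise ValueError("expected a non-negative 2 x k table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or row[0] == 0 or row[1] == 0:
        return 1.0
    k = t.shape[1]

    log_norm = math.lgamma(n + 1) - math.lgamma(row[0] + 1) - math.lgamma(row[1] + 1)

    def log_choose(m: int, x: int) -> float:
        return math.lgamma(m + 1) - math.lgamma(x + 1) - math.lgamma(m - x + 1)

    def log_prob(first_row) -> float:
        # P(table | margins) = prod_j C(col_j, x_j) / C(n, row_0)
        return sum(log_choose(col[j], int(first_row[j])) for j in range(k)) - log_norm

    lp_obs = log_prob(t[0])
    tol = 1e-9
    space = int(np.prod([min(row[0], c) + 1 for c in col[:-1]]))
    if space <= max_enumeration:
        total = 0.0

        def recurse(j: int, remaining: int, lp: float) -> None:
            nonlocal total
            if j == k - 1:
                if 0 <= remaining <= col[j]:
                    full = lp + log_choose(col[j], remaining) - log_norm
                    if full <= lp_obs + tol:
                        total += math.exp(full)
                return
            for x in range(0, min(remaining, int(col[j])) + 1):
                recurse(j + 1, remaining - x, lp + log_choose(col[j], x))

        recurse(0, int(row[0]), 0.0)
        return min(1.0, total)
    # Monte-Carlo fallback: permute labels, fixed seed
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), col)
    hits = 1  # add-one correction for the observed table
    for _ in range(n_mc):
        rng.shuffle(labels)
        first = np.bincount(labels[: row[0]], minlength=k)
        if log_prob(first) <= lp_obs + 1e-9:
            hits += 1
    return min(1.0, hits / (n_mc + 1))


def lifestyle_fisher(
    event_counts: Mapping[str, Mapping[str, int]],
    freqs: LifestyleFrequencies,
) -> dict[str, dict[str, float]]:
    """Per-structure exact test of event allocation across lifestyles.

    For each viral genomic structure, the observed event counts per
    lifestyle are compared with the allocation expected from the species
    frequencies (total events x lifestyle frequency, rounded preserving
    the total) in a 2 x k exact test; p-values are BH-adjusted across
    structures.
    """
    props = freqs.proportions()
    lifestyles = sorted(props)
    structures = sorted(event_counts)
    raw = {}
    for struct in structures:
        obs = np.array([event_counts[struct].get(ls, 0) for ls in lifestyles], dtype=float)
        total = obs.sum()
        if total == 0:
            raw[struct] = 1.0
            continue
        exp = _round_preserving_total(total * np.array([props[ls] for ls in lifestyles]))
        raw[struct] = fisher_exact_2xk(np.vstack([obs.astype(int), exp]))
    adjusted = bh_adjust([raw[s] for s in structures]) if structures else []
    return {
        s: {"p_raw": raw[s], "p_adjusted": float(q)} for s, q in zip(structures, adjusted)
    }


def shared_gene_binomial(x: int, n: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= x), X ~ Binomial(n, p0).

    Used for testing whether two independent domestication events retained
    more of the same donor genes than expected by chance.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    return float(stats.binom.sf(x - 1, n, p0))
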