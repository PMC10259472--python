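"""Mk model of discrete lifestyle evolution on a dated phylogeny.

All off-diagonal transition rates are free ("relaxed" Mk: 6 rates for 3
states, 12 for 4), with independent exponential priors. The likelihood is
computed by Felsenstein pruning with a uniform root prior; the posterior
is sampled by random-walk Metropolis on log-rates with auto-tuned proposal
scales; joint ancestral-state scenarios are drawn by backward filtering /
forward sampling conditional on sampled rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import dendropy
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tree flattening
# ---------------------------------------------------------------------------

@dataclass
class FlatTree:
    """Array representation of a rooted binary tree for fast pruning.

    Nodes are indexed in postorder (root last); ``children[i]`` holds the
    two child indices (-1 for leaves), ``edge_length[i]`` the length of
    the branch leading to node i (0 for the root), ``levels`` groups
    internal nodes into waves whose children are all already computed, so
    each wave evaluates as one vectorized step.
    """

    n_nodes: int
    children: np.ndarray  # (N, 2)
    edge_length: np.ndarray  # (N,)
    parent: np.ndarray  # (N,)
    leaf_labels: dict[int, str]
    levels: list[np.ndarray]
    node_age: np.ndarray  # (N,) height above the tips (My), 0 at leaves
    preorder: np.ndarray

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> np.ndarray:
        return np.nonzero(self.children[:, 0] < 0)[0]


def flatten_tree(tree: dendropy.Tree) -> FlatTree:
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    children = np.full((n, 2), -1, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    edge_length = np.zeros(n)
    leaf_labels: dict[int, str] = {}
    depth = np.zeros(n, dtype=np.int64)
    age = np.zeros(n)
    for i, node in enumerate(nodes):
        kids = node.child_nodes()
        if kids:
            if len(kids) != 2:
                raise ValueError("tree must be strictly binary")
            c = [index[id(k)] for k in kids]
            children[i] = c
            parent[c[0]] = parent[c[1]] = i
            depth[i] = 1 + max(depth[c[0]], depth[c[1]])
            age[i] = max(age[c[j]] + (kids[j].edge.length or 0.0) for j in range(2))
        else:
            leaf_labels[i] = node.taxon.label if node.taxon else str(i)
        edge_length[i] = node.edge.length or 0.0
    levels = [
        np.nonzero(depth == d)[0] for d in range(1, int(depth.max()) + 1)
    ] if n > 1 else []
    preorder = np.array([index[id(nd)] for nd in tree.preorder_node_iter()], dtype=np.int64)
    return FlatTree(n, children, edge_length, parent, leaf_labels, levels, age, preorder)


# ---------------------------------------------------------------------------
# rate matrices and likelihood
# ---------------------------------------------------------------------------

def build_rate_matrix(rates: Sequence[float], k: int) -> np.ndarray:
    """Assemble a k-state rate matrix from the k(k-1) off-diagonal rates
    (row-major order, skipping the diagonal)."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (k * (k - 1),):
        raise ValueError(f"expected {k * (k - 1)} rates for {k} states")
    if not np.all(np.isfinite(rates)) or np.any(rates < 0):
        raise ValueError("rates must be finite and non-negative")
    q = np.zeros((k, k))
    it = iter(rates)
    for i in range(k):
        for j in range(k):
            if i != j:
                q[i, j] = next(it)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _edge_probabilities(q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for every edge at once via eigendecomposition of Q."""
    vals, vecs = np.linalg.eig(q)
    vinv = np.linalg.inv(vecs)
    expd = np.exp(np.multiply.outer(lengths, vals))  # (E, k)
    p = np.real((vecs[None, :, :] * expd[:, None, :]) @ vinv)
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=2, keepdims=True)
    return p


def tip_partials(
    flat: FlatTree, tip_states: Mapping[str, str | None], states: Sequence[str]
) -> np.ndarray:
    """One-hot tip likelihoods; unknown/ambiguous tips get all-ones."""
    k = len(states)
    state_index = {s: i for i, s in enumerate(states)}
    partial = np.zeros((flat.n_nodes, k))
    for i in flat.leaves:
        label = flat.leaf_labels[i]
        st = tip_states.get(label)
        if st is None:
            partial[i] = 1.0
        else:
            if st not in state_index:
                raise ValueError(f"tip {label} has unknown state {st!r}")
            partial[i, state_index[st]] = 1.0
    return partial


def _prune(flat: FlatTree, tips: np.ndarray, p_edge: np.ndarray) -> tuple[np.ndarray, float]:
    """Upward pass; returns per-node conditional likelihoods (rescaled)
    and the accumulated log scaling factor."""
    partial = tips.copy()
    log_scale = 0.0
    last = len(flat.levels) - 1
    for i, level in enumerate(flat.levels):
        c_all = flat.children[level].ravel()
        msgs = np.matmul(p_edge[c_all], partial[c_all, :, None])[..., 0]
        res = msgs[0::2] * msgs[1::2]
        if i % 2 == 0 or i == last:  # rescale often enough to avoid underflow
            norm = res.max(axis=1)
            if not norm.all():
                return partial, -np.inf
            res = res / norm[:, None]
            log_scale += float(np.log(norm).sum())
        partial[level] = res
    return partial, log_scale


def mk_loglikelihood(
    flat: FlatTree,
    tips: np.ndarray,
    q: np.ndarray,
) -> float:
    """Pruning log-likelihood with a uniform root state prior."""
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite rate matrix")
    p_edge = _edge_probabilities(q, flat.edge_length)
    partial, log_scale = _prune(flat, tips, p_edge)
    if not np.isfinite(log_scale):
        return -np.inf
    root_lik = partial[flat.root].mean()
    if root_lik <= 0:
        return -np.inf
    return float(np.log(root_lik) + log_scale)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MkPosterior:
    states: tuple[str, ...]
    rate_draws: np.ndarray  # (chains, draws, n_rates)
    log_likelihoods: np.ndarray  # (chains, draws)
    flat_tree: FlatTree
    tip_partials: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def pooled_rates(self) -> np.ndarray:
        return self.rate_draws.reshape(-1, self.rate_draws.shape[-1])


def mk_mcmc(
    tree: dendropy.Tree,
    tip_states: Mapping[str, str | None],
    states: Sequence[str],
    prior_mean: float = 0.01,
    n_cycles: int = 200_000,
    thin: int = 200,
    burn_in: int = 50_000,
    n_chains: int = 2,
    seed: int = 0,
    tune_cycles: int = 1000,
    tune_interval: int = 300,
    ess_target: float = 100.0,
) -> MkPosterior:
    """Posterior sampling of the Mk transition rates.

    Each cycle updates one randomly chosen rate with a multiplicative
    random-walk proposal; proposal scales are auto-tuned in a preliminary
    run (*tune_cycles* cycles, adjusting every *tune_interval*) and then
    frozen. Samples are retained every *thin* cycles after *burn_in*.
    Convergence is assessed by per-rate effective sample size (target
    *ess_target*) and, with several chains, rank-normalized R-hat and a
    two-sample KS comparison; failures set ``converged=False`` rather than
    raising.
    """
    k = len(states)
    n_rates = k * (k - 1)
    flat = flatten_tree(tree)
    tips = tip_partials(flat, tip_states, states)
    prior_rate = 1.0 / prior_mean

    def logpost(log_rates: np.ndarray) -> float:
        rates = np.exp(log_rates)
        # exponential prior plus log-scale Jacobian
        lp = float(np.sum(-prior_rate * rates + log_rates)) + n_rates * np.log(prior_rate)
        return lp + mk_loglikelihood(flat, tips, build_rate_matrix(rates, k))

    rng_master = np.random.default_rng(seed)
    chain_draws, chain_lls = [], []
    for chain in range(n_chains):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        x = np.log(rng.exponential(prior_mean, size=n_rates))
        lp = logpost(x)
        scales = np.full(n_rates, 0.5)
        accepts = np.zeros(n_rates)
        tries = np.zeros(n_rates)
        # preliminary auto-tuning run (frozen afterwards)
        for cycle in range(tune_cycles):
            j = rng.integers(n_rates)
            prop = x.copy()
            prop[j] += scales[j] * rng.normal()
            lp_prop = logpost(prop)
            tries[j] += 1
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepts[j] += 1
            if (cycle + 1) % tune_interval == 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    rate = np.where(tries > 0, accepts / np.maximum(tries, 1), 0.44)
                scales *= np.exp((rate - 0.44))
                scales = np.clip(scales, 1e-3, 10.0)
                accepts[:] = 0
                tries[:] = 0
        draws, lls = [], []
        for cycle in range(n_cycles):
            j = rng.integers(n_rates)
            prop = x.copy()
            prop[j] += scales[j] * rng.normal()
            lp_prop = logpost(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
            if cycle >= burn_in and (cycle - burn_in) % thin == 0:
                draws.append(np.exp(x))
                lls.append(lp)
        chain_draws.append(np.array(draws))
        chain_lls.append(np.array(lls))
    rate_draws = np.stack(chain_draws)
    lls = np.stack(chain_lls)

    diagnostics: dict = {}
    idata = az.convert_to_dataset(rate_draws, group="posterior")
    ess = az.ess(idata)["x"].values
    diagnostics["ess"] = np.atleast_1d(ess)
    converged = bool(np.all(diagnostics["ess"] >= ess_target))
    if n_chains >= 2:
        rhat = np.atleast_1d(az.rhat(idata)["x"].values)
        diagnostics["rhat"] = rhat
        ks_ps = [
            stats.ks_2samp(rate_draws[0, :, j], rate_draws[1, :, j]).pvalue
            for j in range(n_rates)
        ]
        diagnostics["ks_pvalues"] = np.array(ks_ps)
        converged = converged and bool(np.all(rhat < 1.1))
    if not converged:
        logger.warning("Mk MCMC convergence diagnostics below target: %s", diagnostics)
    return MkPosterior(
        states=tuple(states),
        rate_draws=rate_draws,
        log_likelihoods=lls,
        flat_tree=flat,
        tip_partials=tips,
        diagnostics=diagnostics,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# ancestral scenarios
# ---------------------------------------------------------------------------

def sample_ancestral_scenarios(
    posterior: MkPosterior, n: int = 1000, seed: int = 0
) -> np.ndarray:
    """Joint ancestral-state scenarios from the Mk posterior.

    For each of *n* retained posterior draws (sampled with replacement,
    with a warning, when fewer are available), states are drawn jointly:
    the root from the uniform prior times its conditional likelihood, then
    each child conditional on its parent and the data below it. The state
    of a node is taken as constant along the branch leading to it.

    Returns an integer array (n, n_nodes) of state indices.
    """
    rng = np.random.default_rng(seed)
    pooled = posterior.pooled_rates
    if pooled.shape[0] == 0:
        raise ValueError("empty posterior")
    if n > pooled.shape[0]:
        logger.warning(
            "requested %d scenarios from %d unique posterior samples; sampling "
            "with replacement",
            n,
            pooled.shape[0],
        )
        idx = rng.integers(pooled.shape[0], size=n)
    else:
        idx = rng.choice(pooled.shape[0], size=n, replace=False)
    flat = posterior.flat_tree
    k = len(posterior.states)
    scenarios = np.empty((n, flat.n_nodes), dtype=np.int64)
    for s, draw in enumerate(idx):
        q = build_rate_matrix(pooled[draw], k)
        p_edge = _edge_probabilities(q, flat.edge_length)
        partial, log_scale = _prune(flat, posterior.tip_partials, p_edge)
        if not np.isfinite(log_scale):
            raise ValueError("zero-likelihood rate draw; data inconsistent with rates")
        out = scenarios[s]
        root_w = partial[flat.root] / partial[flat.root].sum()
        out[flat.root] = rng.choice(k, p=root_w)
        for node in flat.preorder[1:]:
            par_state = out[flat.parent[node]]
            w = p_edge[node][par_state] * partial[node]
            w_sum = w.sum()
            if w_sum <= 0:
                raise ValueError("inconsistent conditional state distribution")
            out[node] = rng.choice(k, p=w / w_sum)
    return scenarios


def marginal_ancestral_probabilities(
    posterior: MkPosterior, rates: Sequence[float]
) -> np.ndarray:
    """Exact marginal state probabilities at every node for fixed rates.

    Standard up-down algorithm (conditional on the rate draw); used as the
    consistency oracle for the joint scenario sampler.
    """
    flat = posterior.flat_tree
    k = len(posterior.states)
    q = build_rate_matrix(np.asarray(rates, dtype=float), k)
    p_edge = _edge_probabilities(q, flat.edge_length)
    partial, _ = _prune(flat, posterior.tip_partials, p_edge)
    marg = np.zeros((flat.n_nodes, k))
    # "outside" pass: probability of everything except the subtree
    outside = np.zeros((flat.n_nodes, k))
    outside[flat.root] = 1.0 / k
    for node in flat.preorder:
        c = flat.children[node]
        if c[0] < 0:
            continue
        for a, b in ((c[0], c[1]), (c[1], c[0])):
            sib = np.einsum("ij,j->i", p_edge[b], partial[b])
            msg = outside[node] * sib  # distribution over parent states
            outside[a] = msg @ p_edge[a]
    marg = outside * partial
    marg /= marg.sum(axis=1, keepdims=True)
    return marg
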