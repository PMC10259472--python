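"""Branch-level Bayesian GLMs for lifestyle effects on endogenization.

Per ancestral-lifestyle scenario, the number of endogenization events on
each species-tree branch is modeled with a zero-inflated negative-binomial
regression on lifestyle and branch length (free-living as the reference
level), and the number of domesticated events relative to events with a
binomial logistic regression. Draws from the 1000 (or fewer, scaled)
per-scenario posteriors are pooled; effects are summarized as rate ratios
(exponentiated coefficients) with equal-tailed 89% credible intervals,
the probability of direction (pd), and the posterior probability that the
endoparasitoid coefficient exceeds the ectoparasitoid one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

MAX_NODE_AGE_MY = 160.0  # older branches predate the oldest detectable event


@dataclass
class BranchObservation:
    branch_id: str
    lifestyle: str
    length: float
    n_events: int = 0
    n_devents: int = 0
    node_age: float = 0.0
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("branch length must be positive")
        if self.n_devents > self.n_events:
            raise ValueError("domesticated events exceed events")


def apply_age_cutoff(
    branches: Sequence[BranchObservation], max_age: float = MAX_NODE_AGE_MY
) -> list[BranchObservation]:
    """Exclude branches whose parent node is older than *max_age* My."""
    kept = []
    for b in branches:
        b.excluded = b.node_age > max_age
        if not b.excluded:
            kept.append(b)
    return kept


@dataclass
class GlmFit:
    coef_names: list[str]
    draws: np.ndarray  # (n_draws, n_params)
    acceptance: float
    degenerate: bool = False

    def coef_draws(self, name: str) -> np.ndarray:
        return self.draws[:, self.coef_names.index(name)]

    @property
    def ok(self) -> bool:
        return (not self.degenerate) and 0.05 <= self.acceptance <= 0.8


def _adaptive_metropolis(
    logpost,
    x0: np.ndarray,
    n_iter: int,
    warmup: int,
    thin: int,
    rng: np.random.Generator,
    target: float = 0.234,
) -> tuple[np.ndarray, float]:
    """Joint random-walk Metropolis with warmup-adapted diagonal proposal.

    The proposal scale follows a Robbins-Monro recursion toward *target*
    acceptance during warmup and the per-dimension spreads are refreshed
    from the warmup history; both are frozen for the sampling phase.
    """
    p = len(x0)
    x = x0.astype(float).copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("invalid initial state for the sampler")
    log_scale = np.log(2.38 / np.sqrt(p))
    spread = np.ones(p)
    history = np.empty((warmup, p))
    accept_count = 0
    for i in range(warmup):
        prop = x + np.exp(log_scale) * spread * rng.normal(size=p)
        lp_prop = logpost(prop)
        accepted = np.log(rng.uniform()) < lp_prop - lp
        if accepted:
            x, lp = prop, lp_prop
            accept_count += 1
        history[i] = x
        log_scale += (float(accepted) - target) / (1 + i * 0.1) ** 0.6
        if i == warmup // 2:
            sd = history[: i + 1].std(axis=0)
            spread = np.where(sd > 1e-8, sd, spread)
    draws = []
    accept_count = 0
    for i in range(n_iter):
        prop = x + np.exp(log_scale) * spread * rng.normal(size=p)
        lp_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accept_count += 1
        if i % thin == 0:
            draws.append(x.copy())
    return np.array(draws), accept_count / max(n_iter, 1)


def _design(
    branches: Sequence[BranchObservation],
    lifestyles: Sequence[str],
    reference: str,
    interaction: str,
    log_length: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, lifestyle indicators, standardized branch
    length, and the requested lifestyle x length interactions.

    Branch length enters on the log scale by default (count exposure is
    multiplicative in time, so log-mean is linear in log-length); the
    coefficient stays free rather than being fixed as an offset.
    """
    non_ref = [ls for ls in lifestyles if ls != reference]
    length = np.array([b.length for b in branches])
    if log_length:
        length = np.log(length)
    zlength = (length - length.mean()) / (length.std() if length.std() > 0 else 1.0)
    cols = [np.ones(len(branches))]
    names = ["intercept"]
    for ls in non_ref:
        cols.append(np.array([1.0 if b.lifestyle == ls else 0.0 for b in branches]))
        names.append(ls)
    cols.append(zlength)
    names.append("length")
    inter_with = (
        [ls for ls in non_ref if "ecto" in ls]
        if interaction == "ecto"
        else (non_ref if interaction == "full" else [])
    )
    for ls in inter_with:
        ind = np.array([1.0 if b.lifestyle == ls else 0.0 for b in branches])
        cols.append(ind * zlength)
        names.append(f"{ls}:length")
    return np.column_stack(cols), names


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, size: float) -> np.ndarray:
    return (
        gammaln(y + size)
        - gammaln(size)
        - gammaln(y + 1)
        + size * np.log(size / (size + mu))
        + y * np.log(mu / (size + mu))
    )


def zinb_glm(
    branches: Sequence[BranchObservation],
    lifestyles: Sequence[str],
    reference: str = "free_living",
    interaction: str = "ecto",
    n_iter: int = 10_000,
    warmup: int = 2_000,
    thin: int = 5,
    n_chains: int = 4,
    seed: int = 0,
    coef_prior_sd: float = 5.0,
) -> GlmFit:
    """Zero-inflated negative-binomial regression of per-branch event counts.

    Model: y_b ~ ZINB(mu_b, size, pi) with log mu_b = X_b beta; the
    zero-inflation probability pi has a uniform prior (sampled on the
    logit scale), log size a N(0, 1.5^2) prior, coefficients
    N(0, coef_prior_sd^2). Branches older than the age cutoff must be
    excluded beforehand. Returns pooled thinned draws across chains.
    """
    branches = [b for b in branches if not b.excluded]
    represented = {b.lifestyle for b in branches}
    missing = set(lifestyles) - represented
    if missing:
        raise ValueError(f"no branches for lifestyles: {sorted(missing)}")
    y = np.array([b.n_events for b in branches], dtype=float)
    x, names = _design(branches, lifestyles, reference, interaction)
    degenerate = bool(np.all(y == 0))
    if degenerate:
        logger.warning("all event counts are zero; ZINB fit flagged degenerate")
    p = x.shape[1]
    is_zero = y == 0

    def logpost(theta: np.ndarray) -> float:
        beta, logit_pi, log_size = theta[:p], theta[p], theta[p + 1]
        if abs(log_size) > 10 or abs(logit_pi) > 15:
            return -np.inf
        eta = x @ beta
        if np.any(eta > 30):
            return -np.inf
        mu = np.exp(eta)
        size = np.exp(log_size)
        pi = expit(logit_pi)
        nb = _nb_logpmf(y, mu, size)
        ll = np.where(
            is_zero,
            np.logaddexp(np.log(pi + 1e-300), np.log1p(-pi) + nb),
            np.log1p(-pi) + nb,
        ).sum()
        lprior = (
            -0.5 * np.sum((beta / coef_prior_sd) ** 2)
            + np.log(pi * (1 - pi) + 1e-300)  # uniform prior on pi (logit Jacobian)
            - 0.5 * (log_size / 1.5) ** 2
        )
        return float(ll + lprior)

    rng_master = np.random.default_rng(seed)
    all_draws, accs = [], []
    for _ in range(max(n_chains, 1)):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        x0 = np.concatenate([
            [np.log(y.mean() + 0.5)],
            np.zeros(p - 1),
            [0.0, 0.0],
        ]) + 0.1 * rng.normal(size=p + 2)
        draws, acc = _adaptive_metropolis(
            logpost, x0, n_iter=n_iter, warmup=warmup, thin=thin, rng=rng
        )
        all_draws.append(draws)
        accs.append(acc)
    return GlmFit(
        coef_names=names + ["logit_zi", "log_size"],
        draws=np.vstack(all_draws),
        acceptance=float(np.mean(accs)),
        degenerate=degenerate,
    )


def binomial_glm(
    branches: Sequence[BranchObservation],
    lifestyles: Sequence[str],
    reference: str = "free_living",
    interaction: str = "none",
    n_iter: int = 10_000,
    warmup: int = 2_000,
    thin: int = 5,
    n_chains: int = 4,
    seed: int = 0,
    coef_prior_sd: float = 5.0,
) -> GlmFit:
    """Binomial logistic regression of domesticated events given events.

    Only branches with at least one event enter (they carry the trials);
    logit P(domestication) = X beta with N(0, coef_prior_sd^2) priors.
    """
    branches = [b for b in branches if not b.excluded and b.n_events > 0]
    if not branches:
        raise ValueError("no branch with events > 0")
    trials = np.array([b.n_events for b in branches], dtype=float)
    y = np.array([b.n_devents for b in branches], dtype=float)
    x, names = _design(branches, lifestyles, reference, interaction)
    p = x.shape[1]

    def logpost(theta: np.ndarray) -> float:
        eta = x @ theta
        if np.any(np.abs(eta) > 30):
            return -np.inf
        ll = float(np.sum(y * eta - trials * np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(np.sum((theta / coef_prior_sd) ** 2))

    rng_master = np.random.default_rng(seed)
    all_draws, accs = [], []
    for _ in range(max(n_chains, 1)):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        x0 = 0.1 * rng.normal(size=p)
        draws, acc = _adaptive_metropolis(
            logpost, x0, n_iter=n_iter, warmup=warmup, thin=thin, rng=rng
        )
        all_draws.append(draws)
        accs.append(acc)
    return GlmFit(
        coef_names=names,
        draws=np.vstack(all_draws),
        acceptance=float(np.mean(accs)),
    )


@dataclass
class PosteriorSummary:
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    p_cross: float | None = None  # P(endo coefficient > ecto coefficient)
    n_scenarios: int = 0
    n_failed: int = 0
    flagged: bool = False
    pooled: dict[str, np.ndarray] = field(default_factory=dict)


def probability_of_direction(draws: np.ndarray) -> float:
    """pd as a percentage: the share of draws on the majority side of zero."""
    if draws.size == 0:
        return float("nan")
    pos = float(np.mean(draws > 0))
    return 100.0 * max(pos, 1.0 - pos)


def pool_and_summarize(
    fits: Sequence[GlmFit],
    coef_names: Sequence[str] | None = None,
    endo_name: str = "endoparasitoid",
    ecto_name: str = "ectoparasitoid",
    ci: float = 0.89,
) -> PosteriorSummary:
    """Pool per-scenario posterior draws and summarize lifestyle effects.

    Fits failing the convergence screen (degenerate likelihood or
    pathological acceptance rate) are dropped before pooling; when more
    than half fail, the summary is flagged. Rate ratios are
    exp(coefficient) with equal-tailed credible intervals.
    """
    if len(fits) < 1:
        raise ValueError("no fits to pool")
    good = [f for f in fits if f.ok]
    summary = PosteriorSummary(n_scenarios=len(fits), n_failed=len(fits) - len(good))
    if summary.n_failed > len(fits) / 2:
        summary.flagged = True
        logger.warning(
            "%d/%d scenario fits failed convergence screening", summary.n_failed, len(fits)
        )
    if not good:
        summary.flagged = True
        return summary
    names = list(coef_names) if coef_names is not None else good[0].coef_names
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    for name in names:
        if name not in good[0].coef_names:
            continue
        pooled = np.concatenate([f.coef_draws(name) for f in good])
        summary.pooled[name] = pooled
        rr = np.exp(pooled)
        summary.coefficients[name] = {
            "median": float(np.median(pooled)),
            "rate_ratio": float(np.median(rr)),
            "rr_ci_low": float(np.quantile(rr, lo_q)),
            "rr_ci_high": float(np.quantile(rr, hi_q)),
            "pd": probability_of_direction(pooled),
        }
    if endo_name in summary.pooled and ecto_name in summary.pooled:
        summary.p_cross = float(
            np.mean(summary.pooled[endo_name] > summary.pooled[ecto_name])
        )
    return summary
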