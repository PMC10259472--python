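"""Endogenization confidence scoring of candidate scaffolds (A-X index).

A scaffold carrying candidate EVEs is judged endogenized or free-living
from (i) an empirical sequencing-depth test against scaffolds bearing
conserved single-copy orthologs (BUSCO scaffolds, the null model for the
host genome), and (ii) its genomic environment: counts of insect genes and
transposable elements. Scores A-D are treated as endogenized, E is
undecidable and discarded, F and X flag likely free-living viruses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .intervals import merge_intervals

logger = logging.getLogger(__name__)

SCORES = ("A", "B", "C", "D", "E", "F", "X")
ENDOGENIZED_SCORES = frozenset({"A", "B", "C", "D"})
FREE_LIVING_SCORES = frozenset({"F", "X"})

#: significance level on the BH-corrected depth p-value
ALPHA = 0.05
#: number of null windows resampled from BUSCO scaffolds
N_DEPTH_SAMPLES = 500


@dataclass
class ScaffoldProfile:
    scaffold_id: str
    length: int
    mean_depth: float | None = None
    is_busco_bearing: bool = False
    n_insect_genes: int = 0
    n_te: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("scaffold length must be positive")
        if self.n_insect_genes < 0 or self.n_te < 0:
            raise ValueError("negative feature counts")


@dataclass
class ConfidenceScore:
    value: str
    depth_pvalue_raw: float | None
    depth_pvalue_adjusted: float | None
    rationale: str
    flag: str | None = None  # 'uncovered' marks low-p cases outside the A-X wording

    @property
    def endogenized(self) -> bool:
        return self.value in ENDOGENIZED_SCORES


@dataclass
class DepthTrack:
    """Windowed depth values for one scaffold (BED-style windows)."""

    scaffold_id: str
    starts: np.ndarray
    ends: np.ndarray
    depths: np.ndarray

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    def mean_depth(self, start: int | None = None, end: int | None = None) -> float:
        """Coverage-weighted mean depth over [start, end) (whole scaffold
        by default)."""
        if start is None:
            start = 0
        if end is None:
            end = self.length
        lo = np.maximum(self.starts, start)
        hi = np.minimum(self.ends, end)
        w = np.clip(hi - lo, 0, None).astype(float)
        if w.sum() == 0:
            raise ValueError(f"window [{start}, {end}) not covered on {self.scaffold_id}")
        return float(np.average(self.depths, weights=w))


def empirical_depth_pvalue(
    target_depth: float | None,
    target_length: int,
    busco_tracks: Sequence[DepthTrack],
    n_samples: int = N_DEPTH_SAMPLES,
    seed: int | np.random.Generator = 0,
    return_null: bool = False,
) -> float | None | tuple[float | None, np.ndarray]:
    """Two-sided empirical p-value of a scaffold's mean depth.

    Draws *n_samples* windows of the target scaffold's length from random
    BUSCO scaffolds (clipped to the scaffold when it is shorter, with a
    warning) and takes each window's coverage-weighted mean depth as a null
    draw. The p-value is ``2 * min(frac(null <= obs), frac(null >= obs))``
    capped at 1 — a symmetric two-sided reading of "the proportion of BUSCO
    depth values more extreme than the candidate's".

    Returns ``None`` when the target has no depth data (drives the B/E
    scores downstream).
    """
    if target_depth is None:
        return (None, np.empty(0)) if return_null else None
    if not busco_tracks:
        raise ValueError("at least one BUSCO scaffold with depth is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_samples)
    warned = False
    for i in range(n_samples):
        track = busco_tracks[rng.integers(len(busco_tracks))]
        if track.length <= target_length:
            if not warned and track.length < target_length:
                logger.warning(
                    "BUSCO scaffold %s shorter than target length %d; using full scaffold",
                    track.scaffold_id,
                    target_length,
                )
                warned = True
            start = 0
            end = track.length
        else:
            start = int(rng.integers(track.length - target_length + 1))
            end = start + target_length
        null[i] = track.mean_depth(start, end)
    p = 2.0 * min(float(np.mean(null <= target_depth)), float(np.mean(null >= target_depth)))
    p = min(p, 1.0)
    return (p, null) if return_null else p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] and be non-NaN")
    return multipletests(p, method="fdr_bh")[1]


def count_te(
    te_hits: Iterable[tuple[int, int, float, float]],
    max_e: float = 1e-10,
    min_aln_aa: float = 100.0,
) -> int:
    """Count transposable-element footprints on one scaffold.

    *te_hits* yields ``(start, end, e_value, alignment_length_aa)`` per
    hit (coordinates on the scaffold, 0-based half-open). Hits with
    E-value < *max_e* and alignment strictly greater than *min_aln_aa*
    amino acids qualify; overlapping qualifying hits are merged before
    counting, so a TE covered by several hits counts once.
    """
    qualifying = [
        (s, e) for s, e, ev, aln in te_hits if ev < max_e and aln > min_aln_aa
    ]
    return len(merge_intervals(qualifying))


def count_insect_genes(gene_taxonomies: Iterable[str]) -> int:
    """Count genes whose taxonomic assignment is insect.

    *gene_taxonomies* yields the taxonomy label of each annotated gene on
    the scaffold; only labels containing 'insect' (case-insensitive, e.g.
    'Insecta') are retained.
    """
    return sum(1 for t in gene_taxonomies if t and "insect" in t.lower())


def score_scaffold(
    profile: ScaffoldProfile,
    p_adjusted: float | None,
    busco_mean_depth: float | None,
    p_raw: float | None = None,
    alpha: float = ALPHA,
    min_environment_d: int = 5,
) -> ConfidenceScore:
    """Apply the A-X decision table to one scaffold.

    The table is total: every combination of inputs yields exactly one
    score. Precedence on the low-p side is D, then X, then F; the F score
    additionally covers the combinations the original wording leaves open
    (low p with some genes/TEs but below the D environment threshold, or
    low p with high environment but depth not above the BUSCO mean, or
    p exactly at *alpha*), flagged ``uncovered``.
    """
    genes, te = profile.n_insect_genes, profile.n_te
    env = genes + te
    depth_missing = profile.mean_depth is None
    if depth_missing and p_adjusted is not None:
        raise ValueError("adjusted p-value supplied for a scaffold without depth data")
    if not depth_missing and p_adjusted is None:
        raise ValueError("scaffold has depth but no p-value; run the depth test first")
    if p_adjusted is not None and not 0.0 <= p_adjusted <= 1.0:
        raise ValueError("adjusted p-value outside [0, 1]")

    def result(value: str, rationale: str, flag: str | None = None) -> ConfidenceScore:
        return ConfidenceScore(value, p_raw, p_adjusted, rationale, flag)

    if depth_missing:
        if env >= 1:
            return result("B", "no depth data; eukaryotic gene and/or TE present")
        return result("E", "no depth data and no eukaryotic gene nor TE; undecidable")
    if p_adjusted > alpha:
        if env >= 1:
            return result("A", "depth consistent with BUSCO scaffolds; gene/TE present")
        return result("C", "depth consistent with BUSCO scaffolds; bare scaffold")
    # low-depth-p side (p <= alpha; strict '< alpha' in the original rules,
    # p == alpha routed here and flagged)
    boundary = math.isclose(p_adjusted, alpha)
    if (
        busco_mean_depth is not None
        and profile.mean_depth > busco_mean_depth
        and env >= min_environment_d
    ):
        return result(
            "D",
            "depth significantly higher than BUSCO mean with rich host environment",
            "boundary" if boundary else None,
        )
    if genes == 0 and te == 0:
        return result(
            "X",
            "depth differs from BUSCO scaffolds, no gene nor TE; likely free-living virus",
            "boundary" if boundary else None,
        )
    literal_f = genes < min_environment_d and te == 0
    flag = None if literal_f else "uncovered"
    if boundary:
        flag = "boundary"
    return result(
        "F",
        "depth differs from BUSCO scaffolds with sparse host environment; "
        "likely free-living virus",
        flag,
    )


def score_scaffolds(
    profiles: Sequence[ScaffoldProfile],
    busco_tracks: Sequence[DepthTrack],
    busco_mean_depth: float | None,
    n_samples: int = N_DEPTH_SAMPLES,
    seed: int = 0,
    alpha: float = ALPHA,
) -> dict[str, ConfidenceScore]:
    """Depth-test, BH-adjust and score a batch of scaffolds together.

    The BH family is the set of scaffolds that have depth data; scaffolds
    without depth are scored directly (B/E rules).
    """
    rng = np.random.default_rng(seed)
    raw: dict[str, float | None] = {}
    for prof in profiles:
        raw[prof.scaffold_id] = empirical_depth_pvalue(
            prof.mean_depth, prof.length, busco_tracks, n_samples=n_samples, seed=rng
        )
    tested = [sid for sid, p in raw.items() if p is not None]
    adj = dict(zip(tested, bh_adjust([raw[s] for s in tested]))) if tested else {}
    return {
        prof.scaffold_id: score_scaffold(
            prof,
            adj.get(prof.scaffold_id),
            busco_mean_depth,
            p_raw=raw[prof.scaffold_id],
            alpha=alpha,
        )
        for prof in profiles
    }
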