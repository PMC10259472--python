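"""Domestication evidence: dN/dS branch test, expression, intact ORFs.

An EVE is called domesticated when the branches leading to it evolve
under purifying selection (two-ratio branch codon model, likelihood-ratio
test against a neutral foreground, BH-controlled FDR, with saturated
comparisons dS > 10 removed) or when the gene is highly expressed
(TPM > 1000). A pathway-counting (Nei-Gojobori 1986 style) estimator is
provided as an independent cross-check of the likelihood route, and the
module accepts externally computed (dN, dS, p) tables so full branch-model
output from dedicated software can be plugged in.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

from . import codonmodel as cm
from .confidence import bh_adjust

logger = logging.getLogger(__name__)

TPM_THRESHOLD = 1000.0  # control-EVE median 718.70, rounded up to be conservative
SATURATION_DS = 10.0
FDR = 0.05


@dataclass
class SelectionTestResult:
    clade_id: str
    dN: float = float("nan")
    dS: float = float("nan")
    omega: float = float("nan")
    omega_se: float | None = None
    p_value: float = float("nan")
    q_value: float = float("nan")
    untestable: bool = False
    kappa: float = float("nan")
    omega_background: float = float("nan")

    @property
    def saturated(self) -> bool:
        return bool(self.dS > SATURATION_DS) or (not math.isnan(self.dS) and np.isinf(self.dS))


@dataclass
class ExpressionRecord:
    gene_id: str
    tissue: str
    raw_count: float
    effective_length: float
    tpm: float = float("nan")


# ---------------------------------------------------------------------------
# Nei-Gojobori pathway counting (independent of the likelihood route)
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes its fraction of synonymous single-nucleotide
    changes; changes creating stop codons count as nonsynonymous.
    """
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in cm.STOP_CODONS and cm.translate(mutant) == cm.translate(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over mutational
    pathways between two codons, skipping pathways through stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in cm.STOP_CODONS:
                ok = False
                break
            if cm.translate(cur) == cm.translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:  # all pathways blocked by stops; count everything nonsyn
        return 0.0, float(len(diff_pos))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def ng86_pairwise(seq1: str, seq2: str) -> tuple[float, float]:
    """Nei-Gojobori (1986) pairwise (dN, dS) with Jukes-Cantor correction.

    Saturated proportions (p >= 3/4) yield ``inf``. Gapped or ambiguous
    codon columns are skipped.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be equal-length codon alignments")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if c1 not in cm.CODON_INDEX or c2 not in cm.CODON_INDEX:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        dsd, dnd = _pathway_differences(c1, c2)
        sd += dsd
        nd += dnd

    def _jc(p_obs: float) -> float:
        if p_obs >= 0.75:
            return float("inf")
        return -0.75 * math.log(1.0 - 4.0 * p_obs / 3.0)

    ds = _jc(sd / s_sites) if s_sites > 0 else float("nan")
    dn = _jc(nd / n_sites) if n_sites > 0 else float("nan")
    return dn, ds


def ng86_clade(alignment: Mapping[str, str], clade_taxa: Sequence[str]) -> tuple[float, float]:
    """Mean pairwise NG86 (dN, dS) among clade members.

    With a single member, pairs it against every other sequence in the
    alignment instead.
    """
    taxa = [t for t in clade_taxa if t in alignment]
    pairs = (
        list(itertools.combinations(taxa, 2))
        if len(taxa) >= 2
        else [(taxa[0], o) for o in alignment if o != taxa[0]]
    )
    if not pairs:
        return float("nan"), float("nan")
    dns, dss = [], []
    for a, b in pairs:
        dn, ds = ng86_pairwise(alignment[a], alignment[b])
        dns.append(dn)
        dss.append(ds)
    return float(np.mean(dns)), float(np.mean(dss))


# ---------------------------------------------------------------------------
# likelihood two-ratio branch model
# ---------------------------------------------------------------------------

def _prepare_tree(tree: dendropy.Tree, foreground: set[str]):
    """Postorder edge list with foreground marking.

    An edge is foreground when every leaf below it belongs to the
    foreground clade. Returns (postorder nodes, leaf->taxon map).
    """
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._fg = node.taxon.label in foreground
        else:
            node._fg = all(ch._fg for ch in node.child_nodes())
    return list(tree.postorder_node_iter())


def _site_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pats, counts = np.unique(matrix, axis=1, return_counts=True)
    return pats, counts.astype(float)


def _loglik(
    tree_nodes,
    pats: np.ndarray,
    counts: np.ndarray,
    taxon_row: Mapping[str, int],
    kappa: float,
    omega_fg: float,
    omega_bg: float,
    scale: float,
) -> float:
    q_fg = cm.rate_matrix(kappa, omega_fg)
    q_bg = cm.rate_matrix(kappa, omega_bg)
    n_sites = pats.shape[1]
    for node in tree_nodes:
        if node.is_leaf():
            states = pats[taxon_row[node.taxon.label]]
            partial = np.zeros((n_sites, cm.N_CODONS))
            known = states >= 0
            partial[known, states[known]] = 1.0
            partial[~known] = 1.0  # gap/ambiguous: uninformative
            node._partial = partial
        else:
            partial = np.ones((n_sites, cm.N_CODONS))
            for ch in node.child_nodes():
                t = (ch.edge.length or 0.0) * scale
                q = q_fg if ch._fg else q_bg
                p = cm.transition_probabilities(q, t)
                partial = partial * (ch._partial @ p.T)
            node._partial = partial
    root = tree_nodes[-1]
    site_lik = root._partial.mean(axis=1)  # uniform codon frequencies at root
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.dot(np.log(site_lik), counts))


def estimate_omega(
    alignment: Mapping[str, str],
    gene_tree: dendropy.Tree,
    foreground_clade: Sequence[str],
    clade_id: str = "clade",
) -> SelectionTestResult:
    """Two-ratio branch test of purifying selection on a foreground clade.

    The foreground branches (those leading only to *foreground_clade*
    leaves) get their own omega; the alternative model estimates it
    freely, the null fixes it at 1 (neutral evolution). The p-value is a
    chi-square LRT with 1 df. The reported dN/dS is the likelihood
    estimate averaged over the clade's branches (one shared omega here);
    dN and dS come from the counting cross-check and drive the dS > 10
    saturation exclusion.
    """
    fg = set(foreground_clade)
    taxa = sorted(alignment)
    lengths = {len(alignment[t]) for t in taxa}
    if len(lengths) != 1 or next(iter(lengths)) % 3:
        raise ValueError("alignment sequences must share a length divisible by 3")
    tree = gene_tree
    tree_taxa = {t.label for t in tree.taxon_namespace}
    if not fg <= tree_taxa:
        raise ValueError(f"foreground taxa missing from tree: {sorted(fg - tree_taxa)}")

    result = SelectionTestResult(clade_id=clade_id)
    dn, ds = ng86_clade(alignment, sorted(fg))
    result.dN, result.dS = dn, ds

    rows = {t: i for i, t in enumerate(taxa)}
    matrix = np.stack([cm.encode_codon_sequence(alignment[t]) for t in taxa])
    fg_rows = [rows[t] for t in fg if t in rows]
    fg_sub = matrix[fg_rows]
    informative = fg_sub[:, np.all(fg_sub >= 0, axis=0)]
    if len(fg_rows) < 1 or informative.size == 0:
        result.untestable = True
        return result
    if len(fg_rows) >= 2 and np.all(informative == informative[0]):
        # identical foreground sequences: no substitutions to test
        result.untestable = True
        result.dN = result.dS = 0.0
        result.omega = float("nan")
        return result

    nodes = _prepare_tree(tree, fg)
    has_bg = any(not n._fg for n in nodes if n.parent_node is not None)
    pats, counts = _site_patterns(matrix)

    def negll(x, omega_fg=None):
        i = 0
        kappa = math.exp(x[i]); i += 1
        if omega_fg is None:
            w_fg = math.exp(x[i]); i += 1
        else:
            w_fg = omega_fg
        w_bg = math.exp(x[i]) if has_bg else w_fg
        if has_bg:
            i += 1
        scale = math.exp(x[i])
        return -_loglik(nodes, pats, counts, rows, kappa, w_fg, w_bg, scale)

    x0_alt = [math.log(2.0), math.log(0.5)] + ([math.log(0.5)] if has_bg else []) + [0.0]
    x0_null = [math.log(2.0)] + ([math.log(0.5)] if has_bg else []) + [0.0]
    opt_alt = optimize.minimize(negll, x0_alt, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
    opt_null = optimize.minimize(lambda x: negll(x, omega_fg=1.0), x0_null,
                                 method="Nelder-Mead",
                                 options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
    ll_alt, ll_null = -opt_alt.fun, -opt_null.fun
    i = 1
    result.kappa = math.exp(opt_alt.x[0])
    result.omega = math.exp(opt_alt.x[i]); i += 1
    result.omega_background = math.exp(opt_alt.x[i]) if has_bg else result.omega
    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    result.p_value = float(stats.chi2.sf(lrt, df=1))
    return result


def results_from_table(table) -> list[SelectionTestResult]:
    """Build test results from an externally computed (dN, dS, p) table.

    *table* is a DataFrame-like with columns ``clade_id``, ``dN``, ``dS``,
    ``omega``, ``p_value`` (extra columns ignored), e.g. branch-model
    output from dedicated selection software; feed the result to
    :func:`apply_fdr_and_saturation` and :func:`classify_domestication`.
    """
    out = []
    for row in table.itertuples(index=False):
        out.append(
            SelectionTestResult(
                clade_id=str(row.clade_id),
                dN=float(row.dN),
                dS=float(row.dS),
                omega=float(row.omega),
                p_value=float(row.p_value),
            )
        )
    return out


def apply_fdr_and_saturation(
    results: Sequence[SelectionTestResult], fdr: float = FDR
) -> list[SelectionTestResult]:
    """BH-adjust the testable p-values; saturated results are excluded
    from the adjustment family and never called."""
    testable = [
        r for r in results
        if not r.untestable and not r.saturated and not math.isnan(r.p_value)
    ]
    if testable:
        qs = bh_adjust([r.p_value for r in testable])
        for r, q in zip(testable, qs):
            r.q_value = float(q)
    for r in results:
        if r.saturated:
            r.q_value = float("nan")
    return list(results)


def compute_tpm(counts: Sequence[float], effective_lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per kilobase million.

    TPM_i = (count_i / length_i) / sum_j (count_j / length_j) * 1e6; sums
    to 1e6 over the sample by construction.
    """
    c = np.asarray(counts, dtype=float)
    ln = np.asarray(effective_lengths, dtype=float)
    if np.any(ln <= 0):
        raise ValueError("effective lengths must be positive")
    rate = c / ln
    total = rate.sum()
    if total == 0:
        logger.warning("all-zero counts; TPM undefined, returning zeros")
        return np.zeros_like(rate)
    return rate / total * 1e6


def classify_domestication(
    selection: SelectionTestResult | None,
    max_tpm: float | None,
    tpm_threshold: float = TPM_THRESHOLD,
    fdr: float = FDR,
) -> tuple[bool | None, str]:
    """Domestication call from the two evidence streams.

    Domesticated iff the dN/dS test is significant with omega < 1 (and not
    saturated), or max TPM across tissues exceeds *tpm_threshold*. Returns
    ``(flag, evidence_code)``; flag is ``None`` (untestable) when neither
    stream is available.
    """
    dnds_ok = (
        selection is not None
        and not selection.untestable
        and not selection.saturated
        and not math.isnan(selection.q_value)
        and selection.q_value < fdr
        and selection.omega < 1.0
    )
    tpm_ok = max_tpm is not None and max_tpm > tpm_threshold
    dnds_available = selection is not None and not selection.untestable and not selection.saturated
    if not dnds_available and max_tpm is None:
        return None, "untestable"
    if dnds_ok and tpm_ok:
        return True, "dnds+tpm"
    if dnds_ok:
        return True, "dnds"
    if tpm_ok:
        return True, "tpm"
    return False, "none"


_STOPS = set(cm.STOP_CODONS)


def longest_orf_aa(sequence: str, min_aa: int = 1) -> int:
    """Longest stop-to-stop open reading frame, in amino acids, over all
    six frames."""
    seq = sequence.upper().replace("U", "T")
    comp = str.maketrans("ACGT", "TGCA")
    best = 0
    for strand_seq in (seq, seq.translate(comp)[::-1]):
        for frame in range(3):
            run = 0
            for i in range(frame, len(strand_seq) - 2, 3):
                codon = strand_seq[i : i + 3]
                if codon in _STOPS or any(b not in "ACGT" for b in codon):
                    best = max(best, run)
                    run = 0
                else:
                    run += 1
            best = max(best, run)
    return best if best >= min_aa else 0


def intact_orf(
    eve_orf_length_aa: float, viral_orf_length_aa: float, min_frac: float = 0.50
) -> bool:
    """Is the EVE's longest ORF at least *min_frac* of the donor ORF?"""
    if eve_orf_length_aa < 0 or viral_orf_length_aa <= 0:
        raise ValueError("ORF lengths must be positive")
    return eve_orf_length_aa / viral_orf_length_aa >= min_frac
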