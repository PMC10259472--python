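# Methods

This note records the models implemented in `endovir`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want written
down. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Detection and taxonomic screening

Viral homology hits arrive in a BLAST 12-column tabular dialect extended
with subject length and virus taxonomy columns; 1-based inclusive
coordinates are converted to 0-based half-open intervals at the reader
and nowhere else. A hit is retained when viral-protein coverage ≥ 30%,
identity ≥ 20% and E-value < 5e-4 (all three boundaries inclusive /
strict exactly as written). Overlap merging is the transitive closure of
*strict* overlap — abutting hits (`a.end == b.start`) are separate loci,
because a zero-length overlap is not an overlap — and is checked against
an O(n²) pairwise-closure oracle in the tests.

The generalist (Nr-style) screen is summarized per scaffold with
Hymenoptera hits removed at the reader: a genuinely shared
endogenization will look like a "eukaryotic" hit whenever a database
wasp genome carries the same EVE, and must not count against the locus.
The screen then drops a locus with more than 25 combined eukaryotic
(non-Hymenoptera) + prokaryotic hits unless it also matched at least 10
distinct viral species at bit ≥ 50, and drops single-hit loci with more
than 5 background hits. "More than 5" counts eukaryotic and prokaryotic
hits jointly, which is how the rule reads. Chuviral glycoproteins
captured by LTR retrotransposons are removed by a dedicated rule (locus
overlaps a retrotransposon-class TE annotation *and* the best hit is a
chuvirus glycoprotein), since their copy number reflects transposition,
not independent endogenization.

Best-hit selection breaks E-value ties by higher bit score; this
tie-break is a package decision, not sourced text.

## The A–X confidence index

The depth test resamples, per candidate scaffold, 500 windows of the
scaffold's length from random BUSCO-bearing scaffolds (windows clip to
the scaffold with a logged warning when no BUSCO scaffold is long
enough) and takes each window's coverage-weighted mean depth as a null
draw. The p-value is the symmetric two-sided reading
`p = 2·min(frac(null ≤ obs), frac(null ≥ obs))`, capped at 1; a
recount over the identical seeded draws is asserted in the tests.
p-values are BH-adjusted across the scaffolds that have depth, and the
adjusted value drives the table ("corrected coverage p-value").

The published seven rules leave gaps; the implemented table is total:

- depth missing → **B** if ≥ 1 insect gene or TE else **E**;
- adjusted p > 0.05 → **A** if ≥ 1 gene/TE else **C**;
- otherwise (p ≤ 0.05): **D** when depth exceeds the BUSCO mean and
  genes + TEs ≥ 5; else **X** when the scaffold is bare; else **F**.

`p == 0.05` exactly satisfies neither "> 0.05" nor "< 0.05"; it is
routed to the low-depth side and flagged `boundary`. Low-p scaffolds
with some environment but below the D threshold, or with ≥ 5 gene/TEs
but depth not above the BUSCO mean, are not covered by the original
wording; they are scored F with flag `uncovered` and can be reported
separately. TE counting requires E < 1e-10 and alignment strictly
greater than 100 aa, with overlapping qualifying hits merged first.

## Events

Within a species, the aggregation rules — same scaffold (same genomic
structure only) and same known viral family — run through a union–find
closure, so the result is an order-invariant partition. Unknown families
never merge by family. Across species, a gene-tree clade with support
strictly above 80 merges events when its species map onto a species-tree
clade with at most 20% of that clade's (same-host-family) species
missing, and all species share one host taxonomic family. Because the
cross-species merge reuses the same union–find, co-scaffolding in one
species automatically propagates the merge to the homologous EVEs of
related species. Events touching several families report
`family = "multiple"` and are excluded from family-level tallies only.

Branch mapping: single-species events map to the terminal branch,
multi-species events to the stem branch of the MRCA.

Synteny validation: HSPs with bit score > 50 are merged (interval
union) before summation, so overlapping HSPs are never double-counted.
Calibration simulates, per window size, 500 pairs of (i) two disjoint
random windows and (ii) one window against its own copy, and picks the
smallest threshold whose scenario-(i) exceedance is ≤ 0.015. On
synthetic sequence without substitution noise, HSP discovery is exact
k-mer (k = 15) seed matching with diagonal-run merging — the desk-scale
analogue of a tblastx self-comparison; scenario (ii) therefore
saturates at the window length and TP = 1 by construction, which is the
intended behaviour on zero-divergence copies. An event's window-size
class is the calibrated class nearest in log10 to its scaffold length.

## Domestication

The likelihood route is a two-ratio branch codon model: GY94-style rate
matrix over the 61 sense codons with a transition/transversion ratio κ,
equal codon frequencies, and a separate ω on foreground branches (those
whose descendant leaves all belong to the EVE clade). Branch lengths are
taken from the input tree up to one fitted scale factor; the null fixes
the foreground ω at 1 and the LRT uses χ² with 1 df. "Significantly
below 1" is implemented as q < 0.05 ∧ ω̂ < 1 (the LRT itself is
two-sided). For a two-sequence clade the whole pair is the foreground;
marking only one branch of a pair leaves the split weakly identifiable
(no outgroup polarizes the substitutions) and is not supported usage.
Results with dS > 10 are saturated and excluded before calling; dN and
dS are reported from the independent Nei–Gojobori (1986) pathway count
(Jukes–Cantor corrected, `inf` when p ≥ 3/4), which also serves as the
rank-order cross-check of the likelihood route. Externally computed
(dN, dS, p) tables can be fed directly into the FDR/classification
steps, so full branch-model output from dedicated software plugs in.

TPM is the standard within-sample normalization
`(count/length) / Σ(count/length) × 1e6`; the domestication threshold
is 1000 TPM (a conservative round-up of the control median of ~719),
taken as the maximum over available tissues. Intact-ORF status uses a
six-frame stop-to-stop scan and a ≥ 50% length ratio to the donor ORF.

## Enrichment statistics

Expected structure proportions come from database species counts with
unknown-structure viruses discarded. Goodness of fit is Pearson's χ²
with k−1 df; the strand test is its 1-df special case against the
database negative-strand proportion. The lifestyle test builds, per
genomic structure, a 2×k table of observed event counts versus expected
counts (total × lifestyle frequency, largest-remainder rounding to
preserve the total) and computes the exact conditional p-value by full
enumeration over the two free cells (Monte-Carlo with a fixed seed
beyond 2·10⁶ enumerated cells); BH correction runs across structures,
separately for event and domestication analyses. The 2×k enumeration
reproduces `scipy.stats.fisher_exact` on 2×2 tables and R's
`fisher.test` on 2×3 tables to 1e-10. The shared-gene test is the
upper-tail binomial probability P(X ≥ x).

## Mk model and ancestral scenarios

The lifestyle character evolves under an unequal-rates Mk model (6 free
rates for 3 states, 12 for 4 when an eusocial category is used), uniform
root prior, independent exponential priors on the rates (default mean
0.01 per My — weakly informative on the scale of a few transitions per
100 My). The pruning likelihood uses one eigendecomposition of Q per
evaluation, vectorized transition matrices for all edges, level-wise
vectorized pruning and periodic rescaling; it is checked to 1e-10
against full ancestral-state enumeration on 4-taxon trees.

The sampler is random-walk Metropolis on log-rates, one randomly chosen
rate per cycle, with proposal scales auto-tuned in a preliminary run
(1000 cycles, tuning every 300) and frozen afterwards. The default
schedule is 200,000 cycles, thinning 200, burn-in 50,000, two chains;
convergence is reported (per-rate ESS with target 100, rank-normalized
R-hat, two-sample KS between chains) and failures flag the result
rather than raising. Joint ancestral scenarios are drawn by backward
filtering / forward sampling conditional on a posterior rate draw: root
from prior × conditional likelihood, then each child given its parent
and the data below it. The state of a node is constant along the branch
leading to that node, so a branch carries its head-node state. Joint
draws are checked to marginalize to the exact up-down node posteriors.

## Branch GLMs

Branches from nodes older than 160 My are excluded before fitting (node
age decides, not the branch midpoint). The ZINB model is
`y_b ~ ZINB(μ_b, size, π)` with
`log μ_b = β₀ + β_ecto + β_endo + β_len·z(log length) + β_ecto:len`,
free-living the reference level and, by default, only the
ectoparasitoid×length interaction (the full-interaction variant is a
flag). Branch length enters as a standardized **log**-length covariate
with a free coefficient: exposure is multiplicative in time, so the
log-mean is linear in log-length; a linear-scale covariate cannot absorb
the exposure effect when lifestyle correlates with branch length (young
parasitoid clades have short branches) and demonstrably attenuates the
lifestyle coefficients. It remains a covariate, not an offset. Priors:
N(0, 5²) on coefficients, uniform on the zero-inflation probability
(sampled on the logit scale with the Jacobian), log-normal(0, 1.5) on
the NB size. The binomial model uses branches with ≥ 1 event,
logit-link, the same coefficient priors.

Both models are sampled by joint adaptive random-walk Metropolis
(Robbins–Monro scale adaptation toward 0.234 and per-dimension spreads
estimated during warmup, frozen for sampling); defaults are 4 chains ×
10,000 iterations, thinning 5. Per-scenario fits are screened
(degenerate likelihood, acceptance rate outside [0.05, 0.8]) before
pooling; a summary with > 50% failed scenarios is flagged. Summaries:
rate ratio = median of exp(pooled draws), equal-tailed 89% credible
interval (deterministic, unlike highest-density intervals; an HDI
switch is future work), pd = max(share > 0, share < 0) — which also
defines the degenerate exactly-zero-median case — and
P(endo > ecto) as the pooled share of draws with the endoparasitoid
coefficient above the ectoparasitoid one.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure the analyses assume,
at a scale a laptop can iterate on:

- **Species trees.** Forward-simulated constant-rate birth–death,
  stopped at the (unexecuted) event after the n-th birth, extinct
  lineages pruned. Default birth 0.0157/My, death 0: a 124-tip tree has
  expected crown age ≈ 280 My, the scale of the Hymenoptera radiation.
  The pure-birth mean crown age `(1/λ)·Σ_{k=2..n} 1/k` is asserted in
  the tests.
- **Lifestyles.** Mk simulation at 0.001/My per transition — a handful
  of transitions clade-wide, matching how conserved parasitoid
  lifestyles are. Because the study design samples species of every
  lifestyle in substantial numbers (roughly 63/24/37 of 124), the
  comparative recovery experiment redraws histories until each
  lifestyle reaches ≥ 15% of tips.
- **Branch counts.** Zero-inflated negative binomial with
  structural-zero probability 0.2 and NB size 10 — mildly
  overdispersed, near-Poisson, consistent with the posterior precision
  the model family attains on real data. Default rates 0.030/My
  (free-living, ectoparasitoid) give a few hundred events per 124-tip
  tree, the scale of a clade-wide screen; recovery experiments set the
  endoparasitoid rate as a multiple of free-living.
- **Genome bundles.** Random-sequence scaffolds (20 host, of which 5
  long BUSCO scaffolds at 200 kb — the depth null needs many distinct
  resampled windows, and BUSCO scaffolds are the well-assembled
  fraction), a shared repeat library (5% density) driving TE counts and
  synteny false positives, planted EVEs whose hit parameters straddle
  the filter thresholds (every planted EVE keeps at least one passing
  hit), decoy loci with eukaryote-heavy generalist profiles, and
  contaminant scaffolds at 95.6× against a 33× host, with no genes or
  TEs. The default planting layout is constructed to agree with the
  within-species aggregation rules (unique family per event, no
  same-structure scaffold sharing), so the truth table is the exact
  target partition.
- **Codon alignments.** GY94-style simulation with equal codon
  frequencies; no indels, no internal stops by construction.

Not emulated: raw reads and assembly artifacts, indel structure,
sequence-level divergence of planted EVEs (hits are generated directly,
not re-discovered by alignment), search-tool score distributions, and
real lifestyle misassignment. Passing tests therefore demonstrate the
pipeline's logic and calibration under its own assumptions, not
robustness to assembly noise or annotation error.

## Problem sizes

The long-running checks are scaled deliberately: the comparative
recovery experiment uses 20,000 Mk cycles (burn-in 5,000, thinning 20,
one chain), 200 ancestral scenarios and short adaptive ZINB chains
(300 warmup + 600 iterations, thinned by 2) per scenario, with 20
replicates per arm; the synthetic genome bundle uses ~1 Mb of sequence
and 20 planted EVEs. These sizes keep one replicate near twenty seconds
while leaving the pooled posterior enough draws (> 50,000) for stable
89% intervals.

## Known limitations

- The two-ratio codon model is a desk-scale stand-in for a full branch
  model with estimated codon frequencies and per-branch lengths;
  standard errors of ω are not reported from the optimizer (bootstrap
  or external tables are the supported routes).
- The taxonomic screen is summarized per scaffold, not per locus; loci
  sharing a scaffold share a background profile.
- The Mk sampler updates one rate per cycle; for strongly correlated
  rate posteriors a blocked sampler would mix faster.
- Fisher tests compare observed allocations against rounded expected
  allocations; with very small expected totals the rounding step can
  matter.
- The synteny calibration assumes zero divergence between shared
  copies; on real genomes thresholds must be recalibrated with a real
  aligner.
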