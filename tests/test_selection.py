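"""dN/dS estimation, expression thresholds and domestication calls."""

import math

import dendropy
import numpy as np
import pytest

from endovir.selection import (
    SelectionTestResult,
    apply_fdr_and_saturation,
    classify_domestication,
    compute_tpm,
    estimate_omega,
    intact_orf,
    longest_orf_aa,
    ng86_clade,
    ng86_pairwise,
)
from endovir.simulate.codons import pair_alignment, simulate_codon_alignment


class TestNg86:
    def test_single_synonymous_difference(self):
        # 10 identical codons plus GGT->GGC (glycine, synonymous)
        base = "ATGACTGAACTTCCTAAGGATCGTTGGAAA"
        dn, ds = ng86_pairwise(base + "GGT", base + "GGC")
        assert dn == 0.0
        assert ds > 0.0

    def test_single_nonsynonymous_difference(self):
        base = "ATGACTGAACTTCCTAAGGATCGTTGGAAA"
        dn, ds = ng86_pairwise(base + "GGT", base + "AGT")  # Gly -> Ser
        assert ds == 0.0
        assert dn > 0.0

    def test_identical_sequences(self):
        dn, ds = ng86_pairwise("ATGGCTAAA", "ATGGCTAAA")
        assert dn == 0.0 and ds == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng86_pairwise("ATGGCT", "ATG")


class TestEstimateOmega:
    def test_purifying_selection_detected(self):
        aln, tree = pair_alignment(0.3, 0.3, omega=0.1, n_codons=300, seed=5)
        res = estimate_omega(aln, tree, ["seq1", "seq2"])
        assert res.omega < 0.5
        assert res.p_value < 0.05

    def test_omega_recovery_across_grid(self):
        """Median likelihood estimate within 20% of truth per omega level."""
        for omega in (0.1, 0.5, 1.0, 2.0):
            ests = []
            for rep in range(6):
                aln, tree = pair_alignment(
                    0.3, 0.3, omega=omega, n_codons=300, seed=1000 * rep + int(omega * 10)
                )
                ests.append(estimate_omega(aln, tree, ["seq1", "seq2"]).omega)
            assert np.median(ests) == pytest.approx(omega, rel=0.25)

    def test_neutral_type_i_error_near_nominal(self):
        """Under omega=1 the LRT rejects at roughly the 5% level."""
        rejections = 0
        n = 40
        for rep in range(n):
            aln, tree = pair_alignment(0.4, 0.4, omega=1.0, n_codons=200, seed=7000 + rep)
            res = estimate_omega(aln, tree, ["seq1", "seq2"])
            rejections += res.p_value < 0.05
        # binomial(40, 0.05): central 99.9% mass lies below 9
        assert rejections <= 9

    def test_identical_sequences_untestable(self):
        tree = dendropy.Tree.get(data="(a:0.1,b:0.1);", schema="newick")
        aln = {"a": "ATGGCTAAACCT" * 20, "b": "ATGGCTAAACCT" * 20}
        res = estimate_omega(aln, tree, ["a", "b"])
        assert res.untestable
        assert res.dN == 0.0 and res.dS == 0.0

    def test_counting_and_likelihood_agree_in_rank(self):
        """The pathway-counting ratio orders a synthetic panel like the
        likelihood estimate (independent cross-check routes)."""
        lik, cnt = [], []
        for i, omega in enumerate((0.1, 0.3, 1.0, 2.5)):
            aln, tree = pair_alignment(0.4, 0.4, omega=omega, n_codons=400, seed=300 + i)
            res = estimate_omega(aln, tree, ["seq1", "seq2"])
            dn, ds = ng86_pairwise(aln["seq1"], aln["seq2"])
            lik.append(res.omega)
            cnt.append(dn / ds if ds > 0 else float("inf"))
        assert np.all(np.argsort(lik) == np.argsort(cnt))

    def test_foreground_with_background_branches(self):
        nw = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"
        aln = simulate_codon_alignment(nw, omega=0.2, n_codons=300, seed=7)
        tree = dendropy.Tree.get(data=nw, schema="newick")
        res = estimate_omega(aln, tree, ["A", "B"])
        assert 0.05 < res.omega < 0.6
        assert res.p_value < 0.05


class TestFdrSaturation:
    def test_saturated_excluded_regardless_of_p(self):
        r = SelectionTestResult("sat", dN=1.0, dS=10.5, omega=0.1, p_value=1e-6)
        out = apply_fdr_and_saturation([r])[0]
        assert out.saturated and math.isnan(out.q_value)

    def test_single_test_q_equals_p(self):
        r = SelectionTestResult("a", dN=0.1, dS=0.5, omega=0.2, p_value=0.01)
        assert apply_fdr_and_saturation([r])[0].q_value == pytest.approx(0.01)

    def test_all_null_none_significant(self):
        rs = [
            SelectionTestResult(f"t{i}", dN=0.2, dS=0.2, omega=1.0, p_value=1.0)
            for i in range(20)
        ]
        out = apply_fdr_and_saturation(rs)
        assert all(r.q_value == pytest.approx(1.0) for r in out)


class TestTpm:
    def test_single_gene_takes_everything(self):
        assert compute_tpm([7], [500]) == pytest.approx([1e6])

    def test_equal_counts_equal_lengths(self):
        assert compute_tpm([10, 10], [800, 800]) == pytest.approx([5e5, 5e5])

    def test_length_normalization_closed_form(self):
        got = compute_tpm([10, 10], [1000, 2000])
        assert got == pytest.approx([666_666.6667, 333_333.3333], rel=1e-6)

    def test_sums_to_one_million(self, rng):
        counts = rng.integers(0, 500, size=30)
        counts[0] = 7  # ensure non-degenerate
        lengths = rng.integers(200, 5000, size=30)
        assert compute_tpm(counts, lengths).sum() == pytest.approx(1e6, rel=1e-9)

    def test_zero_total_warns_and_zeroes(self):
        assert compute_tpm([0, 0], [100, 100]) == pytest.approx([0.0, 0.0])


class TestClassifyDomestication:
    def test_significant_purifying_selection(self):
        r = SelectionTestResult("a", dN=0.05, dS=0.3, omega=0.17, p_value=0.01, q_value=0.03)
        assert classify_domestication(r, None) == (True, "dnds")

    def test_high_tpm_alone(self):
        assert classify_domestication(None, 362_836.0) == (True, "tpm")

    def test_tpm_boundary_strictly_above(self):
        assert classify_domestication(None, 1000.0) == (False, "none")
        assert classify_domestication(None, 1000.1) == (True, "tpm")

    def test_neither_stream_fires(self):
        r = SelectionTestResult("a", dN=0.3, dS=0.3, omega=0.9, p_value=0.2, q_value=0.2)
        assert classify_domestication(r, 500.0) == (False, "none")

    def test_untestable_when_no_evidence(self):
        assert classify_domestication(None, None) == (None, "untestable")
        sat = SelectionTestResult("a", dN=2.0, dS=11.0, omega=0.2, p_value=0.01, q_value=0.01)
        assert classify_domestication(sat, None) == (None, "untestable")


class TestIntactOrf:
    def test_half_length_is_intact(self):
        assert intact_orf(150, 300) is True

    def test_just_below_half_is_not(self):
        assert intact_orf(149, 300) is False

    def test_premature_stop_shortens_orf(self):
        codons = ["GCT"] * 120
        full = "ATG" + "".join(codons)
        interrupted = "ATG" + "".join(codons[:30]) + "TAA" + "".join(codons[30:50])
        full_orf = longest_orf_aa(full)
        broken_orf = longest_orf_aa(interrupted)
        assert broken_orf < full_orf
        assert intact_orf(broken_orf, full_orf, min_frac=0.50) is False


def test_ng86_clade_mean_pairwise():
    aln, _ = pair_alignment(0.2, 0.2, omega=0.5, n_codons=200, seed=11)
    dn_pair, ds_pair = ng86_pairwise(aln["seq1"], aln["seq2"])
    dn, ds = ng86_clade(aln, ["seq1", "seq2"])
    assert dn == pytest.approx(dn_pair) and ds == pytest.approx(ds_pair)
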