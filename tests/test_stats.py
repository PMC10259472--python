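"""Enrichment statistics against textbook/enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from endovir.stats import (
    AbundanceTable,
    LifestyleFrequencies,
    expected_structure_distribution,
    fisher_exact_2xk,
    gof_chisq,
    lifestyle_fisher,
    shared_gene_binomial,
    strand_bias_test,
)

INSECT_VIRUS_COUNTS = {
    "ssRNA(-)": 597,
    "ssRNA(+)": 1240,
    "ssDNA": 78,
    "dsRNA": 401,
    "dsDNA": 145,
    "unknown": 148,
}


class TestExpectedDistribution:
    def test_known_structure_proportions(self):
        table = AbundanceTable(INSECT_VIRUS_COUNTS)
        props = expected_structure_distribution(table)
        assert "unknown" not in props
        assert sum(props.values()) == pytest.approx(1.0)
        assert props["ssRNA(-)"] == pytest.approx(597 / 2461)

    def test_single_category(self):
        props = expected_structure_distribution(AbundanceTable({"dsDNA": 7, "unknown": 3}))
        assert props == {"dsDNA": 1.0}

    def test_scaling_invariance(self):
        a = expected_structure_distribution(AbundanceTable({"a": 3, "b": 9}))
        b = expected_structure_distribution(AbundanceTable({"a": 300, "b": 900}))
        assert a == pytest.approx(b)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            expected_structure_distribution(AbundanceTable({"a": 0, "unknown": 5}))


class TestGofChisq:
    def test_exact_fit_gives_zero(self):
        chi2, df, p = gof_chisq([30, 60, 10], [0.3, 0.6, 0.1])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        chi2, df, p = gof_chisq([10, 0], [0.5, 0.5])
        assert chi2 == pytest.approx(10.0) and df == 1

    def test_matches_textbook_formula_on_random_tables(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 6))
            obs = rng.integers(0, 50, size=k).astype(float)
            obs[0] += 1
            props = rng.uniform(0.1, 1.0, size=k)
            props /= props.sum()
            chi2, df, p = gof_chisq(obs, props)
            exp = props * obs.sum()
            oracle = float(np.sum((obs - exp) ** 2 / exp))
            assert chi2 == pytest.approx(oracle, abs=1e-10)
            assert p == pytest.approx(float(sps.chi2.sf(oracle, k - 1)), abs=1e-10)

    def test_zero_expected_with_observations_rejected(self):
        with pytest.raises(ValueError):
            gof_chisq([5, 5], [1.0, 0.0])


class TestStrandBias:
    def test_database_proportion_from_printed_counts(self):
        prop, chi2, p = strand_bias_test(26, 10, (597, 1240))
        assert round(100 * prop, 1) == 32.5

    def test_observation_at_expectation(self):
        prop, chi2, p = strand_bias_test(325, 675, (325, 675))
        assert chi2 == pytest.approx(0.0)

    def test_matches_independent_recomputation(self):
        prop, chi2, _ = strand_bias_test(72, 28, (597, 1240))
        e_neg = 100 * 597 / 1837
        e_pos = 100 - e_neg
        oracle = (72 - e_neg) ** 2 / e_neg + (28 - e_pos) ** 2 / e_pos
        assert chi2 == pytest.approx(oracle, abs=1e-10)


def enumeration_fisher_2xk(table):
    """Independent exact-test oracle: full enumeration over first-row
    compositions (multivariate hypergeometric, two-sided by probability)."""
    t = np.asarray(table, dtype=int)
    row0 = t[0].sum()
    col = t.sum(axis=0)
    n = t.sum()

    def prob(first):
        num = 1.0
        for c, x in zip(col, first):
            num *= math.comb(c, x)
        return num / math.comb(n, row0)

    p_obs = prob(t[0])
    total = 0.0
    ranges = [range(c + 1) for c in col]
    for combo in itertools.product(*ranges):
        if sum(combo) != row0:
            continue
        p = prob(combo)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestFisher2xk:
    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            t[0, 0] += 1
            t[1, 1] += 1
            assert fisher_exact_2xk(t) == pytest.approx(
                sps.fisher_exact(t)[1], abs=1e-10
            )

    def test_matches_enumeration_oracle_on_small_2x3(self, rng):
        for _ in range(12):
            t = rng.integers(0, 6, size=(2, 3))
            t[0, 0] += 1
            t[1, 2] += 1
            assert fisher_exact_2xk(t) == pytest.approx(
                enumeration_fisher_2xk(t), abs=1e-10
            )

    def test_proportional_table_not_significant(self):
        t = np.array([[10, 20, 30], [10, 20, 30]])
        assert fisher_exact_2xk(t) > 0.9


class TestLifestyleFisher:
    def freqs(self):
        return LifestyleFrequencies(
            {"free_living": 63, "ectoparasitoid": 24, "endoparasitoid": 37}
        )

    def test_proportional_split_near_one(self):
        counts = {"dsDNA": {"free_living": 63, "ectoparasitoid": 24, "endoparasitoid": 37}}
        res = lifestyle_fisher(counts, self.freqs())
        assert res["dsDNA"]["p_raw"] > 0.5

    def test_skewed_split_is_small(self):
        counts = {"dsDNA": {"free_living": 5, "ectoparasitoid": 3, "endoparasitoid": 40}}
        res = lifestyle_fisher(counts, self.freqs())
        assert res["dsDNA"]["p_adjusted"] < 0.01

    def test_bh_across_structures(self):
        counts = {
            "dsDNA": {"free_living": 5, "ectoparasitoid": 3, "endoparasitoid": 40},
            "ssRNA(+)": {"free_living": 30, "ectoparasitoid": 12, "endoparasitoid": 18},
        }
        res = lifestyle_fisher(counts, self.freqs())
        assert res["dsDNA"]["p_adjusted"] >= res["dsDNA"]["p_raw"]
        assert res["ssRNA(+)"]["p_adjusted"] <= 1.0


class TestSharedGeneBinomial:
    def test_printed_example(self):
        assert shared_gene_binomial(5, 15, 13 / 108) == pytest.approx(0.02682, abs=5e-5)

    def test_zero_successes_gives_one(self):
        assert shared_gene_binomial(0, 12, 0.2) == pytest.approx(1.0)

    def test_all_successes_closed_form(self):
        assert shared_gene_binomial(7, 7, 0.3) == pytest.approx(0.3**7, rel=1e-12)

    def test_invalid_p0_rejected(self):
        with pytest.raises(ValueError):
            shared_gene_binomial(2, 5, 1.5)
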