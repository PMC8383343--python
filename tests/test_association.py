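"""Allele-count statistics, Fisher exact tests and Fisher's-method aggregation.

Independent oracles: exact hypergeometric enumeration with binomial
coefficients for the 2x2 tests, and the closed forms p and q(1 - ln q) for
Fisher's method at k = 1 and k = 2.
"""

import math
from itertools import product

import numpy as np
import pytest
from scipy import stats

from ptvburden.association import (
    AggregationResult,
    AlleleCounts,
    AssociationError,
    ContingencyTable2x2,
    GenotypeCounts,
    aggregate,
    allele_counts,
    directional_p,
    fisher_exact,
    fisher_method,
    genotype_table_report,
    variant_association,
)
from ptvburden.datasets import canine_ceacam24_genotypes


# ---------------------------------------------------------------------------
# enumeration oracle


def enumerate_fisher(a, b, c, d, alternative):
    """Exact conditional p by brute-force enumeration of all tables with
    the observed margins, using binomial coefficients only."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in probs.items() if x <= a)
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestAlleleCounts:
    @pytest.mark.parametrize(
        "g,alt,total,maf",
        [
            ((87, 42, 34), 118, 174, "67.8"),
            ((196, 12, 44), 68, 392, "17.3"),
            ((10, 0, 0), 0, 20, "0.0"),
            ((18, 6, 9), 21, 36, "58.3"),
        ],
    )
    def test_genotypes_to_alleles(self, g, alt, total, maf):
        ac = allele_counts(GenotypeCounts(*g))
        assert (ac.alt, ac.total) == (alt, total)
        assert ac.maf_percent == maf

    def test_invariants(self):
        with pytest.raises(AssociationError):
            GenotypeCounts(10, 8, 5)
        with pytest.raises(AssociationError):
            AlleleCounts(5, 4)


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_diagonal_table(self):
        # all 6 tables with margins (5,5,5,5); the two extremes have p 1/252
        p = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_degenerate_margins_warn(self):
        with pytest.warns(UserWarning):
            assert fisher_exact(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_matches_enumeration_oracle_small_margins(self):
        """Exhaustive sweep over all tables with every margin <= 8."""
        for a, b, c, d in product(range(9), repeat=4):
            if not (0 < a + b <= 8 and 0 < c + d <= 8):
                continue
            if not (0 < a + c <= 8 and 0 < b + d <= 8):
                continue
            t = ContingencyTable2x2(a, b, c, d)
            for alt in ("two_sided", "greater", "less"):
                assert fisher_exact(t, alt) == pytest.approx(
                    enumerate_fisher(a, b, c, d, alt), rel=1e-9, abs=1e-12
                ), (a, b, c, d, alt)


class TestVariantAssociation:
    def test_canine_vs_golden_controls(self):
        # CMT cases (18 dogs: 6 hom, 9 het) vs Golden controls (87: 42, 34)
        r = variant_association(GenotypeCounts(18, 6, 9),
                                allele_counts(GenotypeCounts(87, 42, 34)))
        assert r.p_two_sided == pytest.approx(0.3334, rel=5e-4)

    def test_canine_vs_pooled_akc(self):
        # vs pooled non-Golden AKC breeds (125 dogs: 23 hom, 10 het)
        r = variant_association(GenotypeCounts(18, 6, 9),
                                allele_counts(GenotypeCounts(125, 23, 10)))
        assert r.p_two_sided == pytest.approx(2.48e-5, rel=5e-3)
        assert r.direction == "risk"

    def test_canine_vs_eva(self):
        # vs the archive cohort (196 dogs: 12 hom, 44 het); the value is
        # cross-checked against R's fisher.test on the same table
        r = variant_association(GenotypeCounts(18, 6, 9),
                                allele_counts(GenotypeCounts(196, 12, 44)))
        assert r.p_two_sided == pytest.approx(2.38031e-7, rel=1e-5)

    def test_null_table_near_one(self):
        r = variant_association(AlleleCounts(100, 1000), AlleleCounts(1000, 10000))
        assert r.p_two_sided > 0.9
        assert r.direction == "null"

    def test_zero_cell_odds_ratio(self):
        r = variant_association(AlleleCounts(5, 10), AlleleCounts(0, 1000))
        assert math.isinf(r.odds_ratio)
        r = variant_association(AlleleCounts(0, 10), AlleleCounts(5, 1000))
        assert r.odds_ratio == 0.0


class TestDirectionalP:
    def test_risk_variant_uses_greater_tail(self):
        r = variant_association(AlleleCounts(30, 100), AlleleCounts(50, 1000))
        assert directional_p(r, "one_sided_greater") == r.p_greater
        assert directional_p(r, "complement") == r.p_greater

    def test_protective_variant_complement(self):
        r = variant_association(AlleleCounts(2, 100), AlleleCounts(200, 1000))
        assert r.direction == "protective"
        assert directional_p(r, "complement") == pytest.approx(1 - r.p_less)

    def test_complement_never_exceeds_greater_tail(self):
        """Both tails include the observed table, so 1 - p_less <= p_greater;
        swept over all small tables with positive margins."""
        for a, b, c, d in product(range(7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            r = variant_association(AlleleCounts(a, a + b), AlleleCounts(c, c + d))
            assert directional_p(r, "complement") <= r.p_greater + 1e-12


class TestFisherMethod:
    def test_k1_identity(self):
        assert fisher_method([0.05]).p_combined == pytest.approx(0.05, rel=1e-12)

    def test_all_ones(self):
        r = fisher_method([1.0, 1.0, 1.0])
        assert r.p_combined == pytest.approx(1.0)
        assert r.statistic == 0.0 and r.df == 6

    def test_k2_closed_form(self):
        # P(chi2_4 > -2 ln q) = q(1 - ln q) with q = p1 p2
        r = fisher_method([0.1, 0.1])
        q = 0.01
        assert r.p_combined == pytest.approx(q * (1 - math.log(q)), rel=1e-10)
        assert r.p_combined == pytest.approx(0.0560517, rel=1e-5)

    def test_k2_closed_form_generic(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p1, p2 = rng.uniform(1e-6, 1, size=2)
            q = p1 * p2
            assert fisher_method([p1, p2]).p_combined == pytest.approx(
                q * (1 - math.log(q)), rel=1e-9
            )

    def test_rejects_invalid_p(self):
        with pytest.raises(AssociationError):
            fisher_method([])
        with pytest.raises(AssociationError):
            fisher_method([0.0, 0.5])
        with pytest.raises(AssociationError):
            fisher_method([1.5])


class TestAggregate:
    def test_gene_level_example(self):
        # two-variant gene at the k = 2 closed form
        genes, fams = aggregate({"G": [0.04803, 0.01431]})
        q = 0.04803 * 0.01431
        assert genes["G"].p_combined == pytest.approx(q * (1 - math.log(q)), rel=1e-9)
        assert genes["G"].p_combined == pytest.approx(0.005693, rel=1e-3)

    def test_empty_gene_contributes_one(self):
        genes, fams = aggregate(
            {"G1": [0.5], "G2": []}, {"fam": ["G1", "G2"]}
        )
        assert genes["G2"].p_combined == 1.0
        assert fams["fam"].k == 2

    def test_family_of_all_null_genes(self):
        genes, fams = aggregate(
            {f"G{i}": [1.0] for i in range(12)}, {"fam": [f"G{i}" for i in range(12)]}
        )
        assert fams["fam"].p_combined == pytest.approx(1.0)

    def test_adding_empty_gene_dilutes_family(self):
        """Same statistic at higher df: the combined p strictly increases."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            ps = list(rng.uniform(0.001, 1, size=3))
            _, with_empty = aggregate(
                {"G1": ps, "G2": []}, {"f": ["G1", "G2"]}
            )
            _, without = aggregate({"G1": ps}, {"f": ["G1"]})
            assert with_empty["f"].p_combined > without["f"].p_combined

    def test_variant_level_family_mode(self):
        ps = {"G1": [0.2, 0.3], "G2": [0.4]}
        _, fams = aggregate(ps, {"f": ["G1", "G2"]}, family_level="variant")
        assert fams["f"].k == 3

    def test_empty_family_rejected(self):
        with pytest.raises(AssociationError):
            aggregate({"G1": [0.5]}, {"f": ["ABSENT"]})


class TestGenotypeTableReport:
    def test_canine_cohort_report(self):
        df = canine_ceacam24_genotypes()
        report, qc = genotype_table_report(df, "cmt_cases")
        by = report.set_index("cohort")
        assert by.loc["cmt_cases", "maf_percent"] == "58.3"
        assert by.loc["golden_controls", "maf_percent"] == "67.8"
        assert by.loc["eva_controls", "maf_percent"] == "17.3"
        assert by.loc["akc_nongolden_controls", "maf_percent"] == "22.4"
        assert by.loc["golden_controls", "p_two_sided"] == pytest.approx(0.3334, rel=5e-4)
        # the case row's published 66.7% disagrees with its genotype counts
        assert any("66.7" in w for w in qc)

    def test_per_breed_mafs(self):
        df = canine_ceacam24_genotypes()
        report, _ = genotype_table_report(df, "cmt_cases")
        labels = report.attrs["label_mafs"].set_index("label")
        assert labels.loc["Petit Basset Griffon Vendeen", "maf_percent"] == "80.0"
        assert labels.loc["Boxer", "maf_percent"] == "0.0"
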