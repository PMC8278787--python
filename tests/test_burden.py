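"""Exact tests: Fisher burden, geneset enrichment, Poisson DNV excess,
phenotype comparisons and symptom counting."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from enhancerdnm.burden import (
    ContingencyTable,
    PhenotypeTable,
    fisher_exact,
    geneset_binding_enrichment,
    phenotype_compare,
    poisson_dnv_excess,
    symptom_count,
)
from enhancerdnm.synthetic_data import synthetic_phenotype_reconstruction


def hypergeometric_pvalue(a, b, c, d, alternative="greater"):
    """Independent oracle: exact-rational hypergeometric mass summation.

    With margins fixed, P(A = k) = C(a+b, k) C(c+d, n1-k) / C(N, n1) where
    n1 = a+c exposed overall.
    """
    row1, row2 = a + b, c + d
    n1 = a + c
    N = row1 + row2
    denom = math.comb(N, n1)

    def mass(k):
        if k < 0 or k > row1 or n1 - k > row2 or n1 - k < 0:
            return Fraction(0)
        return Fraction(math.comb(row1, k) * math.comb(row2, n1 - k), denom)

    kmin, kmax = max(0, n1 - row2), min(row1, n1)
    if alternative == "greater":
        p = sum(mass(k) for k in range(a, kmax + 1))
    elif alternative == "less":
        p = sum(mass(k) for k in range(kmin, a + 1))
    else:
        obs = mass(a)
        p = sum(m for k in range(kmin, kmax + 1) if (m := mass(k)) <= obs)
    return float(p)


class TestFisherExact:
    def test_deletion_burden_printed_value(self):
        # 27 deletion carriers among 29,085 cases vs 0 among 19,584 controls
        res = fisher_exact(ContingencyTable(27, 29058, 0, 19584), "greater")
        assert res.p == pytest.approx(9.14e-7, rel=5e-3)
        assert res.odds_ratio == math.inf

    def test_duplication_burden_printed_value(self):
        res = fisher_exact(ContingencyTable(6, 29079, 0, 19584), "greater")
        assert res.p == pytest.approx(4.55e-2, rel=5e-3)

    def test_exchangeable_table_two_sided_is_one(self):
        res = fisher_exact(ContingencyTable(5, 5, 5, 5), "two_sided")
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_agrees_with_rational_hypergeometric_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                continue
            for alt in ("greater", "less", "two_sided"):
                got = fisher_exact(ContingencyTable(a, b, c, d), alt).p
                assert got == pytest.approx(
                    hypergeometric_pvalue(a, b, c, d, alt), abs=1e-12
                ), (a, b, c, d, alt)

    def test_one_sided_tails_overlap_at_observed(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, 4))
            t = ContingencyTable(a, b, c, d)
            assert fisher_exact(t, "greater").p + fisher_exact(t, "less").p >= 1 - 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestGenesetEnrichment:
    def test_reconstructed_binding_counts(self):
        # 285-gene NDD set with 75 bound, 19,375-gene universe with 3,100
        # bound overall: sample OR = (75*16065)/(210*3025)
        universe = [f"g{i}" for i in range(19375)]
        bound = set(universe[:3100])
        geneset = universe[:75] + universe[3100 : 3100 + 210]
        table, p, orr, frac = geneset_binding_enrichment(geneset, bound, universe)
        assert (table.a, table.b, table.c, table.d) == (75, 210, 3025, 16065)
        assert orr == pytest.approx((75 * 16065) / (210 * 3025), rel=1e-12)
        assert frac == pytest.approx(75 / 285)
        assert p < 1e-4

    def test_fully_bound_geneset_is_extreme(self):
        universe = [f"g{i}" for i in range(100)]
        bound = set(universe[:10])
        table, p, orr, frac = geneset_binding_enrichment(universe[:5], bound, universe)
        assert orr == math.inf and frac == 1.0
        # point-mass hypergeometric probability of drawing 5 bound genes
        expected = math.comb(10, 5) / math.comb(100, 5)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_random_genesets_give_uniformish_p(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(2000)]
        bound = set(rng.choice(universe, 400, replace=False))
        ps = []
        for _ in range(500):
            geneset = rng.choice(universe, 50, replace=False)
            ps.append(geneset_binding_enrichment(geneset, bound, universe)[1])
        # under the null, p is superuniform: P(p <= a) <= a; check both that
        # bound and that small p-values do occur at roughly their nominal rate
        frac05 = np.mean(np.array(ps) <= 0.05)
        assert frac05 <= 0.075
        assert frac05 >= 0.01

    def test_empty_geneset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            geneset_binding_enrichment([], {"a"}, {"a", "b"})


class TestPoissonExcess:
    def test_closed_forms(self):
        assert poisson_dnv_excess(0, 1000, 1e-5) == 1.0
        lam = 2 * 1000 * 1e-5
        assert poisson_dnv_excess(2, 1000, 1e-5) == pytest.approx(
            1 - math.exp(-lam) * (1 + lam), rel=1e-10
        )
        assert poisson_dnv_excess(1, 1000, 1e-5) == pytest.approx(
            1 - math.exp(-lam), rel=1e-10
        )

    def test_monotone_in_both_directions(self):
        ps_n = [poisson_dnv_excess(n, 1000, 1e-5) for n in range(6)]
        assert all(p1 >= p2 for p1, p2 in zip(ps_n, ps_n[1:]))
        ps_mu = [poisson_dnv_excess(3, 1000, mu) for mu in (1e-6, 1e-5, 1e-4)]
        assert all(p1 <= p2 for p1, p2 in zip(ps_mu, ps_mu[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_dnv_excess(-1, 1000, 1e-5)
        with pytest.raises(ValueError):
            poisson_dnv_excess(1, 1000, 0.0)


def pheno_table(rows):
    df = pd.DataFrame([r | {"group": g} for g, r in rows],
                      index=[f"i{k}" for k in range(len(rows))])
    return PhenotypeTable(df)


class TestPhenotypeCompare:
    def test_hand_hypergeometric_case(self):
        # 17/17 present vs 0/3: one-sided p = 1 / C(20, 17)
        rows = [("coding", {"ph": "+"})] * 17 + [("noncoding", {"ph": "-"})] * 3
        table = pheno_table(rows)
        ct, p, orr = phenotype_compare(table, "ph", "coding", "noncoding")
        assert (ct.a, ct.b, ct.c, ct.d) == (17, 0, 0, 3)
        assert p == pytest.approx(1 / math.comb(20, 17), rel=1e-12)

    def test_missing_excluded_per_phenotype_not_globally(self):
        rows = (
            [("coding", {"ph": "+", "other": "NA"})] * 5
            + [("coding", {"ph": "NA", "other": "+"})] * 2
            + [("noncoding", {"ph": "-", "other": "-"})] * 3
        )
        table = pheno_table(rows)
        ct, _, _ = phenotype_compare(table, "ph", "coding", "noncoding")
        assert (ct.a + ct.b, ct.c + ct.d) == (5, 3)
        ct2, _, _ = phenotype_compare(table, "other", "coding", "noncoding")
        assert (ct2.a + ct2.b, ct2.c + ct2.d) == (2, 3)

    def test_equal_prevalence_disfavored_direction(self):
        rows = [("a", {"ph": "+"})] * 3 + [("a", {"ph": "-"})] * 3 \
            + [("b", {"ph": "+"})] * 3 + [("b", {"ph": "-"})] * 3
        _, p, _ = phenotype_compare(pheno_table(rows), "ph", "a", "b", "less")
        assert p > 0.5

    def test_all_missing_group_errors(self):
        rows = [("a", {"ph": "NA"})] * 3 + [("b", {"ph": "+"})] * 3
        with pytest.raises(ValueError, match="no assessed"):
            phenotype_compare(pheno_table(rows), "ph", "a", "b")

    def test_unknown_phenotype_errors(self):
        rows = [("a", {"ph": "+"})] * 2 + [("b", {"ph": "-"})] * 2
        with pytest.raises(KeyError):
            phenotype_compare(pheno_table(rows), "nope", "a", "b")

    def test_invariant_to_row_order_and_all_missing_rows(self):
        rows = (
            [("a", {"ph": "+"})] * 4 + [("a", {"ph": "-"})] * 2
            + [("b", {"ph": "+"})] * 1 + [("b", {"ph": "-"})] * 5
        )
        table = pheno_table(rows)
        shuffled = PhenotypeTable(table.data.sample(frac=1, random_state=0))
        extra = PhenotypeTable(
            pd.concat([table.data,
                       pd.DataFrame([{"group": "a", "ph": "NA"}], index=["x"])])
        )
        p0 = phenotype_compare(table, "ph", "a", "b")[1]
        assert phenotype_compare(shuffled, "ph", "a", "b")[1] == p0
        assert phenotype_compare(extra, "ph", "a", "b")[1] == p0

    def test_invalid_codes_rejected(self):
        df = pd.DataFrame({"group": ["a"], "ph": ["yes"]})
        with pytest.raises(ValueError, match="invalid phenotype codes"):
            PhenotypeTable(df)


class TestReconstructionTable:
    """The synthetic stand-in reproduces the published margins."""

    def test_id_gdd_comparison(self):
        table = synthetic_phenotype_reconstruction()
        ct, p, _ = phenotype_compare(table, "id_gdd", "coding", "noncoding")
        assert (ct.a, ct.b, ct.c, ct.d) == (17, 0, 0, 3)
        assert p == pytest.approx(0.00088, rel=5e-3)

    def test_autism_comparison(self):
        table = synthetic_phenotype_reconstruction()
        ct, p, _ = phenotype_compare(table, "autism", "noncoding", "coding")
        assert (ct.a + ct.b, ct.c + ct.d) == (3, 17)
        assert p == pytest.approx(0.0088, rel=5e-3)

    def test_ataxia_assessed_count(self):
        table = synthetic_phenotype_reconstruction()
        ct, _, _ = phenotype_compare(table, "ataxia", "coding", "noncoding")
        assert ct.a + ct.b == 18  # two coding probands missing the assessment


class TestSymptomCount:
    def _row(self, neuro, diag, cranio):
        vals = {}
        for i in range(6):
            vals[f"neuro_{i}"] = "+" if i < neuro else "-"
            vals[f"diag_{i}"] = "+" if i < diag else "-"
            vals[f"cranio_{i}"] = "+" if i < cranio else "-"
        return pd.Series(vals)

    @pytest.mark.parametrize(
        "neuro,diag,cranio,expected",
        [(4, 3, 2, 8), (0, 0, 0, 0), (6, 0, 1, 7), (2, 1, 0, 3)],
    )
    def test_rule_application(self, neuro, diag, cranio, expected):
        # craniofacial abnormalities contribute at most 1 regardless of count
        assert symptom_count(self._row(neuro, diag, cranio)) == expected

    def test_missing_entries_contribute_zero(self):
        row = self._row(2, 1, 1)
        row["neuro_0"] = "NA"
        assert symptom_count(row) == 1 + 1 + 1
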