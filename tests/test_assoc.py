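"""Association statistics: chi-square, Fisher, odds ratios, HWE, report.

Published-table values are asserted at their printed precision; independent
oracles are scipy.stats.chi2_contingency, a full hypergeometric enumeration
written here, and statsmodels' Table2x2.
"""

import numpy as np
import pytest
from scipy import stats

from hlae_typing import (
    AlleleCounts,
    ContingencyTable2x2,
    GenotypeCounts,
    allele_counts,
    association_report,
    compare_2x2,
    fisher_exact,
    frequencies,
    hwe_test,
    load_study_counts,
    odds_ratio,
    pearson_chi2,
)
from hlae_typing.errors import InputError, StatisticError

DONORS = GenotypeCounts("healthy_donors", 185, 40, 1)
PATIENTS = GenotypeCounts("leukemia_patients", 210, 18, 0)


def random_tables(n_tables, seed, low=1, high=120):
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        yield ContingencyTable2x2(*(int(x) for x in rng.integers(low, high, 4)))


# -- allele counts & frequencies -------------------------------------------

def test_allele_counts_examples():
    assert (lambda ac: (ac.n_G, ac.n_T))(allele_counts(DONORS)) == (410, 42)
    # genotype-derived patient counts: 438/18, not the published allele table's 437/19
    assert (lambda ac: (ac.n_G, ac.n_T))(allele_counts(PATIENTS)) == (438, 18)
    empty = allele_counts(GenotypeCounts("none", 0, 0, 0))
    assert (empty.n_G, empty.n_T) == (0, 0)


def test_allele_counts_conserve_chromosomes():
    rng = np.random.default_rng(1)
    for _ in range(50):
        gc = GenotypeCounts("c", *(int(x) for x in rng.integers(0, 500, 3)))
        ac = allele_counts(gc)
        assert ac.n_G + ac.n_T == 2 * gc.size


def test_frequencies_published_values():
    assert frequencies([437, 19])[1] * 100 == pytest.approx(4.16, abs=0.01)
    assert frequencies([410, 42])[1] * 100 == pytest.approx(9.29, abs=0.005)
    assert frequencies([186, 40])[1] * 100 == pytest.approx(17.70, abs=0.005)


def test_frequencies_sum_to_one_and_reject_empty():
    assert frequencies([3, 5, 2]).sum() == pytest.approx(1.0)
    with pytest.raises(StatisticError):
        frequencies([0, 0])


# -- Pearson chi-square -----------------------------------------------------

@pytest.mark.parametrize(
    "cells,expected",
    [
        ((19, 437, 42, 410), 9.515),
        ((4, 108, 42, 410), 3.921),
        ((14, 294, 42, 410), 6.046),
    ],
)
def test_pearson_chi2_published_tables(cells, expected):
    chi2, p = pearson_chi2(ContingencyTable2x2(*cells))
    assert round(chi2, 3) == expected
    assert 0 <= p <= 0.05


def test_pearson_chi2_independence_gives_zero():
    chi2, p = pearson_chi2(ContingencyTable2x2(10, 20, 30, 60))  # ad == bc
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_pearson_chi2_matches_observed_expected_oracle():
    for t in random_tables(200, seed=2):
        chi2, p = pearson_chi2(t)
        ref_chi2, ref_p, _, _ = stats.chi2_contingency(t.as_array(), correction=False)
        assert chi2 == pytest.approx(ref_chi2, abs=1e-9)
        assert p == pytest.approx(ref_p, abs=1e-9)


def test_pearson_chi2_transpose_invariance():
    for t in random_tables(50, seed=3):
        transposed = ContingencyTable2x2(t.a, t.c, t.b, t.d)
        assert pearson_chi2(t)[0] == pytest.approx(pearson_chi2(transposed)[0])


def test_pearson_chi2_zero_margin_rejected():
    with pytest.raises(StatisticError):
        pearson_chi2(ContingencyTable2x2(0, 0, 5, 5))


def test_pearson_chi2_continuity_correction_is_smaller():
    t = ContingencyTable2x2(19, 437, 42, 410)
    assert pearson_chi2(t, continuity_correction=True)[0] < pearson_chi2(t)[0]


# -- Fisher exact -----------------------------------------------------------

def enumeration_fisher(t):
    """Independent oracle: enumerate all tables with the observed margins."""
    r1, c1, n = t.a + t.b, t.a + t.c, t.n
    probs = [
        stats.hypergeom.pmf(a, n, c1, r1)
        for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    ]
    p_obs = stats.hypergeom.pmf(t.a, n, c1, r1)
    return float(sum(p for p in probs if p <= p_obs * (1 + 1e-9)))


def test_fisher_published_tt_comparison():
    assert round(fisher_exact(ContingencyTable2x2(0, 228, 1, 225)), 3) == 0.498


def test_fisher_identical_rows_p_one():
    assert fisher_exact(ContingencyTable2x2(7, 13, 7, 13)) == pytest.approx(1.0)


def test_fisher_degenerate_margin_p_one():
    assert fisher_exact(ContingencyTable2x2(0, 0, 3, 5)) == 1.0


def test_fisher_matches_full_enumeration_on_all_small_tables():
    for n in range(1, 17):
        for r1 in range(n + 1):
            for c1 in range(n + 1):
                for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                    t = ContingencyTable2x2(a, r1 - a, c1 - a, n - r1 - c1 + a)
                    assert fisher_exact(t) == pytest.approx(
                        enumeration_fisher(t), abs=1e-9
                    ), (n, r1, c1, a)


# -- odds ratio with Woolf CI ----------------------------------------------

@pytest.mark.parametrize(
    "cells,expected",
    [
        ((19, 437, 42, 410), (0.424, 0.243, 0.742)),
        ((18, 210, 40, 186), (0.399, 0.221, 0.719)),
    ],
)
def test_odds_ratio_published_tables(cells, expected):
    or_, lo, hi = odds_ratio(ContingencyTable2x2(*cells))
    assert (round(or_, 3), round(lo, 3), round(hi, 3)) == expected


def test_odds_ratio_independence_gives_one():
    or_, lo, hi = odds_ratio(ContingencyTable2x2(10, 20, 30, 60))
    assert or_ == pytest.approx(1.0) and lo < 1 < hi


def test_odds_ratio_inverting_outcome_mirrors_ci():
    for t in random_tables(50, seed=4):
        or_, lo, hi = odds_ratio(t)
        inv_or, inv_lo, inv_hi = odds_ratio(ContingencyTable2x2(t.b, t.a, t.d, t.c))
        assert inv_or == pytest.approx(1 / or_)
        assert inv_lo == pytest.approx(1 / hi) and inv_hi == pytest.approx(1 / lo)


def test_odds_ratio_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    for t in random_tables(50, seed=5):
        or_, lo, hi = odds_ratio(t)
        table = sm.Table2x2(t.as_array())
        assert or_ == pytest.approx(table.oddsratio)
        ref_lo, ref_hi = table.oddsratio_confint(0.05)
        assert lo == pytest.approx(ref_lo) and hi == pytest.approx(ref_hi)


def test_odds_ratio_zero_cell_rejected():
    with pytest.raises(StatisticError):
        odds_ratio(ContingencyTable2x2(0, 228, 1, 225))
    with pytest.raises(StatisticError):
        odds_ratio(ContingencyTable2x2(5, 0, 3, 4))


# -- Hardy-Weinberg ---------------------------------------------------------

def test_hwe_exact_proportions_give_zero():
    res = hwe_test(GenotypeCounts("x", 25, 50, 25))
    assert res.chi2 == pytest.approx(0.0) and res.p == pytest.approx(1.0)


def test_hwe_donor_cohort_accepted():
    res = hwe_test(DONORS)
    assert res.chi2 == pytest.approx(0.564, abs=5e-4)
    assert res.p > 0.05
    assert res.expected == pytest.approx((185.95, 38.10, 1.95), abs=0.05)
    assert sum(res.expected) == pytest.approx(DONORS.size)


def test_hwe_maximal_disequilibrium_rejected():
    res = hwe_test(GenotypeCounts("x", 50, 0, 50))
    assert res.chi2 == pytest.approx(100.0)
    assert res.p < 0.05


def test_hwe_monomorphic_cohort_trivially_fits():
    res = hwe_test(GenotypeCounts("x", 80, 0, 0))
    assert res.chi2 == 0.0 and res.p == 1.0


def test_hwe_zero_on_random_exact_hwe_counts():
    # counts (g^2, 2gt, t^2) have allele frequency g/(g+t) exactly, so they
    # sit exactly on the HWE surface for any integers g, t
    rng = np.random.default_rng(6)
    for _ in range(20):
        g, t = (int(x) for x in rng.integers(1, 40, 2))
        gc = GenotypeCounts("x", g * g, 2 * g * t, t * t)
        assert hwe_test(gc).chi2 == pytest.approx(0.0, abs=1e-9)


def test_hwe_empty_cohort_rejected():
    with pytest.raises(StatisticError):
        hwe_test(GenotypeCounts("x", 0, 0, 0))


# -- full report ------------------------------------------------------------

@pytest.fixture(scope="module")
def study_report():
    fx = load_study_counts()
    return association_report(
        fx["case_genotypes"],
        fx["control_genotypes"],
        subtype_alleles=fx["subtype_alleles"],
        case_alleles=fx["case_alleles"],
        control_alleles=fx["control_alleles"],
    )


def test_report_reproduces_published_allele_table(study_report):
    row = study_report.allele_table.iloc[0]
    assert round(row.chi2, 3) == 9.515
    assert round(row.OR, 3) == 0.424
    assert (round(row.ci_low, 3), round(row.ci_high, 3)) == (0.243, 0.742)


def test_report_reproduces_published_subtype_table(study_report):
    by_name = study_report.subtype_table.set_index("subtype")
    assert round(by_name.loc["lymphocytic_leukemia", "chi2"], 3) == 3.921
    assert round(by_name.loc["myeloid_leukemia", "chi2"], 3) == 6.046


def test_report_genotype_table_gt_column_and_tt_fisher(study_report):
    by_g = study_report.genotype_table.set_index("genotype")
    assert round(by_g.loc["G/T", "OR"], 3) == 0.399
    assert round(by_g.loc["G/T", "ci_high"], 3) == 0.719
    assert by_g.loc["G/T", "control_pct"] == pytest.approx(17.70, abs=0.005)
    assert by_g.loc["T/T", "method"] == "FISHER"
    assert round(by_g.loc["T/T", "p"], 3) == 0.498
    # the published G/G OR (2.007) is not derivable from the printed counts;
    # the report carries its own genotype-vs-rest value instead
    assert by_g.loc["G/G", "OR"] == pytest.approx(2.586, abs=5e-4)


def test_report_flags_allele_genotype_count_inconsistency(study_report):
    assert any("437 G / 19 T" in note for note in study_report.notes)
    assert all(res.p > 0.05 for res in study_report.hwe.values())


def test_report_identical_cohorts_are_null():
    gc = GenotypeCounts("a", 50, 30, 20)
    rep = association_report(gc, GenotypeCounts("b", 50, 30, 20))
    assert rep.allele_table.chi2.iloc[0] == pytest.approx(0.0)
    assert rep.allele_table.OR.iloc[0] == pytest.approx(1.0)
    assert np.allclose(rep.genotype_table.OR.astype(float), 1.0)


def test_report_summary_mentions_all_sections(study_report):
    text = study_report.summary()
    for token in ("Allele-level", "Genotype-level", "Hardy-Weinberg", "9.515", "0.424"):
        assert token in text


def test_compare_2x2_uses_fisher_when_expected_cells_sparse():
    sparse = compare_2x2(ContingencyTable2x2(0, 228, 1, 225))
    assert sparse.method == "FISHER" and sparse.chi2 is None
    dense = compare_2x2(ContingencyTable2x2(19, 437, 42, 410))
    assert dense.method == "CHI2"


def test_invalid_counts_rejected():
    with pytest.raises(InputError):
        GenotypeCounts("x", -1, 0, 0)
    with pytest.raises(InputError):
        AlleleCounts("x", -1, 5)
    with pytest.raises(InputError):
        ContingencyTable2x2(0, 0, 0, 0)
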