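"""Single-locus statistics: HWE, odds ratios, trend test, Monte-Carlo p."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stonegene as sg
from stonegene.single_locus import SingleLocusScan, armitage_trend

from conftest import make_cohort


# -- Hardy-Weinberg ------------------------------------------------------------

@pytest.mark.parametrize("counts,stat,p", [
    ((25, 50, 25), 0.0, 1.0),                  # perfect HWE
    ((91, 110, 19), 3.1657, 0.0752),           # frozen from the expected-count formula
])
def test_hwe_chi_square(counts, stat, p):
    res = sg.hwe_test(counts)
    assert res.statistic == pytest.approx(stat, abs=1e-3)
    assert res.p_value == pytest.approx(p, abs=1e-3)


def test_hwe_no_heterozygotes_extreme():
    res = sg.hwe_test((100, 0, 100))
    assert res.statistic == pytest.approx(200.0)
    assert res.p_value < 1e-10


def test_hwe_monomorphic_flagged():
    res = sg.hwe_test((50, 0, 0))
    assert res.monomorphic and res.p_value == 1.0 and res.statistic == 0.0


def test_hwe_exact_matches_enumeration_oracle():
    """Exact test equals brute-force enumeration of the conditional
    heterozygote distribution on a small sample."""
    from math import comb

    n0, n1, n2 = 6, 2, 4
    n = n0 + n1 + n2
    rare = min(n1 + 2 * n2, 2 * n - n1 - 2 * n2)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        naa = (rare - h) // 2
        nbb = n - naa - h
        if nbb < 0:
            continue
        probs[h] = (2 ** h) * comb(n, naa) * comb(n - naa, h)
    tot = sum(probs.values())
    p_obs = probs[n1] / tot
    expected = sum(v for v in probs.values() if v / tot <= p_obs * (1 + 1e-12)) / tot
    assert sg.hwe_exact((n0, n1, n2)).p_value == pytest.approx(expected, rel=1e-9)


# -- crude odds ratios -----------------------------------------------------------

def test_crude_or_printed_values(study_cohort):
    dom = sg.genotype_counts(study_cohort, "rs4149056", "dominant")
    assert sg.crude_or(dom).odds_ratio == pytest.approx(1.46, abs=0.005)
    hom = sg.genotype_counts(study_cohort, "rs2234693")[:, (0, 2)]
    assert sg.crude_or(hom).odds_ratio == pytest.approx(2.84, abs=0.005)
    gg = sg.genotype_counts(study_cohort, "rs1800544")[:, (0, 2)]
    assert sg.crude_or(gg).odds_ratio == pytest.approx(1.6, abs=0.05)


def test_crude_or_symmetry():
    res = sg.crude_or([[10, 10], [10, 10]])
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low < 1.0 < res.ci_high


def test_crude_or_zero_cell_haldane():
    res = sg.crude_or([[10, 0], [10, 5]])
    assert res.corrected
    assert np.isfinite(res.odds_ratio)


def test_crude_or_zero_margin_raises():
    with pytest.raises(ValueError, match="undefined"):
        sg.crude_or([[0, 0], [10, 5]])


@settings(deadline=None, max_examples=50)
@given(st.tuples(*[st.integers(1, 200)] * 4))
def test_swapping_groups_inverts_or(cells):
    a, b, c, d = cells
    orig = sg.crude_or([[a, b], [c, d]])
    swapped = sg.crude_or([[c, d], [a, b]])
    assert swapped.odds_ratio == pytest.approx(1 / orig.odds_ratio, rel=1e-9)


# -- adjusted (logistic) odds ratios -----------------------------------------------

def test_logistic_without_covariates_equals_cross_product(study_cohort):
    res = sg.adjusted_or(study_cohort, "rs2234693", model="dominant")
    crude = sg.crude_or(sg.genotype_counts(study_cohort, "rs2234693", "dominant"))
    assert res.odds_ratio == pytest.approx(crude.odds_ratio, abs=1e-6)
    assert res.ci_low == pytest.approx(crude.ci_low, abs=1e-4)


def test_logistic_recovers_true_dominant_or():
    """Dominant OR 2.0 with genotype-independent covariates, large n."""
    rng = np.random.default_rng(0)
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 4000
        g = rng.binomial(2, 0.3, size=2 * n).astype(np.int8)
        carrier = (g >= 1).astype(float)
        logit = -0.5 + np.log(2.0) * carrier
        y = rng.random(2 * n) < 1 / (1 + np.exp(-logit))
        import pandas as pd
        cov = pd.DataFrame({"age": rng.normal(50, 10, 2 * n),
                            "sex": rng.choice(["male", "female"], 2 * n)})
        cohort = make_cohort(g[:, None], y.astype(int), covariates=cov)
        res = sg.adjusted_or(cohort, "s1", model="dominant",
                             covariates=("age", "sex"))
        hits += 1.7 <= res.odds_ratio <= 2.35
    assert hits >= 4


def test_separation_flagged():
    g = np.array([0] * 10 + [2] * 10, dtype=np.int8)
    status = np.array([0] * 10 + [1] * 10)
    cohort = make_cohort(g[:, None], status)
    res = sg.adjusted_or(cohort, "s1", model="dominant")
    assert res.separation


# -- trend test -------------------------------------------------------------------

def test_trend_pgr_dominant_matches_printed_ptrend(study_cohort):
    t = sg.genotype_counts(study_cohort, "rs1042838", "dominant")
    res = armitage_trend(t)
    assert res.p_value == pytest.approx(0.011, abs=0.001)


def test_trend_esr1_printed_table(study_cohort):
    res = armitage_trend(sg.genotype_counts(study_cohort, "rs2234693"))
    assert res.p_value < 1e-3
    assert res.p_value == pytest.approx(4.83e-4, rel=0.01)  # frozen formula value


def test_trend_identical_distributions_null():
    res = armitage_trend([[30, 40, 30], [60, 80, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_trend_single_column_degenerate():
    res = armitage_trend([[50, 0], [60, 0]])
    assert res.degenerate and res.p_value == 1.0


@settings(deadline=None, max_examples=40)
@given(st.tuples(*[st.integers(1, 100)] * 4))
def test_trend_on_2x2_equals_pearson(cells):
    from scipy.stats import chi2_contingency

    a, b, c, d = cells
    table = np.array([[a, b], [c, d]])
    trend = armitage_trend(table)
    chi2 = chi2_contingency(table, correction=False)[0]
    assert trend.statistic == pytest.approx(chi2, rel=1e-9)


# -- Monte-Carlo trend p ------------------------------------------------------------

def test_mcs_null_table_large_p():
    p = sg.mcs_trend_p([[30, 40, 30], [30, 40, 30]], reps=1000, seed=1)
    assert p > 0.5


def test_mcs_deterministic_under_seed(study_cohort):
    t = sg.genotype_counts(study_cohort, "rs2234693")
    assert sg.mcs_trend_p(t, reps=500, seed=42) == sg.mcs_trend_p(t, reps=500, seed=42)


def test_mcs_converges_to_asymptotic(study_cohort):
    t = sg.genotype_counts(study_cohort, "rs2234693")
    asym = armitage_trend(t).p_value
    p = sg.mcs_trend_p(t, reps=10_000, seed=7)
    assert abs(p - asym) <= 2 * np.sqrt(asym * (1 - asym) / 10_000) + 1e-4


def test_mcs_requires_minimum_reps(study_cohort):
    t = sg.genotype_counts(study_cohort, "rs2234693")
    with pytest.raises(ValueError):
        sg.mcs_trend_p(t, reps=10)


# -- scan facade ---------------------------------------------------------------------

def test_scan_report_layout(study_cohort):
    res = SingleLocusScan(study_cohort).fit(mcs_reps=200, seed=0)
    report = res.report()
    assert list(report.columns) == ["snp_id", "label", "row", "control",
                                    "case", "p", "or_ci"]
    block = report[report.snp_id == "rs2234693"]
    # genotype rows, Ptrend, MCS, pooled carrier row, two allele rows
    assert list(block["row"]) == ["CC", "CT", "TT", "Ptrend", "MCS",
                                  "CT+TT", "C", "T"]
    assert block.iloc[0]["control"] == "91 (41.4)"
    assert block.iloc[-1]["case"] == "204 (44.3)"
    summary = res.summary()
    assert len(summary) == 13
    assert summary.loc[summary.snp_id == "rs2234693", "p_trend"].iloc[0] < 1e-3
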