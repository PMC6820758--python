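import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import oracles
from extremeqtl import (
    CollapsedTable,
    ContingencyTable,
    anova_f,
    collapse_table,
    fisher_exact,
    fisher_exact_2x3,
    hwe_exact,
    hypergeom_point_prob,
    lambda_gc,
    logistic_assoc,
)


# ---------------------------------------------------------------- collapsing
@pytest.mark.parametrize(
    "model, expected",
    [
        ("dominant", (2, 1, 0, 3)),
        ("recessive", (3, 0, 1, 2)),
        ("multiplicative", (5, 1, 1, 5)),
    ],
)
def test_collapse_rules(model, expected):
    table = ContingencyTable(2, 1, 0, 0, 1, 2)
    collapsed = collapse_table(table, model)
    assert (collapsed.a, collapsed.b, collapsed.c, collapsed.d) == expected


def test_collapse_preserves_margins():
    table = ContingencyTable(5, 3, 2, 1, 4, 6)
    for model in ("dominant", "recessive"):
        collapsed = collapse_table(table, model)
        assert collapsed.row_totals == (table.n_upper, table.n_lower)
    allelic = collapse_table(table, "multiplicative")
    assert allelic.row_totals == (2 * table.n_upper, 2 * table.n_lower)


# ----------------------------------------------------- hypergeometric kernel
def test_hypergeom_point_prob_example():
    # U=2, L=2, Y_AA=2, U_AA=1 -> C(2,1)C(2,1)/C(4,2) = 2/3
    assert hypergeom_point_prob(CollapsedTable(1, 1, 1, 1)) == pytest.approx(2 / 3)


def test_hypergeom_point_probs_normalize():
    r1, r2, c1 = 7, 5, 6
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    total = sum(
        hypergeom_point_prob(CollapsedTable(x, r1 - x, c1 - x, r2 - (c1 - x)))
        for x in support
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_single_feasible_table_has_probability_one():
    # all individuals in the first column: only one table with these margins
    assert hypergeom_point_prob(CollapsedTable(4, 0, 3, 0)) == pytest.approx(1.0)


# ------------------------------------------------------------- Fisher (2x2)
def test_fisher_extreme_table():
    res = fisher_exact(CollapsedTable(0, 5, 5, 0))
    assert res.p_value == pytest.approx(2 / 252, abs=1e-12)


def test_fisher_mode_table_is_one():
    assert fisher_exact(CollapsedTable(3, 3, 3, 3)).p_value == pytest.approx(1.0)


def test_fisher_zero_margin_is_one():
    assert fisher_exact(CollapsedTable(0, 4, 0, 6)).p_value == 1.0
    with pytest.raises(ValueError):
        fisher_exact(CollapsedTable(0, 0, 0, 0))


def test_fisher_matches_exact_enumeration_everywhere():
    """Exhaustive sweep: every 2x2 table with total <= 12 agrees with the
    rational-arithmetic enumeration oracle."""
    for a, b, c, d in oracles.all_2x2_tables(12):
        expected = float(oracles.fisher_2x2_pvalue(a, b, c, d))
        got = fisher_exact(CollapsedTable(a, b, c, d)).p_value
        assert got == pytest.approx(expected, abs=1e-12), (a, b, c, d)


def test_fisher_matches_scipy(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 40, size=4)
        if a + b == 0 or c + d == 0:
            continue
        ours = fisher_exact(CollapsedTable(int(a), int(b), int(c), int(d))).p_value
        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)


@given(st.tuples(*[st.integers(0, 15)] * 4).filter(lambda t: sum(t) > 0))
def test_fisher_invariant_under_row_and_column_swaps(t):
    a, b, c, d = t
    base = fisher_exact(CollapsedTable(a, b, c, d)).p_value
    assert fisher_exact(CollapsedTable(c, d, a, b)).p_value == pytest.approx(base)
    assert fisher_exact(CollapsedTable(b, a, d, c)).p_value == pytest.approx(base)


# ------------------------------------------------------------- Fisher (2x3)
def test_fisher_2x3_matches_enumeration():
    cases = [
        (10, 13, 7, 21, 4, 5),
        (2, 1, 0, 0, 1, 2),
        (5, 0, 0, 0, 0, 5),
        (3, 3, 3, 3, 3, 3),
        (1, 2, 3, 3, 2, 1),
    ]
    for u in cases:
        expected = float(oracles.fisher_2x3_pvalue(u[:3], u[3:]))
        got = fisher_exact_2x3(ContingencyTable(*u)).p_value
        assert got == pytest.approx(expected, abs=1e-10), u


def test_fisher_2x3_exhaustive_small_tables():
    from itertools import product

    for counts in product(range(3), repeat=6):
        if sum(counts) == 0:
            continue
        expected = float(oracles.fisher_2x3_pvalue(counts[:3], counts[3:]))
        got = fisher_exact_2x3(ContingencyTable(*counts)).p_value
        assert got == pytest.approx(expected, abs=1e-10), counts


def test_fisher_2x3_known_r_values():
    """Frozen references from R's fisher.test on the same matrices."""
    assert fisher_exact_2x3(ContingencyTable(10, 13, 7, 21, 4, 5)).p_value == \
        pytest.approx(0.01028374, abs=1e-7)
    assert fisher_exact_2x3(ContingencyTable(2, 1, 0, 0, 1, 2)).p_value == \
        pytest.approx(0.6, abs=1e-9)


# -------------------------------------------------------------------- ANOVA
def test_anova_constant_response():
    res = anova_f(np.ones(9), np.repeat([0, 1, 2], 3))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_anova_two_groups_equals_squared_t(rng):
    g = np.repeat([0, 1], 20)
    y = rng.normal(size=40) + 0.5 * g
    res = anova_f(y, g)
    t = stats.ttest_ind(y[g == 0], y[g == 1], equal_var=True)
    assert res.statistic == pytest.approx(t.statistic**2)
    assert res.p_value == pytest.approx(t.pvalue)


def test_anova_matches_scipy_three_groups(rng):
    g = rng.integers(0, 3, size=120)
    y = rng.normal(size=120) + 0.2 * g
    res = anova_f(y, g)
    ref = stats.f_oneway(y[g == 0], y[g == 1], y[g == 2])
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)
    assert res.df == 2


def test_anova_needs_two_classes():
    with pytest.raises(ValueError, match="two genotype classes"):
        anova_f(np.arange(5.0), np.zeros(5, dtype=int))


def test_anova_null_pvalues_are_uniform(rng):
    """Under delta=1 the ANOVA p-value is U(0,1): empirical CDF at 0.05
    within 3 MC SE."""
    reps, n = 4000, 120
    g = rng.binomial(2, 0.3, size=(reps, n))
    y = rng.normal(size=(reps, n))
    from extremeqtl._engine import anova_pvalues

    rate = (anova_pvalues(g, y) <= 0.05).mean()
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


# ----------------------------------------------------------------- logistic
def test_logistic_recovers_known_coefficient(rng):
    import statsmodels.api as sm

    n, beta0, beta1 = 3000, -0.5, 0.8
    g = rng.binomial(2, 0.3, size=n).astype(float)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * g)))
    y = (rng.random(n) < p).astype(float)
    res = logistic_assoc(y, g)
    assert not res.separation
    fit = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
    se = fit.bse[1]
    assert abs(fit.params[1] - beta1) < 3 * se
    assert res.p_value < 1e-6  # strong true effect


def test_logistic_flags_separation():
    g = np.array([0, 0, 0, 2, 2, 2], dtype=float)
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    res = logistic_assoc(y, g)
    assert res.separation and res.p_value == 1.0


def test_logistic_flags_constant_genotype():
    res = logistic_assoc(np.array([0, 1, 0, 1]), np.zeros(4))
    assert res.separation and res.p_value == 1.0


def test_logistic_categorical_mode(rng):
    g = rng.binomial(2, 0.4, size=400).astype(float)
    y = rng.integers(0, 2, size=400).astype(float)
    res = logistic_assoc(y, g, coding="categorical")
    assert res.test_name == "logistic_categorical"
    assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------- HWE
def test_hwe_matches_enumeration_oracle():
    cases = [(1, 0, 1), (5, 10, 5), (20, 5, 20), (10, 30, 2), (0, 5, 5)]
    for n_aa, n_ab, n_bb in cases:
        expected = float(oracles.hwe_exact_pvalue(n_aa, n_ab, n_bb))
        assert hwe_exact(n_aa, n_ab, n_bb).p_value == pytest.approx(
            expected, abs=1e-10
        ), (n_aa, n_ab, n_bb)


def test_hwe_monomorphic_is_one():
    assert hwe_exact(10, 0, 0).p_value == 1.0
    assert hwe_exact(0, 0, 7).p_value == 1.0


def test_hwe_null_calibration(rng):
    """Genotypes actually drawn under HWE are rarely rejected."""
    rejections = 0
    for _ in range(200):
        g = rng.binomial(2, 0.3, size=200)
        counts = np.bincount(g, minlength=3)
        if hwe_exact(*map(int, counts)).p_value <= 0.05:
            rejections += 1
    assert rejections / 200 < 0.10  # exact test is conservative


# ---------------------------------------------------------------- lambda_GC
def test_lambda_gc_identities(rng):
    assert lambda_gc(np.full(11, 0.5)) == pytest.approx(1.0)
    p = rng.random(100_000)
    assert lambda_gc(p) == pytest.approx(1.0, abs=0.02)


def test_lambda_gc_detects_twofold_inflation(rng):
    chi2 = 2.0 * stats.chi2.rvs(1, size=100_000, random_state=rng)
    p = stats.chi2.sf(chi2, 1)
    assert lambda_gc(p) == pytest.approx(2.0, abs=0.1)


def test_lambda_gc_domain():
    with pytest.raises(ValueError):
        lambda_gc(np.array([]))
    with pytest.raises(ValueError):
        lambda_gc(np.array([0.5, 1.5]))
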