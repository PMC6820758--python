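import numpy as np
import pandas as pd
import pytest

from extremeqtl import (
    ArmKind,
    Cohort,
    DesignArm,
    EffectSpec,
    ExtremeDesign,
    PopulationSpec,
    analytic_anova_power,
    anova_f,
    build_contingency,
    calibrate_cutoff,
    collapse_table,
    estimate_power,
    fisher_exact,
    fisher_exact_2x3,
    genotype_frequencies,
    genotype_means,
    power_curve,
    ratio_scan,
    select_extremes,
)
from extremeqtl import _engine
from extremeqtl.power import PowerEstimate, child_rng, select_cutoff

NULL_SPEC = PopulationSpec(n=300, maf=0.3, model="dominant", effect=EffectSpec(1.0))


# ------------------------------------------------------------- cutoff choice
def test_cutoff_approaches_alpha_for_continuous_pvalues(rng):
    p = rng.random(100_000)
    assert select_cutoff(p, 0.05) == pytest.approx(0.05, abs=0.005)


def test_cutoff_never_over_rejects_on_calibration_sample(rng):
    """With heavily tied (discrete) p-values the attained rejection rate on
    the calibration sample itself stays at or below floor(alpha*n)/n."""
    atoms = np.array([0.01, 0.03, 0.06, 0.2, 1.0])
    p = rng.choice(atoms, size=10_000, p=[0.02, 0.04, 0.06, 0.3, 0.58])
    cut = select_cutoff(p, 0.05)
    assert (p <= cut).mean() <= 0.05


def test_calibration_requires_null_spec(rng):
    alt = PopulationSpec(n=300, maf=0.3, model="dominant", effect=EffectSpec(1.3))
    with pytest.raises(ValueError, match="null"):
        calibrate_cutoff(alt, DesignArm.full(), rng=rng)
    with pytest.raises(ValueError, match="1000"):
        calibrate_cutoff(NULL_SPEC, DesignArm.full(), n_null_reps=10, rng=rng)


def test_power_requires_matching_calibration(rng):
    cut = calibrate_cutoff(NULL_SPEC, DesignArm.full(), n_null_reps=2000, rng=rng)
    alt = PopulationSpec(n=300, maf=0.3, model="dominant", effect=EffectSpec(1.3))
    with pytest.raises(ValueError, match="different design arm"):
        estimate_power(alt, DesignArm.extreme(0.1), cut, 100, rng)
    other_n = PopulationSpec(n=200, maf=0.3, model="dominant", effect=EffectSpec(1.3))
    with pytest.raises(ValueError, match="different"):
        estimate_power(other_n, DesignArm.full(), cut, 100, rng)


# ------------------------------------------------- design-arm pairing rules
def test_arm_pairing_rules():
    with pytest.raises(ValueError, match="pairs with"):
        DesignArm(kind=ArmKind.EXTREME_CASE_CONTROL, design=ExtremeDesign(0.1, 0.1),
                  test="anova")
    with pytest.raises(ValueError, match="pairs with"):
        DesignArm(kind=ArmKind.FULL_QUANTITATIVE, test="fisher")
    with pytest.raises(ValueError, match="subset"):
        DesignArm(kind=ArmKind.RANDOM_QUANTITATIVE)
    assert DesignArm.median().design == ExtremeDesign(0.5, 0.5)
    assert DesignArm.extreme(0.1, 0.3).n_sampled(300) == 120
    assert DesignArm.random(60).n_sampled(300) == 60
    assert DesignArm.full().n_sampled(300) == 300


# --------------------------------------- vectorized engine == scalar pipeline
def _simulated_block(rng, n_reps=40, n=60, delta=1.3):
    spec = PopulationSpec(n=n, maf=0.3, model="dominant", effect=EffectSpec(delta))
    means = np.array(genotype_means(spec.model, delta))
    return _engine.simulate_cohort_block(n_reps, n, 0.3, means, 1.0, rng)


@pytest.mark.parametrize("test", ["fisher", "fisher_dominant", "fisher_recessive",
                                  "fisher_allelic"])
def test_vectorized_extreme_pvalues_match_scalar_route(rng, test):
    """The batched engine must agree with the one-cohort-at-a-time public
    API (select_extremes -> build_contingency -> collapse -> Fisher)."""
    from extremeqtl.power import _extreme_pvalues

    g, y = _simulated_block(rng)
    arm = DesignArm.extreme(0.2, test=test)
    m = arm.design.n_cases(g.shape[1])
    case, ctrl = _engine.tail_genotype_counts(g, y, m, m)
    if test == "fisher":
        lookup = _engine.FreemanHalton2x3(m, m)
    elif test == "fisher_allelic":
        lookup = _engine.fisher_2x2_pvalue_table(2 * m, 2 * m)
    else:
        lookup = _engine.fisher_2x2_pvalue_table(m, m)
    vec = _extreme_pvalues(arm, case, ctrl, lookup)

    collapse_model = {"fisher_dominant": "dominant", "fisher_recessive": "recessive",
                      "fisher_allelic": "multiplicative"}.get(test)
    for r in range(g.shape[0]):
        cohort = Cohort(genotypes=g[r], phenotypes=y[r])
        sample = select_extremes(cohort, arm.design)
        table = build_contingency(sample, cohort.genotypes)
        if test == "fisher":
            scalar = fisher_exact_2x3(table).p_value
        else:
            scalar = fisher_exact(collapse_table(table, collapse_model)).p_value
        assert vec[r] == pytest.approx(scalar, abs=1e-10)


def test_vectorized_anova_matches_scalar(rng):
    g, y = _simulated_block(rng)
    vec = _engine.anova_pvalues(g, y)
    for r in range(g.shape[0]):
        assert vec[r] == pytest.approx(anova_f(y[r], g[r]).p_value, rel=1e-9)


# ----------------------------------------------------------- analytic oracle
def test_analytic_power_is_alpha_under_null():
    assert analytic_anova_power(NULL_SPEC, alpha=0.05) == 0.05


def test_analytic_noncentrality_arithmetic():
    """Independent re-derivation of lambda for two published settings."""
    from scipy import stats

    # dominant delta=1.2, maf=0.3: lambda = 300 * 0.49*0.51*0.2^2 ~ 2.999
    spec = PopulationSpec(n=300, maf=0.3, model="dominant", effect=EffectSpec(1.2))
    f = np.array(genotype_frequencies(0.3))
    mu = np.array([1.0, 1.2, 1.2])
    lam = 300 * f @ (mu - f @ mu) ** 2
    assert lam == pytest.approx(2.9988, abs=1e-4)
    expected = stats.ncf.sf(stats.f.isf(0.05, 2, 297), 2, 297, lam)
    assert analytic_anova_power(spec) == pytest.approx(expected, rel=1e-12)

    # multiplicative delta=1.2: means (1, 1.2, 1.44), lambda ~ 5.68
    spec_m = PopulationSpec(n=300, maf=0.3, model="multiplicative",
                            effect=EffectSpec(1.2))
    mu_m = np.array([1.0, 1.2, 1.44])
    lam_m = 300 * f @ (mu_m - f @ mu_m) ** 2
    assert lam_m == pytest.approx(5.684, abs=1e-3)
    assert analytic_anova_power(spec_m) == pytest.approx(
        stats.ncf.sf(stats.f.isf(0.05, 2, 297), 2, 297, lam_m), rel=1e-12
    )


def test_full_data_simulation_agrees_with_analytic(rng):
    spec = PopulationSpec(n=300, maf=0.3, model="dominant", effect=EffectSpec(1.3))
    cut = calibrate_cutoff(NULL_SPEC, DesignArm.full(), n_null_reps=20_000,
                          rng=np.random.default_rng(11))
    est = estimate_power(spec, DesignArm.full(), cut, n_reps=4000,
                         rng=np.random.default_rng(12))
    assert abs(est.power - analytic_anova_power(spec)) < 3 * est.mc_se + 0.005


# --------------------------------------------------------------- grid drivers
def test_power_estimate_consistency():
    est = PowerEstimate.from_rejections(440, 2000, 60)
    assert est.power == 0.22
    assert est.power_per_individual == pytest.approx(0.22 / 60)
    assert est.mc_se == pytest.approx(np.sqrt(0.22 * 0.78 / 2000))


def test_power_curve_shape_and_determinism():
    specs = [
        PopulationSpec(n=120, maf=0.3, model="dominant", effect=EffectSpec(d))
        for d in (1.0, 1.5)
    ]
    kwargs = dict(
        fractions=[0.2, 0.5],
        arms=["full_quantitative", "extreme_case_control", "random_quantitative"],
        n_reps=400, calibration_reps=2000, seed=5,
    )
    df1 = power_curve(specs, **kwargs)
    df2 = power_curve(specs, **kwargs)
    # 2 specs x (1 full row + 2 fractions x 2 fraction-dependent arms)
    assert len(df1) == 2 * (1 + 2 * 2)
    pd.testing.assert_frame_equal(df1, df2)  # bit-for-bit reproducible
    assert list(df1.columns)[:6] == ["model", "n", "maf", "sd", "delta", "arm"]
    full = df1[df1["arm"] == "full_quantitative"]
    assert (full["n_sampled"] == 120).all()
    assert df1["power_per_individual"].equals(df1["power"] / df1["n_sampled"])


def test_power_increases_with_effect_size():
    specs = [
        PopulationSpec(n=150, maf=0.3, model="dominant", effect=EffectSpec(d))
        for d in (1.0, 2.0)
    ]
    df = power_curve(specs, fractions=[0.2], arms=["extreme_case_control"],
                     n_reps=600, calibration_reps=3000, seed=9)
    by_delta = df.set_index("delta")["power"]
    assert by_delta[2.0] > by_delta[1.0] + 0.2


def test_ratio_scan_includes_balanced_cell_and_argmax():
    spec = PopulationSpec(n=150, maf=0.3, model="dominant", effect=EffectSpec(1.8))
    df = ratio_scan(spec, f_case=0.1, f_control_grid=[0.1, 0.3],
                    n_reps=400, calibration_reps=2000, seed=3)
    assert set(df["f_lower"]) == {0.1, 0.3}
    assert (df["f_upper"] == 0.1).all()
    assert df.attrs["optimal_power_f_control"] in (0.1, 0.3)
    assert df.attrs["optimal_ppi_f_control"] in (0.1, 0.3)


def test_child_rng_is_key_addressed():
    a = child_rng(7, "power", "cell-a").random(3)
    b = child_rng(7, "power", "cell-a").random(3)
    c = child_rng(7, "power", "cell-b").random(3)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
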