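"""Calibrated type-I-error cutoffs and Monte-Carlo power estimation.

Discrete tests (Fisher-type) and small samples make the attained size of a
nominal alpha = 0.05 rule drift, so all design arms are compared at an
empirically calibrated p-value cutoff: the largest attained null p-value
whose null rejection probability does not exceed alpha, estimated from a
large batch of null (delta = 1) replicates.  Power is then the fraction of
effect replicates with p <= cutoff.

Four analysis arms are supported:

* ``full_quantitative`` -- one-way ANOVA on the whole cohort;
* ``extreme_case_control`` -- Fisher-type exact test on the genotype counts
  in the two phenotype tails (default: the 2x3 conditional exact test on
  the uncollapsed table, which is what R's ``fisher.test`` computes on a
  2x3 matrix; dominant/recessive/allelic 2x2 collapses and a logistic
  mode are available);
* ``random_quantitative`` -- ANOVA on a random subset of the same
  genotyping cost as the matched extreme design;
* ``median_dichotomy`` -- the extreme design with both fractions 0.5,
  i.e. every individual labelled by a median split.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .models import EffectSpec, GeneticModel, PopulationSpec, genotype_frequencies, genotype_means
from .sampling import ExtremeDesign

_FISHER_TESTS = ("fisher", "fisher_dominant", "fisher_recessive", "fisher_allelic")
_EXTREME_TESTS = _FISHER_TESTS + ("logistic",)

DEFAULT_POWER_REPS = 10_000
DEFAULT_CALIBRATION_REPS = 100_000


class ArmKind(str, Enum):
    FULL_QUANTITATIVE = "full_quantitative"
    EXTREME_CASE_CONTROL = "extreme_case_control"
    RANDOM_QUANTITATIVE = "random_quantitative"
    MEDIAN_DICHOTOMY = "median_dichotomy"


@dataclass(frozen=True)
class DesignArm:
    """One analysis arm: a sampling design paired with its test."""

    kind: ArmKind
    design: ExtremeDesign | None = None
    subset: int | None = None
    test: str = "anova"

    def __post_init__(self) -> None:
        kind = ArmKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in (ArmKind.EXTREME_CASE_CONTROL, ArmKind.MEDIAN_DICHOTOMY):
            if self.test not in _EXTREME_TESTS:
                raise ValueError(
                    f"{kind.value} pairs with {_EXTREME_TESTS}, got {self.test!r}"
                )
            if kind is ArmKind.MEDIAN_DICHOTOMY:
                object.__setattr__(self, "design", ExtremeDesign(0.5, 0.5))
            elif self.design is None:
                raise ValueError("extreme_case_control requires an ExtremeDesign")
        else:
            if self.test != "anova":
                raise ValueError(f"{kind.value} pairs with the 'anova' test")
            if kind is ArmKind.RANDOM_QUANTITATIVE and not self.subset:
                raise ValueError("random_quantitative requires a subset size")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def full(cls) -> "DesignArm":
        return cls(kind=ArmKind.FULL_QUANTITATIVE)

    @classmethod
    def extreme(cls, f_upper: float, f_lower: float | None = None, test: str = "fisher") -> "DesignArm":
        design = ExtremeDesign(f_upper, f_upper if f_lower is None else f_lower)
        return cls(kind=ArmKind.EXTREME_CASE_CONTROL, design=design, test=test)

    @classmethod
    def random(cls, subset: int) -> "DesignArm":
        return cls(kind=ArmKind.RANDOM_QUANTITATIVE, subset=subset)

    @classmethod
    def median(cls, test: str = "fisher") -> "DesignArm":
        return cls(kind=ArmKind.MEDIAN_DICHOTOMY, test=test)

    def n_sampled(self, n: int) -> int:
        """Genotyped individuals per replicate (the cost denominator)."""
        if self.kind is ArmKind.FULL_QUANTITATIVE:
            return n
        if self.kind is ArmKind.RANDOM_QUANTITATIVE:
            return int(self.subset)
        return self.design.n_sampled(n)


@dataclass(frozen=True)
class CalibratedCutoff:
    """Empirical p-value threshold with attained null level <= alpha."""

    alpha: float
    cutoff: float
    n_null_reps: int
    arm: DesignArm
    n: int
    maf: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection rate with its binomial standard error and cost."""

    power: float
    mc_se: float
    n_reps: int
    n_sampled: int
    power_per_individual: float

    @classmethod
    def from_rejections(cls, n_reject: int, n_reps: int, n_sampled: int) -> "PowerEstimate":
        power = n_reject / n_reps
        return cls(
            power=power,
            mc_se=float(np.sqrt(power * (1.0 - power) / n_reps)),
            n_reps=n_reps,
            n_sampled=n_sampled,
            power_per_individual=power / n_sampled,
        )


def child_rng(seed: int, *key_parts) -> np.random.Generator:
    """Deterministic per-cell random stream: the cell key, not the execution
    order, decides the stream, so grid cells are order-independent."""
    digest = zlib.crc32("|".join(str(p) for p in key_parts).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, digest]))


def _arm_pvalues(
    spec: PopulationSpec,
    arm: DesignArm,
    n_reps: int,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> np.ndarray:
    """Simulate n_reps cohorts under spec and return the arm's p-values."""
    means = np.asarray(genotype_means(spec.model, spec.effect.delta))
    n = spec.n
    lookup = None
    if arm.kind in (ArmKind.EXTREME_CASE_CONTROL, ArmKind.MEDIAN_DICHOTOMY):
        m_case = arm.design.n_cases(n)
        m_ctrl = arm.design.n_controls(n)
        if arm.test == "fisher":
            lookup = _engine.FreemanHalton2x3(m_case, m_ctrl)
        elif arm.test == "fisher_allelic":
            lookup = _engine.fisher_2x2_pvalue_table(2 * m_case, 2 * m_ctrl)
        elif arm.test in ("fisher_dominant", "fisher_recessive"):
            lookup = _engine.fisher_2x2_pvalue_table(m_case, m_ctrl)
    out = []
    done = 0
    while done < n_reps:
        r = min(chunk, n_reps - done)
        g, y = _engine.simulate_cohort_block(r, n, spec.maf, means, spec.effect.sd, rng)
        if arm.kind is ArmKind.FULL_QUANTITATIVE:
            out.append(_engine.anova_pvalues(g, y))
        elif arm.kind is ArmKind.RANDOM_QUANTITATIVE:
            gs, ys = _engine.random_subsets(g, y, int(arm.subset), rng)
            out.append(_engine.anova_pvalues(gs, ys))
        else:
            case, ctrl = _engine.tail_genotype_counts(g, y, m_case, m_ctrl)
            out.append(_extreme_pvalues(arm, case, ctrl, lookup))
        done += r
    return np.concatenate(out)


def _extreme_pvalues(arm, case_counts, ctrl_counts, lookup) -> np.ndarray:
    if arm.test == "fisher":
        return lookup.pvalues(
            case_counts[:, 0], case_counts[:, 1], ctrl_counts[:, 0], ctrl_counts[:, 1]
        )
    if arm.test == "fisher_dominant":
        x = case_counts[:, 0]
        c1 = x + ctrl_counts[:, 0]
        return lookup[c1, x]
    if arm.test == "fisher_recessive":
        x = case_counts[:, 2]
        c1 = x + ctrl_counts[:, 2]
        return lookup[c1, x]
    if arm.test == "fisher_allelic":
        x = 2 * case_counts[:, 0] + case_counts[:, 1]
        c1 = x + 2 * ctrl_counts[:, 0] + ctrl_counts[:, 1]
        return lookup[c1, x]
    if arm.test == "logistic":
        from .assoc import logistic_assoc

        ps = np.empty(len(case_counts))
        for i, (u, l) in enumerate(zip(case_counts, ctrl_counts)):
            labels = np.r_[np.ones(u.sum()), np.zeros(l.sum())]
            doses = np.r_[np.repeat([0, 1, 2], u), np.repeat([0, 1, 2], l)]
            ps[i] = logistic_assoc(labels, doses).p_value
        return ps
    raise ValueError(f"unknown extreme-arm test {arm.test!r}")


def select_cutoff(null_pvalues: np.ndarray, alpha: float) -> float:
    """Largest attained null p-value whose empirical null rejection
    proportion (P(p <= cutoff)) does not exceed alpha."""
    p = np.asarray(null_pvalues)
    n = len(p)
    k = int(np.floor(alpha * n))
    vals, counts = np.unique(p, return_counts=True)
    cum = np.cumsum(counts)
    idx = np.searchsorted(cum, k, side="right") - 1
    if idx < 0:
        # even the smallest attained p-value is too frequent; reject nothing
        return float(vals[0]) / 2.0 if vals[0] > 0 else np.finfo(float).tiny
    return float(vals[idx])


def calibrate_cutoff(
    spec: PopulationSpec,
    arm: DesignArm,
    alpha: float = 0.05,
    n_null_reps: int = DEFAULT_CALIBRATION_REPS,
    rng: np.random.Generator | None = None,
) -> CalibratedCutoff:
    """Estimate the calibrated cutoff from n_null_reps null replicates.

    The spec must encode the null (delta = 1): calibration is a property
    of the design and sample size, not of the effect.
    """
    if not spec.effect.is_null:
        raise ValueError("calibration requires the null spec (delta = 1)")
    if n_null_reps < 1000:
        raise ValueError("n_null_reps must be at least 1000")
    rng = np.random.default_rng() if rng is None else rng
    p = _arm_pvalues(spec, arm, n_null_reps, rng)
    return CalibratedCutoff(
        alpha=alpha,
        cutoff=select_cutoff(p, alpha),
        n_null_reps=n_null_reps,
        arm=arm,
        n=spec.n,
        maf=spec.maf,
        sd=spec.effect.sd,
    )


def estimate_power(
    spec: PopulationSpec,
    arm: DesignArm,
    cutoff: CalibratedCutoff,
    n_reps: int = DEFAULT_POWER_REPS,
    rng: np.random.Generator | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of the arm at the calibrated cutoff (reject p <= cutoff)."""
    if cutoff.arm != arm:
        raise ValueError("cutoff was calibrated for a different design arm")
    if (cutoff.n, cutoff.maf, cutoff.sd) != (spec.n, spec.maf, spec.effect.sd):
        raise ValueError(
            "cutoff was calibrated under different (n, maf, sd) conditions"
        )
    rng = np.random.default_rng() if rng is None else rng
    p = _arm_pvalues(spec, arm, n_reps, rng)
    return PowerEstimate.from_rejections(
        int((p <= cutoff.cutoff).sum()), n_reps, arm.n_sampled(spec.n)
    )


def analytic_anova_power(spec: PopulationSpec, alpha: float = 0.05) -> float:
    """Closed-form power of the full-data one-way ANOVA via the noncentral F.

    The noncentrality is lambda = n * sum_g f_g (mu_g - mu_bar)^2 / sd^2
    over the HWE genotype frequencies; power is the upper tail of
    F'(df1=2, df2=n-3, lambda) beyond the central-F critical value.
    """
    if spec.n < 4:
        raise ValueError("analytic ANOVA power requires n >= 4")
    freqs = np.asarray(genotype_frequencies(spec.maf))
    mu = np.asarray(genotype_means(spec.model, spec.effect.delta))
    mu_bar = freqs @ mu
    lam = spec.n * (freqs @ (mu - mu_bar) ** 2) / spec.effect.sd**2
    df1, df2 = 2, spec.n - 3
    crit = stats.f.isf(alpha, df1, df2)
    if spec.effect.is_null or lam < 1e-12:  # central case, up to rounding in mu_bar
        return float(alpha)
    return float(stats.ncf.sf(crit, df1, df2, lam))


# ---------------------------------------------------------------------------
# grid drivers

POWER_TABLE_COLUMNS = [
    "model", "n", "maf", "sd", "delta", "arm", "f_upper", "f_lower",
    "n_sampled", "n_reps", "cutoff", "power", "mc_se",
    "power_per_individual", "seed",
]


def _null_spec(spec: PopulationSpec) -> PopulationSpec:
    return PopulationSpec(
        n=spec.n, maf=spec.maf, model=spec.model,
        effect=EffectSpec(delta=1.0, sd=spec.effect.sd),
    )


class _CalibrationCache:
    """One calibration per (arm configuration, n, maf, sd): the null p-value
    distribution does not depend on the effect size."""

    def __init__(self, alpha: float, n_null_reps: int, seed: int) -> None:
        self.alpha = alpha
        self.n_null_reps = n_null_reps
        self.seed = seed
        self._store: dict = {}

    def get(self, spec: PopulationSpec, arm: DesignArm) -> CalibratedCutoff:
        key = (arm, spec.n, spec.maf, spec.effect.sd)
        if key not in self._store:
            rng = child_rng(self.seed, "calibrate", arm, spec.n, spec.maf, spec.effect.sd)
            self._store[key] = calibrate_cutoff(
                _null_spec(spec), arm, self.alpha, self.n_null_reps, rng
            )
        return self._store[key]


def _arm_for(kind: str, spec: PopulationSpec, f: float | None, extreme_test: str) -> DesignArm:
    kind = ArmKind(kind)
    if kind is ArmKind.FULL_QUANTITATIVE:
        return DesignArm.full()
    if kind is ArmKind.EXTREME_CASE_CONTROL:
        return DesignArm.extreme(f, test=extreme_test)
    if kind is ArmKind.MEDIAN_DICHOTOMY:
        return DesignArm.median(test=extreme_test)
    design = ExtremeDesign(f, f)
    return DesignArm.random(design.n_sampled(spec.n))


def _row(spec, arm, cut, est, seed) -> dict:
    design = arm.design
    return {
        "model": spec.model.value,
        "n": spec.n,
        "maf": spec.maf,
        "sd": spec.effect.sd,
        "delta": spec.effect.delta,
        "arm": arm.kind.value,
        "f_upper": design.f_upper if design is not None else np.nan,
        "f_lower": design.f_lower if design is not None else np.nan,
        "n_sampled": est.n_sampled,
        "n_reps": est.n_reps,
        "cutoff": cut.cutoff,
        "power": est.power,
        "mc_se": est.mc_se,
        "power_per_individual": est.power_per_individual,
        "seed": seed,
    }


def power_curve(
    specs: Sequence[PopulationSpec],
    fractions: Iterable[float],
    arms: Iterable[str] = ("full_quantitative", "extreme_case_control", "random_quantitative"),
    n_reps: int = DEFAULT_POWER_REPS,
    calibration_reps: int = DEFAULT_CALIBRATION_REPS,
    alpha: float = 0.05,
    seed: int = 0,
    extreme_test: str = "fisher",
) -> pd.DataFrame:
    """Power for every (spec, sampling fraction, arm) cell, each at its own
    calibrated cutoff; full-data rows are fraction-invariant and appear once
    per spec."""
    fractions = list(fractions)
    if any(not 0.0 < f <= 0.5 for f in fractions):
        raise ValueError("fractions must lie in (0, 0.5]")
    cache = _CalibrationCache(alpha, calibration_reps, seed)
    rows = []
    for spec in specs:
        for kind in arms:
            cell_fractions = [None] if ArmKind(kind) is ArmKind.FULL_QUANTITATIVE else fractions
            for f in cell_fractions:
                arm = _arm_for(kind, spec, f, extreme_test)
                cut = cache.get(spec, arm)
                rng = child_rng(
                    seed, "power", arm, spec.model.value, spec.n, spec.maf,
                    spec.effect.delta, spec.effect.sd,
                )
                est = estimate_power(spec, arm, cut, n_reps, rng)
                rows.append(_row(spec, arm, cut, est, seed))
    return pd.DataFrame(rows, columns=POWER_TABLE_COLUMNS)


def ratio_scan(
    spec: PopulationSpec,
    f_case: float,
    f_control_grid: Iterable[float],
    n_reps: int = DEFAULT_POWER_REPS,
    calibration_reps: int = DEFAULT_CALIBRATION_REPS,
    alpha: float = 0.05,
    seed: int = 0,
    extreme_test: str = "fisher",
) -> pd.DataFrame:
    """Power across unbalanced case:control designs: the case fraction is
    fixed and the control fraction varies.  The returned frame carries the
    power- and efficiency-optimal control fractions in ``DataFrame.attrs``."""
    cache = _CalibrationCache(alpha, calibration_reps, seed)
    rows = []
    for f_ctrl in f_control_grid:
        arm = DesignArm(
            kind=ArmKind.EXTREME_CASE_CONTROL,
            design=ExtremeDesign(f_upper=f_case, f_lower=f_ctrl),
            test=extreme_test,
        )
        cut = cache.get(spec, arm)
        rng = child_rng(
            seed, "power", arm, spec.model.value, spec.n, spec.maf,
            spec.effect.delta, spec.effect.sd,
        )
        est = estimate_power(spec, arm, cut, n_reps, rng)
        rows.append(_row(spec, arm, cut, est, seed))
    df = pd.DataFrame(rows, columns=POWER_TABLE_COLUMNS)
    df.attrs["optimal_power_f_control"] = float(df.loc[df["power"].idxmax(), "f_lower"])
    df.attrs["optimal_ppi_f_control"] = float(
        df.loc[df["power_per_individual"].idxmax(), "f_lower"]
    )
    return df


def write_power_table(df: pd.DataFrame, path) -> None:
    """Write a power grid as TSV with 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
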