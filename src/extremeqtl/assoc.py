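"""Association tests and marker QC statistics.

Fisher's exact test on the tail-genotype table drives the case-control
analyses.  The table of Table-1 form is 2x3 (two tails x three genotypes);
it can be tested directly with the 2x3 conditional exact test
(Freeman-Halton), or collapsed to 2x2 under a dominant, recessive or
allelic (multiplicative) coding first.  Two-sided p-values use the
point-probability convention: the p-value is the total conditional
probability of all tables with the observed margins whose probability does
not exceed that of the observed table.

Quantitative analyses use one-way fixed-effects ANOVA across genotype
classes; the per-SNP pipeline can also fit a univariate logistic
regression of case status on dosage.  QC helpers provide the exact
Hardy-Weinberg test and the genomic inflation factor lambda_GC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .models import GeneticModel
from .sampling import ContingencyTable

# relative tolerance when comparing point probabilities for the two-sided
# "as or less probable" rule; guards against floating-point near-ties
_TIE_RTOL = 1e-9


@dataclass
class TestResult:
    """Outcome of a single association or QC test."""

    p_value: float
    statistic: float
    test_name: str
    df: int | None = None
    separation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class CollapsedTable:
    """2x2 counts after model-specific collapsing; rows are upper/lower tail."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name} must be a nonnegative integer, got {v}")

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def column_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def collapse_table(table: ContingencyTable, model: GeneticModel | str) -> CollapsedTable:
    """Collapse the 2x3 tail-genotype table to 2x2 under a genetic model.

    dominant: AA vs (AB u BB); recessive: (AA u AB) vs BB;
    multiplicative: allele counts, each individual contributing two alleles.
    """
    model = GeneticModel.coerce(model)
    if model is GeneticModel.DOMINANT:
        return CollapsedTable(
            a=table.u_aa, b=table.u_ab + table.u_bb,
            c=table.l_aa, d=table.l_ab + table.l_bb,
        )
    if model is GeneticModel.RECESSIVE:
        return CollapsedTable(
            a=table.u_aa + table.u_ab, b=table.u_bb,
            c=table.l_aa + table.l_ab, d=table.l_bb,
        )
    return CollapsedTable(
        a=2 * table.u_aa + table.u_ab, b=table.u_ab + 2 * table.u_bb,
        c=2 * table.l_aa + table.l_ab, d=table.l_ab + 2 * table.l_bb,
    )


def hypergeom_point_prob(table: CollapsedTable) -> float:
    """Conditional (hypergeometric) probability of a 2x2 table given its margins:

    C(r1, a) * C(r2, c) / C(N, a + c).
    """
    r1, r2 = table.row_totals
    n = table.total
    if n == 0:
        raise ValueError("table has no observations")
    return float(stats.hypergeom.pmf(table.a, n, table.a + table.c, r1))


def fisher_exact(table: CollapsedTable) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table (point-probability method).

    The statistic reported is the hypergeometric probability of the
    observed table.  A table with a zero column margin carries no
    association information and yields p = 1.
    """
    if table.total == 0:
        raise ValueError("cannot test an all-zero table")
    r1, _ = table.row_totals
    c1, c2 = table.column_totals
    n = table.total
    p_obs = hypergeom_point_prob(table)
    if c1 == 0 or c2 == 0 or r1 == 0 or r1 == n:
        return TestResult(p_value=1.0, statistic=p_obs, test_name="fisher_exact")
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p = pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum()
    return TestResult(p_value=float(min(p, 1.0)), statistic=p_obs, test_name="fisher_exact")


def fisher_exact_2x3(table: ContingencyTable) -> TestResult:
    """Two-sided conditional exact test on the full 2x3 tail-genotype table
    (Freeman-Halton extension of Fisher's test, point-probability method)."""
    if table.total == 0:
        raise ValueError("cannot test an all-zero table")
    u, l = table.n_upper, table.n_lower
    ya, yb, yc = table.column_totals
    if u == 0 or l == 0 or sum(m > 0 for m in (ya, yb, yc)) < 2:
        return TestResult(p_value=1.0, statistic=1.0, test_name="fisher_exact_2x3")
    lp, pairs = _fh_log_probs(u, l, ya, yb)
    logp_obs = lp[pairs.index((table.u_aa, table.u_ab))]
    probs = np.exp(lp)
    p_obs = float(np.exp(logp_obs))
    p = probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum()
    return TestResult(
        p_value=float(min(p, 1.0)), statistic=p_obs, test_name="fisher_exact_2x3"
    )


def _fh_log_probs(u: int, l: int, ya: int, yb: int) -> tuple[np.ndarray, list]:
    """Log conditional probabilities of all 2x3 tables with row sums (u, l)
    and column sums (ya, yb, u + l - ya - yb); returns (log-probs, (a, b) list)."""
    n = u + l
    yc = n - ya - yb
    lf = gammaln(np.arange(n + 2) + 1.0)  # lf[k] = log(k!), k <= n+1
    const = lf[u] + lf[l] + lf[ya] + lf[yb] + lf[yc] - lf[n]
    pairs = []
    lps = []
    for a in range(max(0, ya - l), min(u, ya) + 1):
        b_lo = max(0, u - a - yc)
        b_hi = min(u - a, yb)
        for b in range(b_lo, b_hi + 1):
            c = u - a - b
            lps.append(
                const
                - (lf[a] + lf[b] + lf[c] + lf[ya - a] + lf[yb - b] + lf[yc - c])
            )
            pairs.append((a, b))
    return np.asarray(lps), pairs


def anova_f(phenotypes: np.ndarray, genotypes: np.ndarray) -> TestResult:
    """One-way fixed-effects ANOVA of the trait across genotype classes present.

    Uses every genotype class with at least one observation (up to three
    groups); df1 = groups - 1, df2 = n - groups.
    """
    y = np.asarray(phenotypes, dtype=float)
    g = np.asarray(genotypes)
    if y.shape != g.shape:
        raise ValueError("phenotypes and genotypes must have equal length")
    counts = np.bincount(g, minlength=3)
    present = np.flatnonzero(counts)
    k = len(present)
    n = len(y)
    if k < 2:
        raise ValueError("ANOVA needs at least two genotype classes present")
    if n - k < 1:
        raise ValueError("ANOVA needs positive residual degrees of freedom")
    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for cls in present:
        yi = y[g == cls]
        ss_between += len(yi) * (yi.mean() - grand) ** 2
        ss_within += ((yi - yi.mean()) ** 2).sum()
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(p_value=1.0, statistic=0.0, test_name="anova_f", df=df1)
        # perfectly separated group means with zero residual variance
        p = float(np.finfo(float).tiny)
        return TestResult(p_value=p, statistic=np.inf, test_name="anova_f", df=df1)
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return TestResult(
        p_value=max(p, np.finfo(float).tiny) if f_stat > 0 else 1.0,
        statistic=float(f_stat),
        test_name="anova_f",
        df=df1,
    )


def logistic_assoc(
    case_labels: np.ndarray,
    genotypes: np.ndarray,
    coding: str = "additive",
) -> TestResult:
    """Univariate logistic regression of case status on genotype.

    additive coding regresses on the 0/1/2 dosage and reports the Wald
    p-value of the dosage slope; categorical coding treats genotype as a
    factor and reports the 2-df likelihood-ratio p-value.  Complete or
    quasi-complete separation (or a constant genotype) is flagged with
    ``separation=True`` and p = 1 rather than raised, so per-SNP scans
    never abort.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(case_labels, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if y.shape != g.shape:
        raise ValueError("labels and genotypes must have equal length")
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("case labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both case and control labels must be present")
    flagged = TestResult(
        p_value=1.0, statistic=0.0, test_name=f"logistic_{coding}", separation=True
    )
    if np.ptp(g) == 0:
        return flagged
    if coding == "additive":
        x = sm.add_constant(g)
    elif coding == "categorical":
        levels = np.unique(g)
        x = np.column_stack([np.ones_like(g)] + [(g == lv).astype(float) for lv in levels[1:]])
    else:
        raise ValueError(f"unknown coding {coding!r}")
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected explicitly below and flagged, not raised
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return flagged
    if not fit.mle_retvals.get("converged", False) or np.any(fit.bse[1:] > 1e3):
        return flagged
    if coding == "additive":
        z = float(fit.params[1] / fit.bse[1])
        p = float(2.0 * stats.norm.sf(abs(z)))
        return TestResult(
            p_value=min(max(p, np.finfo(float).tiny), 1.0),
            statistic=z,
            test_name="logistic_additive",
            df=1,
        )
    lr = float(fit.llr)
    p = float(stats.chi2.sf(lr, fit.df_model))
    return TestResult(
        p_value=min(max(p, np.finfo(float).tiny), 1.0),
        statistic=lr,
        test_name="logistic_categorical",
        df=int(fit.df_model),
    )


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> TestResult:
    """Exact test of Hardy-Weinberg equilibrium on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts as or less probable than the observed one.
    Monomorphic markers yield p = 1.
    """
    for name, v in (("n_aa", n_aa), ("n_ab", n_ab), ("n_bb", n_bb)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual is required")
    n_a = 2 * n_aa + n_ab  # A-allele count
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return TestResult(p_value=1.0, statistic=float(n_ab), test_name="hwe_exact")
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    lf = gammaln(np.arange(2 * n + 2) + 1.0)
    # P(h | n_A, n_B) proportional to n! 2^h / ((n_A-h)/2)! h! ((n_B-h)/2)!
    lp = hets * np.log(2.0) - (
        lf[(n_a - hets) // 2] + lf[hets] + lf[(n_b - hets) // 2]
    )
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    p_obs = probs[np.where(hets == n_ab)[0][0]]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return TestResult(p_value=min(p, 1.0), statistic=float(n_ab), test_name="hwe_exact")


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square implied by the
    p-values divided by the null chi-square median (~0.4549)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be nonempty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
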