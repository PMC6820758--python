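"""Vectorized Monte-Carlo internals for the power engine.

These routines replicate, across thousands of simulated cohorts at once,
exactly what the scalar path (simulate_cohort -> select_extremes ->
build_contingency -> fisher/anova) computes one cohort at a time; the
test suite asserts bitwise agreement of the two routes on shared inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

_TIE_RTOL = 1e-9


def fisher_2x2_pvalue_table(n_row1: int, n_row2: int) -> np.ndarray:
    """Two-sided Fisher p-values for all 2x2 tables with fixed row sums.

    Returns P of shape (n_row1 + n_row2 + 1, n_row1 + 1) where
    P[c1, x] is the point-probability two-sided p-value of the table with
    first-column total c1 and first-row/first-column cell x.  Infeasible
    (c1, x) combinations hold 1.0.
    """
    n = n_row1 + n_row2
    table = np.ones((n + 1, n_row1 + 1))
    for c1 in range(n + 1):
        lo = max(0, c1 - n_row2)
        hi = min(n_row1, c1)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, n, c1, n_row1)
        if c1 == 0 or c1 == n:
            table[c1, support] = 1.0
            continue
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        ranks = np.searchsorted(pmf[order], pmf * (1.0 + _TIE_RTOL), side="right") - 1
        table[c1, support] = np.minimum(csum[ranks], 1.0)
    return table


class FreemanHalton2x3:
    """Grouped evaluator for the 2x3 conditional exact test at fixed row sums.

    Replicates sharing column margins (ya, yb) share one enumeration of the
    conditional table distribution; results are cached across calls, so a
    long calibration run amortizes the enumeration cost.
    """

    def __init__(self, n_row1: int, n_row2: int) -> None:
        self.u = int(n_row1)
        self.l = int(n_row2)
        n = self.u + self.l
        self._lf = gammaln(np.arange(n + 2) + 1.0)  # log(k!)
        # margin key -> (sorted probs, cumsum, dense p_obs grid, a_lo, b_lo)
        self._cache: dict[int, tuple] = {}

    def _margin_tables(self, ya: int, yb: int):
        u, l, lf = self.u, self.l, self._lf
        n = u + l
        yc = n - ya - yb
        a_lo, a_hi = max(0, ya - l), min(u, ya)
        b_lo, b_hi = 0, min(u, yb)
        a = np.arange(a_lo, a_hi + 1)[:, None]
        b = np.arange(b_lo, b_hi + 1)[None, :]
        c = u - a - b
        feasible = (b <= yb) & (c >= 0) & (c <= yc)
        la, lb, lc = ya - a, yb - b, yc - c
        const = lf[u] + lf[l] + lf[ya] + lf[yb] + lf[yc] - lf[n]
        with np.errstate(invalid="ignore"):
            lp = np.where(
                feasible,
                const
                - (
                    lf[np.clip(a, 0, None)]
                    + lf[np.clip(b, 0, None)]
                    + lf[np.clip(c, 0, None)]
                    + lf[np.clip(la, 0, None)]
                    + lf[np.clip(lb, 0, None)]
                    + lf[np.clip(lc, 0, None)]
                ),
                -np.inf,
            )
        probs = np.exp(lp)
        flat = probs[feasible]
        order = np.sort(flat)
        csum = np.cumsum(order)
        return order, csum, probs, a_lo, b_lo

    def pvalues(
        self,
        u_aa: np.ndarray,
        u_ab: np.ndarray,
        l_aa: np.ndarray,
        l_ab: np.ndarray,
    ) -> np.ndarray:
        """p-values for a batch of 2x3 tables with this object's row sums."""
        u_aa = np.asarray(u_aa)
        u_ab = np.asarray(u_ab)
        ya = u_aa + np.asarray(l_aa)
        yb = u_ab + np.asarray(l_ab)
        out = np.empty(len(ya))
        n = self.u + self.l
        keys = ya * (n + 1) + yb
        uniq, inverse = np.unique(keys, return_inverse=True)
        for gi, key in enumerate(uniq):
            g_ya, g_yb = int(key) // (n + 1), int(key) % (n + 1)
            members = np.flatnonzero(inverse == gi)
            if g_ya + g_yb > n:
                raise ValueError("column margins exceed the table total")
            degenerate = (
                sum(m > 0 for m in (g_ya, g_yb, n - g_ya - g_yb)) < 2
                or self.u == 0
                or self.l == 0
            )
            if degenerate:
                out[members] = 1.0
                continue
            entry = self._cache.get(int(key))
            if entry is None:
                entry = self._margin_tables(g_ya, g_yb)
                self._cache[int(key)] = entry
            order, csum, probs, a_lo, b_lo = entry
            p_obs = probs[u_aa[members] - a_lo, u_ab[members] - b_lo]
            idx = np.searchsorted(order, p_obs * (1.0 + _TIE_RTOL), side="right") - 1
            out[members] = np.minimum(csum[idx], 1.0)
        return out


def anova_pvalues(genotypes: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Row-wise one-way ANOVA p-values across genotype classes.

    genotypes: (R, n) dosages in {0, 1, 2}; phenotypes: (R, n) floats.
    Rows with fewer than two genotype classes yield p = 1 (no test).
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotypes, dtype=float)
    r, n = y.shape
    ss_groups = np.zeros(r)
    k = np.zeros(r, dtype=int)
    for cls in (0, 1, 2):
        mask = g == cls
        n_g = mask.sum(axis=1)
        s_g = np.where(mask, y, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(n_g > 0, s_g * s_g / np.maximum(n_g, 1), 0.0)
        ss_groups += contrib
        k += (n_g > 0).astype(int)
    total = y.sum(axis=1)
    sst = (y * y).sum(axis=1) - total * total / n
    ssb = ss_groups - total * total / n
    ssw = sst - ssb
    df1 = k - 1
    df2 = n - k
    testable = (k >= 2) & (df2 >= 1) & (ssw > 0)
    p = np.ones(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = (ssb / np.maximum(df1, 1)) / np.where(testable, ssw, 1.0) * df2
    p[testable] = stats.f.sf(f_stat[testable], df1[testable], df2[testable])
    # zero residual variance but real group differences: off-the-scale F
    exact_sep = (k >= 2) & (df2 >= 1) & (ssw == 0) & (ssb > 0)
    p[exact_sep] = np.finfo(float).tiny
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_cohort_block(
    n_reps: int,
    n: int,
    maf: float,
    means: np.ndarray,
    sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate n_reps cohorts at once: (R, n) dosages and phenotypes."""
    g = rng.binomial(2, maf, size=(n_reps, n)).astype(np.int8)
    y = rng.normal(np.asarray(means)[g], sd)
    return g, y


def tail_genotype_counts(
    g: np.ndarray, y: np.ndarray, m_case: int, m_ctrl: int
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype counts (R, 3) among the top m_case and bottom m_ctrl phenotypes
    of each row, with ties broken by ascending column index (stable sort)."""
    order = np.argsort(y, axis=1, kind="stable")
    n = y.shape[1]
    ctrl_g = np.take_along_axis(g, order[:, :m_ctrl], axis=1)
    case_g = np.take_along_axis(g, order[:, n - m_case:], axis=1)
    case_counts = np.stack([(case_g == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
    ctrl_counts = np.stack([(ctrl_g == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
    return case_counts, ctrl_counts


def random_subsets(
    g: np.ndarray, y: np.ndarray, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row uniform subsets of size m (without replacement) of (g, y)."""
    keys = rng.random(y.shape)
    pick = np.argpartition(keys, m - 1, axis=1)[:, :m]
    return np.take_along_axis(g, pick, axis=1), np.take_along_axis(y, pick, axis=1)
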