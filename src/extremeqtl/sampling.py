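"""Sampling designs: extreme tails, random subsets, and genotype contingency counts.

An extreme design genotypes only the individuals in the two tails of the
phenotype distribution: the upper-tail fraction becomes "cases" and the
lower-tail fraction "controls".  Tail membership is decided by rank
(order statistics), so the selected counts are exact; phenotype ties are
broken by ascending individual index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Cohort


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ExtremeDesign:
    """Upper/lower tail sampling fractions.

    f_upper is the fraction of the cohort taken from the upper tail as
    cases, f_lower the fraction taken from the lower tail as controls.
    ``f_upper == f_lower == 0.5`` is the median-dichotomy design in which
    every individual is labelled.
    """

    f_upper: float
    f_lower: float

    def __post_init__(self) -> None:
        for name, f in (("f_upper", self.f_upper), ("f_lower", self.f_lower)):
            if not 0.0 < f <= 0.5:
                raise ValueError(f"{name} must be in (0, 0.5], got {f}")
        if self.f_upper + self.f_lower > 1.0 + 1e-12:
            raise ValueError(
                f"tails overlap: f_upper + f_lower = {self.f_upper + self.f_lower} > 1"
            )

    def n_cases(self, n: int) -> int:
        return max(1, _round_half_up(n * self.f_upper))

    def n_controls(self, n: int) -> int:
        return max(1, _round_half_up(n * self.f_lower))

    def n_sampled(self, n: int) -> int:
        """Genotyping cost: number of individuals selected."""
        return self.n_cases(n) + self.n_controls(n)


@dataclass
class CaseControlSample:
    """Index sets of selected cases and controls with the induced thresholds.

    t1 is the largest control phenotype (control threshold), t2 the
    smallest case phenotype (case threshold); t1 <= t2 except in the
    median-dichotomy limit where they may coincide.
    """

    case_indices: np.ndarray
    control_indices: np.ndarray
    t1: float
    t2: float

    def __post_init__(self) -> None:
        self.case_indices = np.asarray(self.case_indices, dtype=np.intp)
        self.control_indices = np.asarray(self.control_indices, dtype=np.intp)
        if np.intersect1d(self.case_indices, self.control_indices).size:
            raise ValueError("case and control index sets must be disjoint")

    @property
    def n_cases(self) -> int:
        return len(self.case_indices)

    @property
    def n_controls(self) -> int:
        return len(self.control_indices)


@dataclass(frozen=True)
class ContingencyTable:
    """Genotype counts in the two tails (upper row = cases, lower row = controls)."""

    u_aa: int
    u_ab: int
    u_bb: int
    l_aa: int
    l_ab: int
    l_bb: int

    def __post_init__(self) -> None:
        for name in ("u_aa", "u_ab", "u_bb", "l_aa", "l_ab", "l_bb"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def n_upper(self) -> int:
        return self.u_aa + self.u_ab + self.u_bb

    @property
    def n_lower(self) -> int:
        return self.l_aa + self.l_ab + self.l_bb

    @property
    def total(self) -> int:
        return self.n_upper + self.n_lower

    @property
    def column_totals(self) -> tuple[int, int, int]:
        return (
            self.u_aa + self.l_aa,
            self.u_ab + self.l_ab,
            self.u_bb + self.l_bb,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.u_aa, self.u_ab, self.u_bb], [self.l_aa, self.l_ab, self.l_bb]]
        )


def select_extremes(cohort: Cohort, design: ExtremeDesign) -> CaseControlSample:
    """Select the top round(n*f_upper) phenotypes as cases and the bottom
    round(n*f_lower) as controls (rank-based; ties broken by ascending index)."""
    n = len(cohort)
    m_case = design.n_cases(n)
    m_ctrl = design.n_controls(n)
    if m_case + m_ctrl > n:
        raise ValueError(
            f"design selects {m_case}+{m_ctrl} individuals from a cohort of {n}"
        )
    order = np.argsort(cohort.phenotypes, kind="stable")
    control_idx = order[:m_ctrl]
    case_idx = order[n - m_case:]
    return CaseControlSample(
        case_indices=case_idx,
        control_indices=control_idx,
        t1=float(cohort.phenotypes[order[m_ctrl - 1]]),
        t2=float(cohort.phenotypes[order[n - m_case]]),
    )


def select_random(cohort: Cohort, m: int, rng: np.random.Generator) -> np.ndarray:
    """Simple random sample (without replacement) of m individual indices.

    The subset keeps its quantitative phenotypes; no case/control
    dichotomization is applied (random subsets are analysed quantitatively
    downstream).
    """
    n = len(cohort)
    if not 1 <= m <= n:
        raise ValueError(f"subset size m must be in [1, {n}], got {m}")
    return np.sort(rng.choice(n, size=m, replace=False)).astype(np.intp)


def build_contingency(sample: CaseControlSample, genotypes: np.ndarray) -> ContingencyTable:
    """Count genotypes among cases (upper row) and controls (lower row)."""
    genotypes = np.asarray(genotypes)
    u = np.bincount(genotypes[sample.case_indices], minlength=3)
    l = np.bincount(genotypes[sample.control_indices], minlength=3)
    return ContingencyTable(
        u_aa=int(u[0]), u_ab=int(u[1]), u_bb=int(u[2]),
        l_aa=int(l[0]), l_ab=int(l[1]), l_bb=int(l[2]),
    )
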