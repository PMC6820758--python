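"""Per-SNP threshold-defined case-control association scan.

Mirrors the real-data workflow: pick percentile thresholds T1 (controls)
and T2 (cases) on the trait, drop the individuals strictly between them,
test every SNP for case-control association, adjust with Bonferroni over
the SNPs actually tested, and optionally scan a grid of (T1, T2) pairs
summarizing each cell by its count of significant SNPs and smallest
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .assoc import collapse_table, fisher_exact, fisher_exact_2x3, hwe_exact, logistic_assoc
from .io import GenotypeMatrix, logger
from .sampling import CaseControlSample, ContingencyTable


@dataclass(frozen=True)
class ThresholdPair:
    """Percentile thresholds: controls at/below t1_pct, cases at/above t2_pct."""

    t1_pct: float
    t2_pct: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.t1_pct <= 50.0:
            raise ValueError(f"t1_pct must be in [1, 50], got {self.t1_pct}")
        if not 50.0 <= self.t2_pct <= 99.0:
            raise ValueError(f"t2_pct must be in [50, 99], got {self.t2_pct}")


@dataclass
class AssocRecord:
    """Per-SNP association result with QC annotations."""

    snp_id: str
    maf: float
    n_case: int
    n_control: int
    test_name: str
    p_value: float
    p_bonferroni: float
    significant: bool
    hwe_p: float
    separation_flag: bool = False
    monomorphic: bool = False


@dataclass
class ScanSummary:
    """One threshold-grid cell: significant-SNP count and smallest raw p."""

    t1_pct: float
    t2_pct: float
    n_significant: int
    min_p: float
    min_p_snp: str
    n_case: int
    n_control: int


def dichotomize_by_percentile(
    phenotypes: np.ndarray, thresholds: ThresholdPair
) -> CaseControlSample:
    """Label the trait tails by nearest-rank percentiles (inclusive boundary).

    Controls: trait <= the t1_pct-th percentile value; cases: trait >= the
    t2_pct-th percentile value.  Ties at a threshold shared by both sides
    go to the control side, so the sets stay disjoint even at a median
    split.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotypes must take at least two distinct values")
    y_sorted = np.sort(y)
    t1 = y_sorted[ceil(thresholds.t1_pct / 100.0 * n) - 1]
    t2 = y_sorted[ceil(thresholds.t2_pct / 100.0 * n) - 1]
    control = y <= t1
    case = (y >= t2) & ~control
    if not case.any() or not control.any():
        raise ValueError(
            f"thresholds ({thresholds.t1_pct}, {thresholds.t2_pct}) leave an "
            "empty case or control set"
        )
    return CaseControlSample(
        case_indices=np.flatnonzero(case),
        control_indices=np.flatnonzero(control),
        t1=float(t1),
        t2=float(t2),
    )


_PIPELINE_TESTS = (
    "fisher_dominant",
    "fisher_recessive",
    "fisher_allelic",
    "fisher_genotypic",
    "logistic",
)


def _test_one_snp(dosage: np.ndarray, labels: np.ndarray, test: str):
    """(p_value, test_name, separation_flag) for one complete-case SNP."""
    if test == "logistic":
        res = logistic_assoc(labels, dosage)
        return res.p_value, res.test_name, res.separation
    counts_case = np.bincount(dosage[labels == 1].astype(int), minlength=3)
    counts_ctrl = np.bincount(dosage[labels == 0].astype(int), minlength=3)
    table = ContingencyTable(
        u_aa=int(counts_case[0]), u_ab=int(counts_case[1]), u_bb=int(counts_case[2]),
        l_aa=int(counts_ctrl[0]), l_ab=int(counts_ctrl[1]), l_bb=int(counts_ctrl[2]),
    )
    if test == "fisher_genotypic":
        res = fisher_exact_2x3(table)
        return res.p_value, res.test_name, False
    model = test.removeprefix("fisher_")
    model = {"allelic": "multiplicative"}.get(model, model)
    res = fisher_exact(collapse_table(table, model))
    return res.p_value, f"{test}", False


def run_association(
    geno: GenotypeMatrix,
    sample: CaseControlSample,
    test: str = "fisher_dominant",
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[AssocRecord]:
    """Test every SNP for case-control association in the selected sample.

    Missing genotypes are dropped per SNP (complete case); the MAF is
    computed among the tested individuals; the HWE exact p-value uses all
    genotyped individuals in the matrix.  Bonferroni uses m = the number
    of SNPs actually tested (monomorphic SNPs are reported with p = 1 but
    excluded from m).
    """
    if test not in _PIPELINE_TESTS:
        raise ValueError(f"test must be one of {_PIPELINE_TESTS}, got {test!r}")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"correction must be 'bonferroni' or 'none', got {correction!r}")
    idx = np.concatenate([sample.case_indices, sample.control_indices])
    labels = np.r_[
        np.ones(len(sample.case_indices)), np.zeros(len(sample.control_indices))
    ]
    records: list[AssocRecord] = []
    for j, snp in enumerate(geno.snp_ids):
        col = geno.dosages[idx, j]
        keep = ~np.isnan(col)
        dosage = col[keep].astype(int)
        lab = labels[keep]
        n_case = int((lab == 1).sum())
        n_control = int((lab == 0).sum())
        full_col = geno.dosages[:, j]
        full_counts = np.bincount(full_col[~np.isnan(full_col)].astype(int), minlength=3)
        hwe_p = hwe_exact(int(full_counts[0]), int(full_counts[1]), int(full_counts[2])).p_value
        maf = float(dosage.mean() / 2.0) if len(dosage) else float("nan")
        if n_case == 0 or n_control == 0 or len(dosage) == 0 or np.ptp(dosage) == 0:
            records.append(
                AssocRecord(
                    snp_id=snp, maf=maf, n_case=n_case, n_control=n_control,
                    test_name=test, p_value=1.0, p_bonferroni=1.0,
                    significant=False, hwe_p=hwe_p, monomorphic=True,
                )
            )
            continue
        p, name, sep = _test_one_snp(dosage, lab, test)
        records.append(
            AssocRecord(
                snp_id=snp, maf=maf, n_case=n_case, n_control=n_control,
                test_name=name, p_value=p, p_bonferroni=p, significant=False,
                hwe_p=hwe_p, separation_flag=sep,
            )
        )
    m_tested = sum(1 for r in records if not r.monomorphic)
    for r in records:
        if r.monomorphic:
            continue
        if correction == "bonferroni":
            r.p_bonferroni = min(1.0, m_tested * r.p_value)
            r.significant = r.p_bonferroni <= alpha
        else:
            r.p_bonferroni = r.p_value
            r.significant = r.p_value <= alpha
    logger.info(
        "association: %d SNPs tested (%d monomorphic skipped), %d significant",
        m_tested, len(records) - m_tested, sum(r.significant for r in records),
    )
    return records


def records_to_frame(records: list[AssocRecord]) -> pd.DataFrame:
    cols = [
        "snp_id", "maf", "n_case", "n_control", "test_name", "p_value",
        "p_bonferroni", "significant", "hwe_p", "separation_flag", "monomorphic",
    ]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def threshold_scan(
    geno: GenotypeMatrix,
    phenotypes: np.ndarray,
    t1_grid,
    t2_grid,
    test: str = "fisher_dominant",
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[ScanSummary]:
    """Run the association scan on every (t1, t2) percentile pair.

    Cells whose case or control set is empty are skipped (logged) and the
    scan continues.
    """
    y = np.asarray(phenotypes, dtype=float)
    summaries: list[ScanSummary] = []
    for t1 in t1_grid:
        for t2 in t2_grid:
            try:
                sample = dichotomize_by_percentile(y, ThresholdPair(t1, t2))
            except ValueError as exc:
                logger.warning("scan cell (t1=%s, t2=%s) skipped: %s", t1, t2, exc)
                continue
            records = run_association(geno, sample, test=test, alpha=alpha,
                                      correction=correction)
            tested = [r for r in records if not r.monomorphic]
            if not tested:
                logger.warning("scan cell (t1=%s, t2=%s): no testable SNPs", t1, t2)
                continue
            best = min(tested, key=lambda r: r.p_value)
            summaries.append(
                ScanSummary(
                    t1_pct=float(t1), t2_pct=float(t2),
                    n_significant=sum(r.significant for r in tested),
                    min_p=best.p_value, min_p_snp=best.snp_id,
                    n_case=sample.n_cases, n_control=sample.n_controls,
                )
            )
    return summaries


def scan_to_frame(summaries: list[ScanSummary]) -> pd.DataFrame:
    cols = ["t1_pct", "t2_pct", "n_significant", "min_p", "min_p_snp",
            "n_case", "n_control"]
    return pd.DataFrame([[getattr(s, c) for c in cols] for s in summaries], columns=cols)


def pivot_scan(summaries: list[ScanSummary], value: str = "n_significant") -> pd.DataFrame:
    """Pivot a scan into the conventional matrix layout: control-threshold
    (t1) rows 10th..50th, case-threshold (t2) columns 90th..50th."""
    df = scan_to_frame(summaries)
    pivot = df.pivot(index="t1_pct", columns="t2_pct", values=value)
    return pivot.sort_index().sort_index(axis=1, ascending=False)
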