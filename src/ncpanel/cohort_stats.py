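"""Normality-gated two-group tests, correlations and stratified contrasts.

The inferential layer mirrors common practice for small targeted-panel
cohorts: each two-group contrast is tested with an unpaired Student t-test
when both groups pass a Shapiro-Wilk normality check, and with a two-sided
Mann-Whitney U-test otherwise; correlations between expression and clinical
variables use Pearson when both variables look normal and Spearman
otherwise.  No multiplicity adjustment is applied by default.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import BmiClass, PatientRecord
from .normalization import NormalizedMatrix
from .rcc_io import Group

__all__ = [
    "TestKind",
    "GroupComparisonResult",
    "CorrelationResult",
    "compare_groups",
    "compare_expression_all_genes",
    "correlate_expression_clinical",
    "stratified_comparison",
]

log = logging.getLogger(__name__)


class TestKind(str, enum.Enum):
    T_TEST = "t_test"
    MANN_WHITNEY = "mann_whitney"


class CorrMethod(str, enum.Enum):
    PEARSON = "pearson"
    SPEARMAN = "spearman"


@dataclass(frozen=True)
class GroupComparisonResult:
    gene: str
    groups: tuple[str, str]
    n_per_group: tuple[int, int]
    test_used: TestKind
    statistic: float
    p_value: float
    direction: str  # "group1_higher" | "group2_higher" | "none"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    clinical_variable: str
    method: CorrMethod
    coefficient: float
    p_value: float
    n: int


def _is_normalish(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # Shapiro undefined on constant input
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha_normality: float = 0.05,
    groups: tuple[str, str] = ("group1", "group2"),
    gene: str = "",
    welch: bool = False,
) -> GroupComparisonResult:
    """Two-group contrast with a Shapiro-Wilk gate.

    Both groups normal at ``alpha_normality`` -> unpaired two-sided Student
    t-test (Welch optional); otherwise two-sided Mann-Whitney U (exact for
    small tie-free samples, normal approximation with tie correction
    otherwise, as chosen by scipy's ``method="auto"``).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"need >=3 values per group, got {a.size} and {b.size}")

    if _is_normalish(a, alpha_normality) and _is_normalish(b, alpha_normality):
        res = stats.ttest_ind(a, b, equal_var=not welch)
        kind = TestKind.T_TEST
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        kind = TestKind.MANN_WHITNEY

    if a.mean() > b.mean():
        direction = "group1_higher"
    elif a.mean() < b.mean():
        direction = "group2_higher"
    else:
        direction = "none"
    return GroupComparisonResult(
        gene=gene,
        groups=groups,
        n_per_group=(a.size, b.size),
        test_used=kind,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
    )


def compare_expression_all_genes(
    norm: NormalizedMatrix, alpha_normality: float = 0.05, welch: bool = False
) -> list[GroupComparisonResult]:
    """Patients-vs-controls contrast for every detectable gene, unadjusted."""
    patients = norm.sample_ids_in(Group.PATIENT)
    controls = norm.sample_ids_in(Group.CONTROL)
    vals = norm.detectable_values()
    return [
        compare_groups(
            vals.loc[gene, patients],
            vals.loc[gene, controls],
            alpha_normality=alpha_normality,
            groups=("patient", "control"),
            gene=gene,
            welch=welch,
        )
        for gene in vals.index
    ]


_CLINICAL_GETTERS = {
    "fasting_glucose": lambda r: r.fasting_glucose_mg_dl,
    "hba1c": lambda r: r.hba1c_pct,
    "c_peptide": lambda r: r.c_peptide_ng_ml,
    "bmi": lambda r: r.bmi_kg_m2,
    "onset_age": lambda r: r.onset_age_years,
}


def correlate_expression_clinical(
    norm: NormalizedMatrix,
    patients: Iterable[PatientRecord],
    variables: Sequence[str] = ("fasting_glucose", "hba1c", "c_peptide"),
    alpha_normality: float = 0.05,
    min_pairs: int = 4,
) -> list[CorrelationResult]:
    """Correlate each detectable gene with each clinical variable.

    Pairwise-complete over patients with a non-missing clinical value;
    Pearson when both expression and the clinical variable pass the
    normality gate, Spearman otherwise.  Pairs with fewer than ``min_pairs``
    observations are skipped with a logged reason.
    """
    by_id = {r.case_id: r for r in patients}
    cols = [s for s in norm.sample_ids_in(Group.PATIENT) if s in by_id]
    vals = norm.detectable_values()
    out: list[CorrelationResult] = []
    for var in variables:
        getter = _CLINICAL_GETTERS.get(var)
        if getter is None:
            raise ValueError(f"unknown clinical variable {var!r}")
        clin = {s: getter(by_id[s]) for s in cols}
        keep = [s for s in cols if clin[s] is not None]
        for gene in vals.index:
            if len(keep) < min_pairs:
                log.info("skipping %s ~ %s: only %d paired values", gene, var, len(keep))
                continue
            x = vals.loc[gene, keep].to_numpy(dtype=float)
            y = np.array([clin[s] for s in keep], dtype=float)
            if _is_normalish(x, alpha_normality) and _is_normalish(y, alpha_normality):
                r = stats.pearsonr(x, y)
                method = CorrMethod.PEARSON
            else:
                r = stats.spearmanr(x, y)
                method = CorrMethod.SPEARMAN
            out.append(
                CorrelationResult(
                    gene=gene,
                    clinical_variable=var,
                    method=method,
                    coefficient=float(r.statistic),
                    p_value=float(r.pvalue),
                    n=len(keep),
                )
            )
    return out


def stratified_comparison(
    norm: NormalizedMatrix,
    patients: Iterable[PatientRecord],
    stratifier: str,
    alpha_normality: float = 0.05,
    min_per_stratum: int = 3,
) -> list[GroupComparisonResult]:
    """Within-patient contrasts by clinical stratum, per detectable gene.

    ``onset_age_25`` splits patients at diabetes onset <= 25 vs > 25 years;
    ``bmi_class`` contrasts obese (BMI >= 30) against normal-weight
    (18.5 <= BMI < 25) patients, leaving the overweight stratum out of the
    contrast.  Strata smaller than ``min_per_stratum`` are skipped with a
    logged reason.
    """
    by_id = {r.case_id: r for r in patients}
    cols = [s for s in norm.sample_ids_in(Group.PATIENT) if s in by_id]

    if stratifier == "onset_age_25":
        g1 = [s for s in cols if by_id[s].onset_age_years is not None and by_id[s].onset_age_years <= 25]
        g2 = [s for s in cols if by_id[s].onset_age_years is not None and by_id[s].onset_age_years > 25]
        labels = ("onset<=25", "onset>25")
    elif stratifier == "bmi_class":
        g1 = [s for s in cols if by_id[s].bmi_class is BmiClass.OBESE]
        g2 = [s for s in cols if by_id[s].bmi_class is BmiClass.NORMAL]
        labels = ("obese", "normal_weight")
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")

    if len(g1) < min_per_stratum or len(g2) < min_per_stratum:
        log.info(
            "stratifier %s skipped: strata sizes %d vs %d below %d",
            stratifier, len(g1), len(g2), min_per_stratum,
        )
        return []
    vals = norm.detectable_values()
    return [
        compare_groups(
            vals.loc[gene, g1],
            vals.loc[gene, g2],
            alpha_normality=alpha_normality,
            groups=labels,
            gene=gene,
        )
        for gene in vals.index
    ]


def results_to_frame(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    """Flatten contrast results to a TSV-ready frame, one row per gene x contrast."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "group1": [r.groups[0] for r in results],
            "group2": [r.groups[1] for r in results],
            "n1": [r.n_per_group[0] for r in results],
            "n2": [r.n_per_group[1] for r in results],
            "test_used": [r.test_used.value for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )
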