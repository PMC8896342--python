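"""Normality-gated two-group tests, correlations and stratified contrasts."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from ncpanel.clinical import PatientRecord, Sex
from ncpanel.cohort_stats import TestKind as GateKind
from ncpanel.cohort_stats import (
    CorrMethod,
    compare_expression_all_genes,
    compare_groups,
    correlate_expression_clinical,
    stratified_comparison,
)
from ncpanel.normalization import normalize_cohort
from ncpanel.synthetic_data import GeneratorConfig, generate_cohort


def test_identical_groups_not_significant():
    r = compare_groups([1, 2, 3], [1, 2, 3])
    assert r.p_value == pytest.approx(1.0)
    assert r.direction == "none"


def test_separated_groups_detected_with_direction():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 8)
    b = rng.normal(5, 1, 19)  # 5 SD shift
    r = compare_groups(a, b, groups=("control", "patient"))
    assert r.p_value < 0.05
    assert r.direction == "group2_higher"


def test_small_groups_rejected():
    with pytest.raises(ValueError, match=">=3"):
        compare_groups([1, 2], [1, 2, 3])


def test_gate_agrees_with_independent_oracle_over_random_datasets():
    """The branch taken (t vs Mann-Whitney) must equal an oracle that applies
    the same Shapiro-Wilk rule directly, over 200 seeded datasets."""
    rng = np.random.default_rng(2024)
    agree = 0
    for _ in range(200):
        n1, n2 = rng.integers(3, 25, size=2)
        if rng.random() < 0.5:
            a, b = rng.normal(0, 1, n1), rng.normal(0, 1, n2)
        else:
            a, b = rng.lognormal(0, 1.2, n1), rng.lognormal(0, 1.2, n2)
        r = compare_groups(a, b)
        normal = stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        expected = GateKind.T_TEST if normal else GateKind.MANN_WHITNEY
        agree += r.test_used is expected
    assert agree == 200


def test_mann_whitney_branch_monotone_invariant():
    rng = np.random.default_rng(9)
    a = rng.lognormal(0, 1.5, 12)
    b = rng.lognormal(0.5, 1.5, 15)
    r1 = compare_groups(a, b)
    r2 = compare_groups(np.exp(a), np.exp(b))  # strictly monotone transform
    assert r1.test_used is GateKind.MANN_WHITNEY
    assert r2.test_used is GateKind.MANN_WHITNEY
    assert r1.p_value == pytest.approx(r2.p_value)


def test_gated_test_type_one_error_in_band():
    """Null normal data, n=8 vs 19, 2000 replicates: rejection rate at
    nominal alpha 0.05 must land in [0.035, 0.065]."""
    rng = np.random.default_rng(7)
    rej = sum(
        compare_groups(rng.normal(0, 1, 8), rng.normal(0, 1, 19)).p_value < 0.05
        for _ in range(2000)
    )
    assert 0.035 <= rej / 2000 <= 0.065


class TestExpressionContrasts:
    def test_planted_group_shift_recovered(self):
        cfg = GeneratorConfig(seed=21)
        _, _, truth = generate_cohort(cfg)
        gene = sorted(truth.detectable)[0]
        cohort, _, _ = generate_cohort(
            dataclasses.replace(cfg, group_shifts=((gene, -1.5),))
        )
        norm = normalize_cohort(cohort)
        results = {r.gene: r for r in compare_expression_all_genes(norm)}
        assert len(results) == len(norm.detectable_genes)
        r = results[gene]
        assert r.p_value < 0.05
        assert r.groups == ("patient", "control")
        assert r.direction == "group2_higher"  # patients lower

    def test_one_result_per_detectable_gene(self, default_cohort):
        cohort, _, _ = default_cohort
        norm = normalize_cohort(cohort)
        results = compare_expression_all_genes(norm)
        assert sorted(r.gene for r in results) == sorted(norm.detectable_genes)


class TestCorrelations:
    def test_perfect_linear_pair(self, default_cohort):
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        gene = norm.detectable_genes[0]
        # make HbA1c exactly linear in that gene's expression
        vals = norm.detectable_values()
        rigged = [
            dataclasses.replace(
                r, hba1c_pct=float(5 + 1e-3 * vals.loc[gene, r.case_id])
            )
            for r in patients
        ]
        res = correlate_expression_clinical(norm, rigged, variables=("hba1c",))
        by_gene = {c.gene: c for c in res}
        assert by_gene[gene].coefficient == pytest.approx(1.0)

    def test_spearman_on_monotone_nonlinear_pair(self, default_cohort):
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        gene = norm.detectable_genes[0]
        vals = norm.detectable_values()
        # heavy-tailed monotone transform fails the normality gate
        rigged = [
            dataclasses.replace(
                r, c_peptide_ng_ml=float(np.exp(vals.loc[gene, r.case_id] / vals.loc[gene].std()))
            )
            for r in patients
        ]
        res = correlate_expression_clinical(norm, rigged, variables=("c_peptide",))
        c = {x.gene: x for x in res}[gene]
        assert c.method is CorrMethod.SPEARMAN
        assert c.coefficient == pytest.approx(1.0)

    def test_spearman_branch_equals_pearson_on_ranks(self, default_cohort):
        """Rank-correlation oracle: the nonparametric branch's coefficient
        must equal a Pearson correlation computed on ranks by hand."""
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        gene = norm.detectable_genes[2]
        vals = norm.detectable_values()
        rng = np.random.default_rng(13)
        rigged = [
            dataclasses.replace(r, hba1c_pct=float(np.exp(rng.normal(0, 2))))
            for r in patients
        ]
        res = correlate_expression_clinical(norm, rigged, variables=("hba1c",))
        c = {x.gene: x for x in res}[gene]
        assert c.method is CorrMethod.SPEARMAN
        x = vals.loc[gene, [r.case_id for r in rigged]].to_numpy()
        y = np.array([r.hba1c_pct for r in rigged])
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert c.coefficient == pytest.approx(oracle)

    def test_too_few_pairs_skipped(self, default_cohort):
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        rigged = [dataclasses.replace(r, hba1c_pct=None) for r in patients[:-2]] + list(
            patients[-2:]
        )
        res = correlate_expression_clinical(norm, rigged, variables=("hba1c",))
        assert res == []

    def test_coefficients_bounded(self, default_cohort):
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        res = correlate_expression_clinical(norm, patients)
        assert res and all(abs(c.coefficient) <= 1.0 for c in res)


class TestStratified:
    def test_planted_early_onset_shift_recovered(self):
        cfg = GeneratorConfig(seed=33)
        _, _, truth = generate_cohort(cfg)
        gene = sorted(truth.detectable)[1]
        cohort, patients, _ = generate_cohort(
            dataclasses.replace(cfg, stratum_shifts=((gene, "early_onset", 1.5),))
        )
        norm = normalize_cohort(cohort)
        res = {r.gene: r for r in stratified_comparison(norm, patients, "onset_age_25")}
        r = res[gene]
        assert r.groups == ("onset<=25", "onset>25")
        assert r.p_value < 0.05
        assert r.direction == "group1_higher"

    def test_single_stratum_skipped(self, default_cohort):
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        all_late = [dataclasses.replace(r, onset_age_years=40, age_years=60) for r in patients]
        assert stratified_comparison(norm, all_late, "onset_age_25") == []

    def test_unknown_stratifier(self, default_cohort):
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        with pytest.raises(ValueError, match="sex"):
            stratified_comparison(norm, patients, "sex")

    def test_patient_order_invariance(self, default_cohort):
        cohort, patients, _ = default_cohort
        norm = normalize_cohort(cohort)
        res1 = stratified_comparison(norm, patients, "bmi_class")
        res2 = stratified_comparison(norm, list(reversed(patients)), "bmi_class")
        assert res1 == res2
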