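"""End-to-end orchestration: raw cohort -> normalized matrix -> z-score calls
-> group statistics -> clinical summaries, with a machine-readable run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .clinical import PatientRecord, cohort_summary, read_patient_table
from .cohort_stats import (
    compare_expression_all_genes,
    correlate_expression_clinical,
    results_to_frame,
    stratified_comparison,
)
from .config import PipelineConfig
from .normalization import NormalizationError, normalize_cohort
from .outlier_calls import (
    compute_zscores,
    control_reference,
    export_zscore_heatmap_table,
    summarize_calls,
)
from .rcc_io import CohortMatrix, Group, read_count_matrix_tsv
from .synthetic_data import load_fixture_bundle

__all__ = ["PipelineError", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunReport:
    """Everything needed to re-run identically plus a manifest of outputs."""

    config: dict
    n_samples: int
    n_controls: int
    n_patients: int
    detectable_genes: list[str]
    reference_genes: list[str]
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True), encoding="utf-8"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_input(input_path: Path, metadata: Path | None) -> tuple[CohortMatrix, list[PatientRecord]]:
    if input_path.is_dir():
        cohort, patients, _ = load_fixture_bundle(input_path)
        return cohort, patients
    cohort = read_count_matrix_tsv(input_path, metadata)
    return cohort, []


def run_pipeline(
    input_path: str | Path,
    out_dir: str | Path,
    metadata: str | Path | None = None,
    clinical_table: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run the full analysis and write all result tables under ``out_dir``.

    ``input_path`` is either a directory of RCC files with a ``samples.tsv``
    sidecar or a TSV count matrix (with ``metadata`` as its sidecar).
    ``clinical_table`` (patients TSV) enables correlations, stratified
    contrasts and the clinical cohort summary; a bundle's ``patients.tsv``
    is picked up automatically.
    """
    cfg = config or PipelineConfig()
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings: list[str] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("read_input"):
        cohort, patients = _load_input(input_path, Path(metadata) if metadata else None)
        if clinical_table is not None:
            patients = read_patient_table(clinical_table)
        controls = cohort.sample_ids_in(Group.CONTROL)
        patient_samples = cohort.sample_ids_in(Group.PATIENT)
        if not controls:
            raise ValueError("no control group in input")
        if not patient_samples:
            raise ValueError("no patient samples in input")

    with stage("normalize"):
        norm = normalize_cohort(cohort, cfg)
        norm.values.round(6).to_csv(out_dir / "normalized_matrix.tsv", sep="\t")
        provenance = {
            "background_thresholds": norm.background.per_sample_threshold,
            "positive_factors": norm.factors.positive_factor,
            "content_factors": norm.factors.content_factor,
            "reference_genes": norm.factors.reference_genes,
            "genorm_m_values": norm.genorm.m_values,
            "genorm_v_curve": norm.genorm.v_curve,
            "genorm_n_selected": norm.genorm.n_selected,
            "detectable": norm.detectable,
        }
        (out_dir / "normalization_provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True), encoding="utf-8"
        )
        if not norm.detectable_genes:
            raise ValueError("no detectable endogenous genes above background")

    with stage("zscores"):
        ref = control_reference(norm)
        table = compute_zscores(norm, ref)
        export_zscore_heatmap_table(table, out_dir / "zscores.tsv")
        summary = summarize_calls(table)
        (out_dir / "call_summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )

    with stage("group_stats"):
        results = compare_expression_all_genes(norm, cfg.alpha_normality, cfg.welch)
        results_to_frame(results).to_csv(
            out_dir / "group_comparisons.tsv", sep="\t", index=False
        )
        if patients:
            corr = correlate_expression_clinical(
                norm, patients, alpha_normality=cfg.alpha_normality
            )
            pd.DataFrame(
                {
                    "gene": [c.gene for c in corr],
                    "clinical_variable": [c.clinical_variable for c in corr],
                    "method": [c.method.value for c in corr],
                    "coefficient": [c.coefficient for c in corr],
                    "p_value": [c.p_value for c in corr],
                    "n": [c.n for c in corr],
                }
            ).to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
            for strat in ("onset_age_25", "bmi_class"):
                res = stratified_comparison(norm, patients, strat, cfg.alpha_normality)
                if res:
                    results_to_frame(res).to_csv(
                        out_dir / f"stratified_{strat}.tsv", sep="\t", index=False
                    )
                else:
                    warnings.append(f"stratified contrast {strat} skipped (small strata)")
        else:
            warnings.append("no clinical table: correlations and stratified contrasts skipped")

    with stage("clinical_summary"):
        if patients:
            (out_dir / "cohort_summary.json").write_text(
                json.dumps(cohort_summary(patients), indent=2, sort_keys=True),
                encoding="utf-8",
            )

    report = RunReport(
        config=cfg.to_dict(),
        n_samples=len(cohort.samples),
        n_controls=len(controls),
        n_patients=len(patient_samples),
        detectable_genes=norm.detectable_genes,
        reference_genes=norm.factors.reference_genes,
        stage_seconds=timings,
        warnings=warnings,
    )
    for f in sorted(out_dir.iterdir()):
        if f.is_file() and f.name != "run_report.json":
            report.outputs[f.name] = _sha256(f)
    report.to_json(out_dir / "run_report.json")
    return report
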