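"""Control-referenced z-score outlier calling.

Each patient's normalized count ``x`` for a detectable gene is scored
against the control cohort: ``z = (x - mu) / sigma`` with ``mu`` and
``sigma`` the mean and sample SD of the controls' normalized counts.
``z >= 2`` is called overexpression (``high``), ``z <= -2`` low expression
(``low``); anything between is ``normal``.  No multiple-testing correction
is applied across genes or patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .normalization import NormalizedMatrix
from .rcc_io import Group

__all__ = [
    "ControlReference",
    "ZScoreTable",
    "CallSummary",
    "control_reference",
    "compute_zscores",
    "summarize_calls",
    "export_zscore_heatmap_table",
    "zscore_table_from_entries",
    "example_zscore_entries",
]

log = logging.getLogger(__name__)

Z_CALL_THRESHOLD = 2.0


@dataclass(frozen=True)
class ControlReference:
    """Per-gene control mean and sample SD (n-1), detectable genes only."""

    mu: pd.Series
    sigma: pd.Series
    n_controls: int


@dataclass
class ZScoreTable:
    """z-scores for patients x detectable genes, with categorical calls.

    ``z`` is indexed by gene (rows, alphabetical) with patient columns in
    cohort order.
    """

    z: pd.DataFrame

    @property
    def calls(self) -> pd.DataFrame:
        return self.z.map(call_for_z)

    @property
    def patients(self) -> list[str]:
        return list(self.z.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)


def call_for_z(z: float, threshold: float = Z_CALL_THRESHOLD) -> str:
    if z >= threshold:
        return "high"
    if z <= -threshold:
        return "low"
    return "normal"


def control_reference(norm: NormalizedMatrix) -> ControlReference:
    """Per-gene mean/SD of the control samples' normalized counts."""
    controls = norm.sample_ids_in(Group.CONTROL)
    if len(controls) < 2:
        raise ValueError(f"need >=2 control samples, got {len(controls)}")
    vals = norm.detectable_values()[controls]
    mu = vals.mean(axis=1)
    sigma = vals.std(axis=1, ddof=1)
    degenerate = sigma.index[sigma == 0].tolist()
    if degenerate:
        raise ValueError(
            f"control SD is zero for gene(s) {degenerate}; z-scores undefined"
        )
    return ControlReference(mu=mu, sigma=sigma, n_controls=len(controls))


def compute_zscores(
    norm: NormalizedMatrix,
    ref: ControlReference,
    samples: Sequence[str] | None = None,
) -> ZScoreTable:
    """z = (x - mu)/sigma for each patient x detectable gene.

    ``samples`` defaults to the patient columns; pass the control ids to
    score controls against their own reference (self-standardization).
    """
    if samples is None:
        samples = norm.sample_ids_in(Group.PATIENT)
    vals = norm.detectable_values()[list(samples)]
    z = vals.sub(ref.mu, axis=0).div(ref.sigma, axis=0)
    return ZScoreTable(z=z.sort_index())


@dataclass(frozen=True)
class CallSummary:
    per_patient_counts: dict[str, int]
    n_patients: int
    patients_flagged: list[str]
    fraction_flagged: float
    multi_gene_patients: list[str]
    per_gene_calls: dict[str, dict[str, list[str]]]

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "patients_flagged": self.patients_flagged,
            "n_flagged": len(self.patients_flagged),
            "fraction_flagged": self.fraction_flagged,
            "multi_gene_patients": self.multi_gene_patients,
            "per_patient_counts": self.per_patient_counts,
            "per_gene_calls": self.per_gene_calls,
        }


def summarize_calls(table: ZScoreTable) -> CallSummary:
    """Cohort-level view of the extreme-expression calls.

    Reports the per-patient count of non-normal calls, which patients carry
    at least one call (and the fraction over all patients in the table),
    which carry calls in more than one gene, and per-gene low/high patient
    lists (the numeric content of a call heatmap).
    """
    if table.z.empty:
        raise ValueError("summarize_calls: empty z-score table")
    calls = table.calls
    nonnormal = calls != "normal"
    per_patient = nonnormal.sum(axis=0).astype(int)
    flagged = [p for p in table.patients if per_patient[p] >= 1]
    multi = [p for p in table.patients if per_patient[p] > 1]
    per_gene = {
        gene: {
            "low": [p for p in table.patients if calls.loc[gene, p] == "low"],
            "high": [p for p in table.patients if calls.loc[gene, p] == "high"],
        }
        for gene in table.genes
    }
    n = len(table.patients)
    return CallSummary(
        per_patient_counts={p: int(per_patient[p]) for p in table.patients},
        n_patients=n,
        patients_flagged=flagged,
        fraction_flagged=len(flagged) / n,
        multi_gene_patients=multi,
        per_gene_calls=per_gene,
    )


def export_zscore_heatmap_table(table: ZScoreTable, path: str | Path) -> None:
    """Write z-scores and calls as a TSV: genes as rows (alphabetical),
    patients as columns in cohort order, one ``<patient>.call`` column per
    patient after the z columns."""
    z = table.z.sort_index()
    calls = z.map(call_for_z)
    out = pd.concat([z, calls.add_suffix(".call", axis=1)], axis=1)
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6g")


def zscore_table_from_entries(
    entries: Iterable[tuple[str, str, float]],
    patients: Sequence[str],
    genes: Sequence[str],
    fill: float = 0.0,
) -> ZScoreTable:
    """Build a dense z-score table from sparse (patient, gene, z) entries.

    Cells without an entry get ``fill`` (0 = unremarkable).  Entries whose
    patient or gene is not in the given lists are dropped with a warning —
    this is how un-attributable rows in a published call list are excluded.
    """
    z = pd.DataFrame(fill, index=sorted(genes), columns=list(patients), dtype=float)
    for patient, gene, value in entries:
        if patient not in z.columns:
            log.warning("dropping z entry for unknown patient %r (gene %s)", patient, gene)
            continue
        if gene not in z.index:
            log.warning("dropping z entry for unknown gene %r (patient %s)", gene, patient)
            continue
        z.loc[gene, patient] = float(value)
    return ZScoreTable(z=z)


def example_zscore_entries() -> list[tuple[str, str, float]]:
    """The bundled extreme z-score list of the 19-patient suspected-MODY cohort.

    Sparse (patient, gene, z) entries as reported for the worked-example
    cohort; includes one entry whose patient label matches no enrolled case,
    which :func:`zscore_table_from_entries` drops.
    """
    with resources.as_file(
        resources.files("ncpanel.data").joinpath("mody_cohort_zscores.tsv")
    ) as p:
        lines = Path(p).read_text(encoding="utf-8").splitlines()
    entries = []
    for line in lines[1:]:
        if line.strip():
            patient, gene, z = line.split("\t")
            entries.append((patient, gene, float(z)))
    return entries
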