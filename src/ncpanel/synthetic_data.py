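"""Seeded synthetic cohorts with known ground truth.

Emulates the data a targeted blood expression panel produces for a
suspected-MODY study: 8 healthy controls and 19 patients measured on a
19-gene endogenous panel with 8 housekeeping candidates, a shared
positive-control titration scaled by per-sample lane efficiency, low-count
negative probes, genes expressed below background in blood, housekeeping
candidates of varying stability, and optional planted signals (per-cell
expression outliers, group shifts, stratum shifts).  Every random draw comes
from one seeded generator in a fixed order, so the same seed reproduces the
cohort byte for byte — and planting outliers perturbs only the planted
cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clinical import PatientRecord, Sex, Therapy, read_patient_table, write_patient_table
from .rcc_io import (
    CodeClass,
    CohortMatrix,
    Group,
    ProbeRecord,
    SampleRecord,
    assemble_cohort,
    read_rcc,
    write_rcc,
)

__all__ = [
    "PANEL_GENES",
    "HOUSEKEEPING_GENES",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_cohort",
    "write_fixture_bundle",
    "load_fixture_bundle",
]

# 19 MODY-associated target genes of the diagnostic panel
PANEL_GENES = (
    "ABCC8", "APPL1", "BLK", "CEL", "GCK", "GLIS3", "HADH", "HNF1A", "HNF1B",
    "HNF4A", "IER3IP1", "INS", "KCNJ11", "KLF11", "NEUROD1", "PAX4", "PDX1",
    "PLAGL1", "UCP2",
)

# 8 candidate reference genes carried on the panel
HOUSEKEEPING_GENES = ("ABCF1", "ALAS1", "EEF1G", "G6PD", "GAPDH", "GUSB", "HPRT1", "TBP")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped generator settings.

    Defaults mirror the emulated study design: 8 controls vs 19 patients,
    12 of 19 endogenous genes below background (7 detectable in blood),
    3 of 8 housekeeping candidates unstable, a 6-level 4-fold positive
    titration, 8 negative probes with a Poisson(10) floor, lane efficiency
    spread 0.3 on the log2 scale, RNA-content spread 0.2 log2, biological
    CV 20% and positive-control technical CV 5%.
    """

    n_controls: int = 8
    n_patients: int = 19
    endogenous_genes: tuple[str, ...] = PANEL_GENES
    housekeeping_genes: tuple[str, ...] = HOUSEKEEPING_GENES
    n_undetectable: int = 12
    n_unstable_hk: int = 3
    n_positive_probes: int = 6
    n_negative_probes: int = 8
    positive_top_count: float = 20000.0
    positive_fold: float = 4.0
    positive_cv: float = 0.05
    background_lambda: float = 10.0
    lane_efficiency_sd_log2: float = 0.3
    content_sd_log2: float = 0.2
    biological_cv: float = 0.2
    unstable_hk_sd_log2: float = 0.5
    baseline_log2_range: tuple[float, float] = (8.0, 12.0)
    hk_baseline_log2_range: tuple[float, float] = (9.0, 13.0)
    outlier_cells: tuple[tuple[str, str, float], ...] = ()  # (patient, gene, log2 FC)
    group_shifts: tuple[tuple[str, float], ...] = ()  # (gene, log2 FC) patients vs controls
    stratum_shifts: tuple[tuple[str, str, float], ...] = ()  # (gene, stratum, log2 FC)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 1:
            raise ValueError("need >=2 controls and >=1 patient")
        if not 0 <= self.n_undetectable < len(self.endogenous_genes):
            raise ValueError("n_undetectable must be < number of endogenous genes")
        if not 0 <= self.n_unstable_hk <= len(self.housekeeping_genes):
            raise ValueError("n_unstable_hk out of range")
        if self.n_positive_probes < 2 or self.n_negative_probes < 2:
            raise ValueError("need >=2 positive and >=2 negative probes")
        for p in ("positive_top_count", "positive_fold", "background_lambda"):
            if getattr(self, p) <= 0:
                raise ValueError(f"{p} must be positive")
        patient_ids = {f"M{i + 1}" for i in range(self.n_patients)}
        genes = set(self.endogenous_genes)
        for patient, gene, _ in self.outlier_cells:
            if patient not in patient_ids:
                raise ValueError(f"outlier cell names unknown patient {patient!r}")
            if gene not in genes:
                raise ValueError(f"outlier cell names unknown gene {gene!r}")
        for gene, stratum, _ in self.stratum_shifts:
            if gene not in genes:
                raise ValueError(f"stratum shift names unknown gene {gene!r}")
            if stratum not in ("early_onset", "obese"):
                raise ValueError(f"unknown stratum {stratum!r}")

    @property
    def control_ids(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_controls)]

    @property
    def patient_ids(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_patients)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth serialized alongside each synthetic cohort."""

    lane_efficiency: dict[str, float]
    content_factor: dict[str, float]
    undetectable: frozenset[str]
    unstable_hk: frozenset[str]
    outlier_cells: dict[tuple[str, str], float]
    baseline_expression: dict[str, float]

    @property
    def detectable(self) -> frozenset[str]:
        return frozenset(self.baseline_expression) - self.undetectable

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lane_efficiency": self.lane_efficiency,
            "content_factor": self.content_factor,
            "undetectable": sorted(self.undetectable),
            "unstable_hk": sorted(self.unstable_hk),
            "outlier_cells": [
                {"patient": p, "gene": g, "log2_fold_change": fc}
                for (p, g), fc in sorted(self.outlier_cells.items())
            ],
            "baseline_expression": self.baseline_expression,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            lane_efficiency=payload["lane_efficiency"],
            content_factor=payload["content_factor"],
            undetectable=frozenset(payload["undetectable"]),
            unstable_hk=frozenset(payload["unstable_hk"]),
            outlier_cells={
                (c["patient"], c["gene"]): c["log2_fold_change"]
                for c in payload["outlier_cells"]
            },
            baseline_expression=payload["baseline_expression"],
        )


def _log2_noise_sd(cv: float) -> float:
    return math.log2(1.0 + cv)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[CohortMatrix, list[PatientRecord], SyntheticTruth]:
    """Draw one synthetic cohort.

    Counts: negatives ~ Poisson(lambda_bg); positives = lane efficiency x
    4-fold titration x log-normal technical noise; housekeeping and
    detectable endogenous genes = lane efficiency x RNA content x gene
    baseline x log-normal biological noise (unstable housekeeping genes get
    extra per-sample jitter); undetectable genes ~ Poisson(lambda_bg); all
    rounded to integers.  Planted shifts multiply the mean of the affected
    patient cells by 2**fold_change before the noise draw, so two configs
    differing only in planted signals share every other count.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    endo = list(cfg.endogenous_genes)
    hk = list(cfg.housekeeping_genes)
    sample_ids = cfg.control_ids + cfg.patient_ids
    n_samples = len(sample_ids)

    undetectable = frozenset(
        rng.choice(sorted(endo), size=cfg.n_undetectable, replace=False).tolist()
    )
    unstable = frozenset(
        rng.choice(sorted(hk), size=cfg.n_unstable_hk, replace=False).tolist()
    )
    endo_baseline = 2.0 ** rng.uniform(*cfg.baseline_log2_range, size=len(endo))
    hk_baseline = 2.0 ** rng.uniform(*cfg.hk_baseline_log2_range, size=len(hk))
    lane_eff = 2.0 ** rng.normal(0.0, cfg.lane_efficiency_sd_log2, size=n_samples)
    content = 2.0 ** rng.normal(0.0, cfg.content_sd_log2, size=n_samples)

    sd_bio = _log2_noise_sd(cfg.biological_cv)
    sd_pos = _log2_noise_sd(cfg.positive_cv)
    pos_noise = 2.0 ** rng.normal(0.0, sd_pos, size=(cfg.n_positive_probes, n_samples))
    neg_counts = rng.poisson(cfg.background_lambda, size=(cfg.n_negative_probes, n_samples))
    hk_noise = 2.0 ** rng.normal(0.0, sd_bio, size=(len(hk), n_samples))
    hk_jitter = 2.0 ** rng.normal(0.0, cfg.unstable_hk_sd_log2, size=(len(hk), n_samples))
    endo_noise = 2.0 ** rng.normal(0.0, sd_bio, size=(len(endo), n_samples))
    endo_bg = rng.poisson(cfg.background_lambda, size=(len(endo), n_samples))

    patients = _draw_clinical(cfg, rng)
    by_id = {r.case_id: r for r in patients}
    early = {r.case_id for r in patients if r.onset_age_years is not None and r.onset_age_years <= 25}
    obese = {r.case_id for r in patients if r.bmi_kg_m2 is not None and r.bmi_kg_m2 >= 30}
    group_shift = dict(cfg.group_shifts)
    outliers = {(p, g): fc for p, g, fc in cfg.outlier_cells}

    pos_levels = cfg.positive_top_count / cfg.positive_fold ** np.arange(cfg.n_positive_probes)
    pos_names = [f"POS_{chr(ord('A') + i)}" for i in range(cfg.n_positive_probes)]
    neg_names = [f"NEG_{chr(ord('A') + i)}" for i in range(cfg.n_negative_probes)]

    samples: list[SampleRecord] = []
    for j, sid in enumerate(sample_ids):
        is_patient = sid.startswith("M")
        probes: list[ProbeRecord] = []
        for i, name in enumerate(pos_names):
            c = max(1, round(lane_eff[j] * pos_levels[i] * pos_noise[i, j]))
            probes.append(ProbeRecord(CodeClass.POSITIVE, name, f"ERCC_{i:05d}.1", c))
        for i, name in enumerate(neg_names):
            probes.append(ProbeRecord(CodeClass.NEGATIVE, name, "", int(neg_counts[i, j])))
        for i, gene in enumerate(endo):
            if gene in undetectable:
                c = int(endo_bg[i, j])
            else:
                mean = endo_baseline[i]
                if is_patient:
                    mean *= 2.0 ** group_shift.get(gene, 0.0)
                    for g2, stratum, fc in cfg.stratum_shifts:
                        if g2 == gene and (
                            (stratum == "early_onset" and sid in early)
                            or (stratum == "obese" and sid in obese)
                        ):
                            mean *= 2.0 ** fc
                    if (sid, gene) in outliers:
                        mean *= 2.0 ** outliers[(sid, gene)]
                c = max(1, round(lane_eff[j] * content[j] * mean * endo_noise[i, j]))
            probes.append(ProbeRecord(CodeClass.ENDOGENOUS, gene, f"NM_{i:06d}.1", int(c)))
        for i, gene in enumerate(hk):
            noise = hk_noise[i, j] * (hk_jitter[i, j] if gene in unstable else 1.0)
            c = max(1, round(lane_eff[j] * content[j] * hk_baseline[i] * noise))
            probes.append(ProbeRecord(CodeClass.HOUSEKEEPING, gene, f"NM_{i + 500:06d}.1", int(c)))
        samples.append(
            SampleRecord(
                sample_id=sid,
                group=Group.PATIENT if is_patient else Group.CONTROL,
                probes=probes,
            )
        )

    truth = SyntheticTruth(
        lane_efficiency={sid: float(e) for sid, e in zip(sample_ids, lane_eff)},
        content_factor={sid: float(c) for sid, c in zip(sample_ids, content)},
        undetectable=undetectable,
        unstable_hk=unstable,
        outlier_cells=outliers,
        baseline_expression={g: float(b) for g, b in zip(endo, endo_baseline)},
    )
    return assemble_cohort(samples), patients, truth


_THERAPY_PROBS = (
    (Therapy.INSULIN, 0.5),
    (Therapy.METFORMIN, 0.4),
    (Therapy.DPP4I, 0.2),
    (Therapy.SGLT2I, 0.15),
    (Therapy.GLP1RA, 0.1),
)


def _draw_clinical(cfg: GeneratorConfig, rng: np.random.Generator) -> list[PatientRecord]:
    """Clinical rows with onset ages spanning the 25-year cut and BMIs
    spanning the WHO classes, so stratified contrasts always have members."""
    records = []
    for i, sid in enumerate(cfg.patient_ids):
        onset = int(rng.integers(12, 46))
        age = onset + int(rng.integers(5, 26))
        bmi = float(np.clip(np.round(rng.normal(27.0, 5.0), 1), 17.0, 42.0))
        hba1c = float(np.clip(np.round(rng.normal(7.3, 1.2), 1), 5.0, 12.0))
        glucose = float(np.clip(np.round(rng.normal(130.0, 25.0)), 70.0, 250.0))
        c_pep = float(np.clip(np.round(rng.lognormal(0.0, 0.4), 2), 0.2, 4.0))
        sex = Sex.M if rng.random() < 0.5 else Sex.F
        therapies = frozenset(t for t, p in _THERAPY_PROBS if rng.random() < p)
        records.append(
            PatientRecord(
                case_id=sid,
                age_years=age,
                sex=sex,
                onset_age_years=onset,
                family_history_dm_n=int(rng.integers(0, 8)),
                bmi_kg_m2=bmi,
                hba1c_pct=hba1c,
                fasting_glucose_mg_dl=glucose,
                c_peptide_ng_ml=c_pep,
                secondary_complications=bool(rng.random() < 0.2),
                therapies=therapies,
            )
        )
    return records


def write_fixture_bundle(
    cohort: CohortMatrix,
    patients: Sequence[PatientRecord],
    truth: SyntheticTruth,
    directory: str | Path,
    overwrite: bool = False,
) -> None:
    """Write one RCC file per sample plus samples.tsv, patients.tsv, truth.json."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    for j, sample in enumerate(cohort.samples):
        probes = [
            ProbeRecord(p.code_class, p.name, p.accession, int(cohort.counts[i, j]))
            for i, p in enumerate(cohort.probes)
        ]
        write_rcc(
            SampleRecord(sample_id=sample.sample_id, group=sample.group, probes=probes),
            directory / f"{sample.sample_id}.RCC",
        )
    with (directory / "samples.tsv").open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for s in cohort.samples:
            fh.write(f"{s.sample_id}\t{s.group.value}\n")
    write_patient_table(patients, directory / "patients.tsv")
    truth.to_json(directory / "truth.json")


def load_fixture_bundle(
    directory: str | Path,
) -> tuple[CohortMatrix, list[PatientRecord], SyntheticTruth | None]:
    """Read a bundle written by :func:`write_fixture_bundle` (or any directory
    of RCC files with a samples.tsv sidecar)."""
    directory = Path(directory)
    sidecar = directory / "samples.tsv"
    if not sidecar.exists():
        raise FileNotFoundError(f"{sidecar} not found")
    groups: dict[str, Group] = {}
    order: list[str] = []
    for line in sidecar.read_text(encoding="utf-8").splitlines()[1:]:
        if line.strip():
            sid, grp = line.split("\t")
            groups[sid] = Group(grp)
            order.append(sid)
    samples = []
    for sid in order:
        path = directory / f"{sid}.RCC"
        if not path.exists():
            raise FileNotFoundError(f"RCC file for sample {sid!r} not found: {path}")
        rec = read_rcc(path)
        rec.group = groups[sid]
        samples.append(rec)
    patients_path = directory / "patients.tsv"
    patients = read_patient_table(patients_path) if patients_path.exists() else []
    truth_path = directory / "truth.json"
    truth = SyntheticTruth.from_json(truth_path) if truth_path.exists() else None
    return assemble_cohort(samples), patients, truth
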