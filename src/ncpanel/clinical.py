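"""Patient clinical data model, derived classifications and cohort summaries.

Holds the per-patient record used alongside the expression panel (demographics,
diabetes onset, BMI, glycemia markers, antidiabetic therapies), WHO BMI
classification, the HbA1c treatment-target flag, biochemical reference-range
checks, and descriptive cohort statistics (mean +/- SD for numeric fields,
counts and fractions for categorical ones).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Sex",
    "Therapy",
    "BmiClass",
    "GlycemicControl",
    "ReferenceRanges",
    "PatientRecord",
    "bmi_class",
    "glycemic_control_flag",
    "within_reference",
    "cohort_summary",
    "read_patient_table",
    "write_patient_table",
    "example_clinical_cohort",
]


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Therapy(str, enum.Enum):
    INSULIN = "insulin"
    METFORMIN = "metformin"
    DPP4I = "dpp4i"
    SGLT2I = "sglt2i"
    GLP1RA = "glp1ra"


class BmiClass(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


class GlycemicControl(str, enum.Enum):
    CONTROLLED = "controlled"
    POOR = "poor"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ReferenceRanges:
    """Laboratory reference intervals for the glycemia markers.

    Defaults are routine clinical-chemistry ranges: fasting glucose
    74-105 mg/dL, HbA1c < 5.7 %, C-peptide 0.81-2.85 ng/mL; the HbA1c
    treatment target separating controlled from poor glycemic control is 7 %.
    """

    glucose_low: float = 74.0
    glucose_high: float = 105.0
    hba1c_upper: float = 5.7
    c_peptide_low: float = 0.81
    c_peptide_high: float = 2.85
    hba1c_control_target: float = 7.0

    def __post_init__(self) -> None:
        if not (self.glucose_low < self.glucose_high):
            raise ValueError("glucose_low must be < glucose_high")
        if not (self.c_peptide_low < self.c_peptide_high):
            raise ValueError("c_peptide_low must be < c_peptide_high")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical row.

    Missing values are ``None`` and stay first-class: they are excluded from
    means/SDs and from classification denominators.  If ``weight_kg`` and
    ``height_m`` are given, BMI is derived as weight/height^2 and must agree
    with any stored BMI to within 0.05 kg/m^2.
    """

    case_id: str
    age_years: int
    sex: Sex
    onset_age_years: int | None = None
    family_history_dm_n: int | None = None
    bmi_kg_m2: float | None = None
    weight_kg: float | None = None
    height_m: float | None = None
    hba1c_pct: float | None = None
    fasting_glucose_mg_dl: float | None = None
    c_peptide_ng_ml: float | None = None
    secondary_complications: bool | None = None
    therapies: frozenset[Therapy] = frozenset()

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"{self.case_id}: age_years must be positive")
        if self.onset_age_years is not None:
            if self.onset_age_years <= 0:
                raise ValueError(f"{self.case_id}: onset_age_years must be positive")
            if self.onset_age_years > self.age_years:
                raise ValueError(
                    f"{self.case_id}: onset age {self.onset_age_years} exceeds age {self.age_years}"
                )
        if self.weight_kg is not None and self.height_m is not None:
            derived = self.weight_kg / self.height_m**2
            if self.bmi_kg_m2 is None:
                object.__setattr__(self, "bmi_kg_m2", derived)
            elif abs(derived - self.bmi_kg_m2) > 0.05:
                raise ValueError(
                    f"{self.case_id}: stored BMI {self.bmi_kg_m2} inconsistent with "
                    f"weight/height^2 = {derived:.2f}"
                )
        if self.bmi_kg_m2 is not None and self.bmi_kg_m2 <= 0:
            raise ValueError(f"{self.case_id}: BMI must be positive")

    @property
    def bmi_class(self) -> BmiClass | None:
        return None if self.bmi_kg_m2 is None else bmi_class(self.bmi_kg_m2)

    @property
    def glycemic_control(self) -> GlycemicControl:
        return glycemic_control_flag(self.hba1c_pct)

    @property
    def has_family_history(self) -> bool | None:
        if self.family_history_dm_n is None:
            return None
        return self.family_history_dm_n >= 1


def bmi_class(bmi: float) -> BmiClass:
    """WHO class: <18.5 underweight, [18.5, 25) normal, [25, 30) overweight, >=30 obese."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return BmiClass.UNDERWEIGHT
    if bmi < 25.0:
        return BmiClass.NORMAL
    if bmi < 30.0:
        return BmiClass.OVERWEIGHT
    return BmiClass.OBESE


def glycemic_control_flag(
    hba1c: float | None, target: float = 7.0
) -> GlycemicControl:
    """Treatment-target flag: poor iff HbA1c >= target (i.e. not below 7 %)."""
    if hba1c is None:
        return GlycemicControl.UNKNOWN
    if hba1c <= 0:
        raise ValueError(f"HbA1c must be positive, got {hba1c}")
    return GlycemicControl.POOR if hba1c >= target else GlycemicControl.CONTROLLED


def within_reference(
    value: float, analyte: str, ranges: ReferenceRanges = ReferenceRanges()
) -> bool:
    """True iff ``value`` lies in the analyte's closed reference interval.

    HbA1c has an upper bound only (normal is strictly below it).
    """
    if value <= 0:
        raise ValueError(f"analyte value must be positive, got {value}")
    if analyte == "glucose":
        return ranges.glucose_low <= value <= ranges.glucose_high
    if analyte == "hba1c":
        return value < ranges.hba1c_upper
    if analyte == "c_peptide":
        return ranges.c_peptide_low <= value <= ranges.c_peptide_high
    raise ValueError(f"unknown analyte {analyte!r}; expected glucose, hba1c or c_peptide")


_NUMERIC_FIELDS = (
    "age_years",
    "onset_age_years",
    "family_history_dm_n",
    "bmi_kg_m2",
    "hba1c_pct",
    "fasting_glucose_mg_dl",
    "c_peptide_ng_ml",
)


def cohort_summary(records: Iterable[PatientRecord]) -> dict:
    """Descriptive statistics of a patient cohort.

    Numeric fields get mean and sample SD (n-1 denominator; SD is ``None``
    when fewer than 2 non-missing values) over non-missing values.
    Categorical fields (sex, BMI class, glycemic control, therapies) get
    counts, with fractions reported over the full cohort denominator.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort_summary requires at least one record")
    n = len(records)

    numeric: dict[str, dict] = {}
    for fname in _NUMERIC_FIELDS:
        vals = [getattr(r, fname) for r in records if getattr(r, fname) is not None]
        entry: dict = {"n": len(vals)}
        if vals:
            arr = np.asarray(vals, dtype=float)
            entry["mean"] = float(arr.mean())
            entry["sd"] = float(arr.std(ddof=1)) if len(vals) >= 2 else None
        else:
            entry["mean"] = None
            entry["sd"] = None
        numeric[fname] = entry

    sex_counts = {s.value: sum(r.sex is s for r in records) for s in Sex}
    bmi_counts = {c.value: sum(r.bmi_class is c for r in records) for c in BmiClass}
    control_counts = {
        c.value: sum(r.glycemic_control is c for r in records) for c in GlycemicControl
    }
    therapy_counts = {t.value: sum(t in r.therapies for r in records) for t in Therapy}
    n_any_therapy = sum(bool(r.therapies) for r in records)
    n_combination = sum(len(r.therapies) >= 2 for r in records)
    fam_known = [r.has_family_history for r in records if r.has_family_history is not None]

    return {
        "n": n,
        "numeric": numeric,
        "sex": sex_counts,
        "bmi_class": {
            "counts": bmi_counts,
            "fractions": {k: v / n for k, v in bmi_counts.items()},
        },
        "glycemic_control": {
            "counts": control_counts,
            "poor_fraction": control_counts["poor"] / n,
        },
        "therapies": {
            "counts": therapy_counts,
            "n_any": n_any_therapy,
            "n_combination": n_combination,
        },
        "family_history": {
            "n_known": len(fam_known),
            "n_positive": sum(fam_known),
        },
    }


_TSV_COLUMNS = [
    "case_id",
    "age_years",
    "sex",
    "onset_age_years",
    "family_history_dm_n",
    "bmi_kg_m2",
    "hba1c_pct",
    "fasting_glucose_mg_dl",
    "c_peptide_ng_ml",
    "secondary_complications",
    "insulin",
    "metformin",
    "dpp4i",
    "sglt2i",
    "glp1ra",
]

_THERAPY_BY_COLUMN = {
    "insulin": Therapy.INSULIN,
    "metformin": Therapy.METFORMIN,
    "dpp4i": Therapy.DPP4I,
    "sglt2i": Therapy.SGLT2I,
    "glp1ra": Therapy.GLP1RA,
}


def _parse_bool(raw: str, origin: str) -> bool:
    low = raw.strip().lower()
    if low in ("yes", "true", "1"):
        return True
    if low in ("no", "false", "0"):
        return False
    raise ValueError(f"{origin}: expected Yes/No, got {raw!r}")


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a patient metadata TSV (missing values as empty fields)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty patient table")
    header = lines[0].split("\t")
    missing = [c for c in _TSV_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in _TSV_COLUMNS}
    records: list[PatientRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")

        def get(col: str) -> str:
            return fields[idx[col]].strip()

        def opt_float(col: str) -> float | None:
            raw = get(col)
            return float(raw) if raw else None

        def opt_int(col: str) -> int | None:
            raw = get(col)
            return int(raw) if raw else None

        therapies = frozenset(
            t for col, t in _THERAPY_BY_COLUMN.items() if get(col) and _parse_bool(get(col), f"{path}:{lineno}")
        )
        sec_raw = get("secondary_complications")
        records.append(
            PatientRecord(
                case_id=get("case_id"),
                age_years=int(get("age_years")),
                sex=Sex(get("sex")),
                onset_age_years=opt_int("onset_age_years"),
                family_history_dm_n=opt_int("family_history_dm_n"),
                bmi_kg_m2=opt_float("bmi_kg_m2"),
                hba1c_pct=opt_float("hba1c_pct"),
                fasting_glucose_mg_dl=opt_float("fasting_glucose_mg_dl"),
                c_peptide_ng_ml=opt_float("c_peptide_ng_ml"),
                secondary_complications=(
                    _parse_bool(sec_raw, f"{path}:{lineno}") if sec_raw else None
                ),
                therapies=therapies,
            )
        )
    return records


def write_patient_table(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records as a TSV readable by :func:`read_patient_table`."""

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return "Yes" if v else "No"
        if isinstance(v, float):
            return f"{v:g}"
        return str(v)

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            row = [
                r.case_id,
                str(r.age_years),
                r.sex.value,
                fmt(r.onset_age_years),
                fmt(r.family_history_dm_n),
                fmt(None if r.bmi_kg_m2 is None else round(r.bmi_kg_m2, 2)),
                fmt(r.hba1c_pct),
                fmt(r.fasting_glucose_mg_dl),
                fmt(r.c_peptide_ng_ml),
                fmt(r.secondary_complications),
            ]
            row += ["Yes" if t in r.therapies else "No" for t in _THERAPY_BY_COLUMN.values()]
            fh.write("\t".join(row) + "\n")


def example_clinical_cohort() -> list[PatientRecord]:
    """The bundled 19-patient suspected-MODY clinical table.

    Clinical and biochemical data of a published 19-patient cohort with
    clinical suspicion of monogenic diabetes (MODY) but a negative genetic
    diagnosis, used as the worked example throughout the package.
    """
    with resources.as_file(
        resources.files("ncpanel.data").joinpath("mody_cohort_clinical.tsv")
    ) as p:
        return read_patient_table(p)
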