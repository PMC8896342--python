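"""Reading and writing nCounter-style RCC sample files and cohort count matrices.

An RCC file is the per-sample text format of hybridization-based molecule
counting platforms: a handful of bracketed sections (``<Header>``,
``<Sample_Attributes>``, ``<Lane_Attributes>``, ...) holding ``key,value``
lines, and a ``<Code_Summary>`` section holding one CSV row per probe with
columns ``CodeClass,Name,Accession,Count``.  This module parses that dialect
into validated records, assembles per-sample records into a cohort count
matrix, and round-trips both the RCC format and a TSV matrix representation
losslessly.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodeClass",
    "Group",
    "ProbeRecord",
    "SampleRecord",
    "CohortMatrix",
    "RccFormatError",
    "read_rcc",
    "write_rcc",
    "assemble_cohort",
    "read_count_matrix_tsv",
    "write_count_matrix_tsv",
]


class CodeClass(str, enum.Enum):
    """Probe category on a targeted counting panel."""

    ENDOGENOUS = "Endogenous"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    HOUSEKEEPING = "Housekeeping"


class Group(str, enum.Enum):
    """Cohort arm of a sample."""

    CONTROL = "control"
    PATIENT = "patient"


class RccFormatError(ValueError):
    """Structural problem in an RCC or TSV file (missing section, ragged row...)."""


@dataclass(frozen=True)
class ProbeRecord:
    """One probe row: code class, probe name, transcript accession, raw count."""

    code_class: CodeClass
    name: str
    accession: str = ""
    count: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("probe name must be non-empty")
        if not isinstance(self.count, (int, np.integer)) or isinstance(self.count, bool):
            raise ValueError(f"probe {self.name!r}: count must be an integer, got {self.count!r}")
        if self.count < 0:
            raise ValueError(f"probe {self.name!r}: count must be non-negative, got {self.count}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.code_class.value, self.name)


# section order used when writing a sample that was built in memory
_DEFAULT_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes")


@dataclass
class SampleRecord:
    """All probes of one sample plus its cohort arm and preserved file sections.

    ``sections`` maps section name -> raw body lines for every non-probe
    section of the originating RCC file, preserved verbatim so that
    ``write_rcc(read_rcc(path))`` reproduces the file byte for byte.
    """

    sample_id: str
    group: Group | None = None
    probes: list[ProbeRecord] = field(default_factory=list)
    lane_attributes: dict[str, str] = field(default_factory=dict)
    sections: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        keys = [p.key for p in self.probes]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"sample {self.sample_id!r}: duplicate probes {dupes}")
        n_neg = sum(p.code_class is CodeClass.NEGATIVE for p in self.probes)
        n_pos = sum(p.code_class is CodeClass.POSITIVE for p in self.probes)
        if n_neg < 1:
            raise ValueError(f"sample {self.sample_id!r}: needs >=1 Negative probe, has {n_neg}")
        if n_pos < 2:
            raise ValueError(f"sample {self.sample_id!r}: needs >=2 Positive probes, has {n_pos}")

    def counts_by_class(self, code_class: CodeClass) -> dict[str, int]:
        return {p.name: p.count for p in self.probes if p.code_class is code_class}


def read_rcc(path: str | Path) -> SampleRecord:
    """Parse one RCC file into a :class:`SampleRecord`.

    Probes reproduce the ``Code_Summary`` rows in file order; all other
    sections are preserved verbatim for round-tripping.  The sample id is
    taken from the ``ID`` key of ``Sample_Attributes`` when present, else
    from the file stem.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("<") and stripped.endswith(">"):
            tag = stripped[1:-1]
            if tag.startswith("/"):
                if current != tag[1:]:
                    raise RccFormatError(f"{path}:{lineno}: unmatched closing tag <{tag}>")
                current = None
            else:
                if tag in sections:
                    raise RccFormatError(f"{path}:{lineno}: duplicate section <{tag}>")
                current = tag
                sections[tag] = []
            continue
        if current is None:
            if stripped:
                raise RccFormatError(f"{path}:{lineno}: content outside any section")
            continue
        sections[current].append(line)
    if current is not None:
        raise RccFormatError(f"{path}: section <{current}> never closed")
    if "Code_Summary" not in sections:
        raise RccFormatError(f"{path}: missing required section Code_Summary")

    probes = _parse_code_summary(sections.pop("Code_Summary"), origin=str(path))

    lane_attrs: dict[str, str] = {}
    for line in sections.get("Lane_Attributes", []):
        if "," in line:
            k, v = line.split(",", 1)
            lane_attrs[k] = v
    sample_id = path.stem
    for line in sections.get("Sample_Attributes", []):
        if line.startswith("ID,"):
            value = line.split(",", 1)[1]
            if value:
                sample_id = value
            break

    sample = SampleRecord(
        sample_id=sample_id, probes=probes, lane_attributes=lane_attrs, sections=sections
    )
    sample.validate()
    return sample


def _parse_code_summary(lines: Sequence[str], origin: str) -> list[ProbeRecord]:
    rows = [r for r in csv.reader(lines) if r]
    if not rows:
        raise RccFormatError(f"{origin}: empty Code_Summary section")
    header = [c.strip() for c in rows[0]]
    if header[:4] != ["CodeClass", "Name", "Accession", "Count"]:
        raise RccFormatError(
            f"{origin}: Code_Summary header must be CodeClass,Name,Accession,Count, got {header}"
        )
    probes: list[ProbeRecord] = []
    for row in rows[1:]:
        if len(row) != 4:
            raise RccFormatError(f"{origin}: Code_Summary row {row} does not have 4 fields")
        cls_raw, name, accession, count_raw = (c.strip() for c in row)
        try:
            code_class = CodeClass(cls_raw)
        except ValueError:
            raise RccFormatError(
                f"{origin}: unsupported CodeClass {cls_raw!r} in row {row}; "
                f"expected one of {[c.value for c in CodeClass]}"
            ) from None
        try:
            count = int(count_raw)
        except ValueError:
            raise ValueError(f"{origin}: non-integer Count {count_raw!r} in row {row}") from None
        if count < 0:
            raise ValueError(f"{origin}: negative Count {count} in row {row}")
        probes.append(ProbeRecord(code_class, name, accession, count))
    return probes


def write_rcc(sample: SampleRecord, path: str | Path) -> None:
    """Write ``sample`` as an RCC file; exact inverse of :func:`read_rcc`."""
    if not sample.probes:
        raise RccFormatError(f"sample {sample.sample_id!r}: refusing to write 0 probes")
    sample.validate()
    sections = dict(sample.sections)
    if not sections:
        sections = {
            "Header": ["FileVersion,1.7", "SoftwareVersion,ncpanel"],
            "Sample_Attributes": [f"ID,{sample.sample_id}", "Date,", "GeneRLF,", "Owner,"],
            "Lane_Attributes": [f"{k},{v}" for k, v in sample.lane_attributes.items()]
            or ["ID,1"],
        }
    buf = io.StringIO()
    for name in sections:
        buf.write(f"<{name}>\n")
        for line in sections[name]:
            buf.write(line + "\n")
        buf.write(f"</{name}>\n")
    buf.write("<Code_Summary>\n")
    buf.write("CodeClass,Name,Accession,Count\n")
    for p in sample.probes:
        buf.write(f"{p.code_class.value},{p.name},{p.accession},{p.count}\n")
    buf.write("</Code_Summary>\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


@dataclass
class CohortMatrix:
    """Probes x samples raw count matrix with shared probe ordering.

    ``counts[i, j]`` is the count of probe ``probes[i]`` in ``samples[j]``.
    Columns are ordered controls first, then patients, each arm in stable
    input order (see :func:`assemble_cohort`).
    """

    probes: list[ProbeRecord]  # counts field unused; identity is (code_class, name, accession)
    samples: list[SampleRecord]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> dict[str, Group]:
        return {s.sample_id: s.group for s in self.samples if s.group is not None}

    def sample_ids_in(self, group: Group) -> list[str]:
        return [s.sample_id for s in self.samples if s.group is group]

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by probe name, columns sample ids."""
        return pd.DataFrame(
            self.counts, index=[p.name for p in self.probes], columns=self.sample_ids
        )

    def class_frame(self, code_class: CodeClass) -> pd.DataFrame:
        idx = [i for i, p in enumerate(self.probes) if p.code_class is code_class]
        return pd.DataFrame(
            self.counts[idx, :],
            index=[self.probes[i].name for i in idx],
            columns=self.sample_ids,
        )

    def gene_names(self, code_class: CodeClass) -> list[str]:
        return [p.name for p in self.probes if p.code_class is code_class]


def assemble_cohort(samples: Iterable[SampleRecord]) -> CohortMatrix:
    """Stack per-sample records into a :class:`CohortMatrix`.

    All samples must carry exactly the same probe set; probe order is taken
    from the first sample.  Output columns are controls first, then patients,
    both sub-orders stable in input order.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError(f"need >=2 samples to assemble a cohort, got {len(samples)}")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    for s in samples:
        if s.group is None:
            raise ValueError(f"sample {s.sample_id!r} has no group (control/patient)")
        s.validate()

    ref_keys = [p.key for p in samples[0].probes]
    ref_set = set(ref_keys)
    for s in samples[1:]:
        diff = ref_set.symmetric_difference(p.key for p in s.probes)
        if diff:
            raise ValueError(
                f"probe sets differ between {samples[0].sample_id!r} and "
                f"{s.sample_id!r}: {sorted(diff)}"
            )

    ordered = [s for s in samples if s.group is Group.CONTROL] + [
        s for s in samples if s.group is Group.PATIENT
    ]
    probes = [
        ProbeRecord(p.code_class, p.name, p.accession, 0) for p in samples[0].probes
    ]
    counts = np.zeros((len(probes), len(ordered)), dtype=np.int64)
    for j, s in enumerate(ordered):
        by_key = {p.key: p.count for p in s.probes}
        counts[:, j] = [by_key[k] for k in ref_keys]
    return CohortMatrix(probes=probes, samples=ordered, counts=counts)


def _default_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".samples.tsv")


def write_count_matrix_tsv(
    matrix: CohortMatrix, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Write the cohort as a TSV matrix plus a sample-id -> group sidecar TSV.

    Matrix columns: ``code_class``, ``name``, ``accession``, then one column
    per sample.  Lossless inverse of :func:`read_count_matrix_tsv`.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _default_sidecar(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(["code_class", "name", "accession", *matrix.sample_ids]) + "\n")
        for i, p in enumerate(matrix.probes):
            row = [p.code_class.value, p.name, p.accession]
            row += [str(int(c)) for c in matrix.counts[i, :]]
            fh.write("\t".join(row) + "\n")
    with sidecar.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for s in matrix.samples:
            fh.write(f"{s.sample_id}\t{s.group.value}\n")


def read_count_matrix_tsv(
    path: str | Path, sidecar: str | Path | None = None
) -> CohortMatrix:
    """Read a TSV count matrix written by :func:`write_count_matrix_tsv`."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _default_sidecar(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise RccFormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[:2] != ["code_class", "name"]:
        raise RccFormatError(f"{path}: first two columns must be code_class, name")
    has_accession = len(header) > 2 and header[2] == "accession"
    meta_cols = 3 if has_accession else 2
    sample_ids = header[meta_cols:]
    if not sample_ids:
        raise RccFormatError(f"{path}: no sample columns")

    groups = _read_sidecar(sidecar)
    missing = [sid for sid in sample_ids if sid not in groups]
    if missing:
        raise RccFormatError(f"{sidecar}: missing group for sample(s) {missing}")

    probes: list[ProbeRecord] = []
    counts: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise RccFormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            code_class = CodeClass(fields[0])
        except ValueError:
            raise RccFormatError(f"{path}:{lineno}: unsupported code_class {fields[0]!r}") from None
        accession = fields[2] if has_accession else ""
        try:
            row = [int(c) for c in fields[meta_cols:]]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer count") from None
        probes.append(ProbeRecord(code_class, fields[1], accession, 0))
        counts.append(row)

    arr = np.asarray(counts, dtype=np.int64)
    samples = []
    for j, sid in enumerate(sample_ids):
        probe_objs = [
            ProbeRecord(p.code_class, p.name, p.accession, int(arr[i, j]))
            for i, p in enumerate(probes)
        ]
        samples.append(SampleRecord(sample_id=sid, group=groups[sid], probes=probe_objs))
    matrix = CohortMatrix(probes=probes, samples=samples, counts=arr)
    return matrix


def _read_sidecar(path: Path) -> dict[str, Group]:
    if not path.exists():
        raise RccFormatError(f"sample-group sidecar not found: {path}")
    groups: dict[str, Group] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and line.lower().startswith("sample_id"):
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise RccFormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        sid, grp = fields
        try:
            groups[sid] = Group(grp)
        except ValueError:
            raise RccFormatError(
                f"{path}:{lineno}: group must be control or patient, got {grp!r}"
            ) from None
    return groups
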