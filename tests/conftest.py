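import numpy as np
import pytest

from ncpanel.rcc_io import CodeClass, Group, ProbeRecord, SampleRecord, assemble_cohort
from ncpanel.synthetic_data import GeneratorConfig, generate_cohort


def make_sample(
    sample_id: str,
    group: Group = Group.CONTROL,
    endogenous: dict[str, int] | None = None,
    housekeeping: dict[str, int] | None = None,
    negatives: tuple[int, ...] = (10, 12, 14),
    positives: tuple[int, ...] = (8000, 2000, 500),
) -> SampleRecord:
    """Hand-rolled minimal valid sample for unit tests."""
    probes = [
        ProbeRecord(CodeClass.POSITIVE, f"POS_{chr(65 + i)}", f"ERCC_{i}", c)
        for i, c in enumerate(positives)
    ]
    probes += [
        ProbeRecord(CodeClass.NEGATIVE, f"NEG_{chr(65 + i)}", "", c)
        for i, c in enumerate(negatives)
    ]
    for name, c in (endogenous or {"GCK": 300, "HADH": 210}).items():
        probes.append(ProbeRecord(CodeClass.ENDOGENOUS, name, f"NM_{name}", c))
    for name, c in (housekeeping or {"GAPDH": 5000, "TBP": 900, "GUSB": 1200}).items():
        probes.append(ProbeRecord(CodeClass.HOUSEKEEPING, name, f"NM_{name}", c))
    return SampleRecord(sample_id=sample_id, group=group, probes=probes)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (8 controls + 19 patients), seed 1."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture
def uniform_cohort():
    """Every sample identical: normalization must be the identity."""
    samples = [
        make_sample(f"C{i}", Group.CONTROL) for i in range(1, 4)
    ] + [make_sample(f"M{i}", Group.PATIENT) for i in range(1, 4)]
    return assemble_cohort(samples)
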