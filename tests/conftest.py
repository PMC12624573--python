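from __future__ import annotations

import random

import pytest

from isletpep import ElutionClass, PeptideRecord, SyntheticConfig, generate_immunopeptidome
from isletpep.model import AMINO_ACIDS


def random_peptide(rng: random.Random, lo: int = 8, hi: int = 25) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(lo, hi)))


def make_record(
    sequence: str,
    sample_id: str = "S1",
    elution: ElutionClass = ElutionClass.DR,
    **kwargs,
) -> PeptideRecord:
    return PeptideRecord(
        sequence=sequence, sample_id=sample_id, elution_class=elution, **kwargs
    )


@pytest.fixture(scope="session")
def default_peptidome():
    """One default-configuration synthetic experiment, shared read-only."""
    return generate_immunopeptidome(SyntheticConfig(seed=17))


@pytest.fixture()
def rng():
    return random.Random(1234)
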