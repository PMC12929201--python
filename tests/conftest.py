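import pandas as pd
import pytest

from gapvigil.lexicon import AbstractRecord, build_drug_lexicon, \
    default_population_lexicon
from gapvigil.landscape import ClaimsCohort
from gapvigil.simulate import SimConfig, gen_abstract_corpus


@pytest.fixture(scope="session")
def drug_lexicon():
    return build_drug_lexicon({
        "aspirin": ["acetylsalicylic acid", "ASA"],
        "acetaminophen": ["paracetamol", "tylenol"],
        "metformin": ["metformin hydrochloride", "glucophage"],
    })


@pytest.fixture(scope="session")
def pop_lexicon():
    return default_population_lexicon()


@pytest.fixture
def record():
    return AbstractRecord(
        record_id="PM0000001",
        title="Aspirin pharmacokinetics in pregnant women",
        abstract="We measured clearance of aspirin in a cohort of mothers.",
        mesh_terms=("Aspirin", "Pregnancy"),
        keywords=("pharmacokinetics",),
        year=2021,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A 400-record generated corpus with ground truth (session-cached)."""
    return gen_abstract_corpus(SimConfig(seed=42, n_papers=400))


@pytest.fixture
def tiny_cohort():
    """Hand-built cohort: two pregnant persons (one enrollment violator)."""
    persons = pd.DataFrame({
        "person_id": ["a", "b", "c"],
        "birth_day": [-9000, -9500, 400],
        "sex": ["F", "F", "M"],
    })
    spans = pd.DataFrame({
        "person_id": ["a", "b", "c"],
        "start_day": [0, 1000, 0],
        "end_day": [2000, 1400, 2000],
    })
    rx = pd.DataFrame({
        "person_id": ["a", "a", "a", "b"],
        "drug": ["drugx", "drugx", "drugy", "drugx"],
        "day": [730, 1000, 1001, 1100],
    })
    dx = pd.DataFrame({
        "person_id": ["a"], "icd10_code": ["R00.0"], "day": [750],
    })
    deliveries = pd.DataFrame({
        "person_id": ["a", "b"], "day": [1000, 1200], "code": ["O80", "O80"],
    })
    return ClaimsCohort(persons, spans, rx, dx, deliveries)
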