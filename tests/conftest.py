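import pytest

from ethnoindices.core_data import (Dataset, Freelist, Participant,
                                    SpeciesRecord, UseReport)
from ethnoindices.synthetic import GeneratorConfig, generate_dataset


def make_participant(pid="P001", sex="female", age=30.0, migration="none"):
    return Participant(pid, sex, age, migration)


@pytest.fixture
def tiny_dataset():
    """Four informants, three species, hand-checkable indices."""
    participants = {
        "P001": Participant("P001", "female", 25.0, "none"),
        "P002": Participant("P002", "male", 45.0, "none"),
        "P003": Participant("P003", "female", 65.0, "none"),
        "P004": Participant("P004", "male", 18.0, "temporary"),
    }
    species = {c: SpeciesRecord(code=c, scientific_name=f"Species {c}")
               for c in ("AA", "BB", "CC")}
    freelists = {
        "P001": Freelist("P001", ("AA", "BB")),        # AA: 1.0, BB: 0.5
        "P002": Freelist("P002", ("BB", "AA", "CC")),  # AA: 2/3, BB: 1.0
        "P003": Freelist("P003", ("AA",)),             # AA: 1.0
        # P004 gave no freelist: salience 0 everywhere
    }
    reports = [
        UseReport("P001", "AA", "medicine", "stomach ache"),
        UseReport("P001", "AA", "medicine", "influenza"),
        UseReport("P001", "AA", "fuel", "firewood"),
        UseReport("P002", "AA", "medicine", "stomach ache"),
        UseReport("P002", "BB", "fodder", "goats"),
        UseReport("P003", "BB", "fodder", "sheep"),
        UseReport("P003", "BB", "construction", "roof beams"),
    ]
    return Dataset(participants, species, freelists, reports)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (40 informants, 14 species)."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=42)
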