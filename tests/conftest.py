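import pytest

from silicogut.synthetic_data import ToyModelSpec, generate_toy_models
from silicogut.workflow import run_cohort

ROLE_SPECS = [
    ToyModelSpec("fp", "Bacteroidia", "fiber_propionate"),
    ToyModelSpec("bcf", "Clostridia", "butyrate_crossfeeder"),
    ToyModelSpec("lp", "Bacilli", "lactate_producer"),
    ToyModelSpec("ap", "Gammaproteobacteria", "acetate_producer"),
    ToyModelSpec("gen", "Other", "generalist"),
]


@pytest.fixture(scope="session")
def role_models():
    """One toy model per ecological role, keyed by short species id."""
    return generate_toy_models(ROLE_SPECS, seed=0)


@pytest.fixture(scope="session")
def role_taxonomy():
    return {s.species_id: s.taxon_class for s in ROLE_SPECS}


@pytest.fixture(scope="session")
def cohort_run():
    """The default synthetic cohort (10 healthy + 10 dysbiotic, seed 7),
    fully simulated.  Shared session-wide: it anchors the group-level
    emergent-property checks."""
    return run_cohort()
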