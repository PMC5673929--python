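import numpy as np
import pytest

from chemrich import fixtures, pipeline


@pytest.fixture(scope="session")
def study_and_truth():
    return fixtures.generate_fixture_study(seed=7)


@pytest.fixture(scope="session")
def mini_db():
    return fixtures.mini_ontology()


@pytest.fixture(scope="session")
def default_run(study_and_truth, mini_db):
    study, _ = study_and_truth
    return pipeline.run_chemrich(study, mini_db)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
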