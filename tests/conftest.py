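import pytest

from bchicea.interface import build_parameters, load_and_validate
from bchicea.synthetic_data import make_life_table


@pytest.fixture(scope="session")
def run_config():
    return load_and_validate()


@pytest.fixture(scope="session")
def base_inputs(run_config):
    """(osia, baha, model_config, life_table) built from packaged fixtures."""
    return build_parameters(run_config)


@pytest.fixture(scope="session")
def summaries(run_config):
    from bchicea.evidence_synthesis import load_study_summaries

    return load_study_summaries(run_config.study_summaries)


@pytest.fixture(scope="session")
def immortal():
    return make_life_table("constant", q=0.0)
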