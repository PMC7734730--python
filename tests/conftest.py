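import pytest
from hypothesis import settings

from textkg import load_replay_fixture, load_roleset_inventory
from textkg.linking import load_lexicon_tsv
from textkg.pipeline import packaged_data

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# The worked-example sentences used throughout the suite.
CONFIRMS = "This study confirms the high prevalence of poststroke cognitive impairment."
CONFIRMS_LONG = (
    "This study confirms the high prevalence of poststroke cognitive impairment "
    "in diverse populations."
)
WARRANT = "Ethnoracial differences warrant attention in the development of prevention strategies."
CONJUNCTION = (
    "This study confirms cognitive impairment in populations, and points to "
    "ethnoracial differences."
)
SULCI = (
    "High-convexity tight sulci may confound clinical and biomarker interpretation "
    "in Alzheimer's Disease clinical trials."
)
RISK_FACTORS = "This study also highlights common risk factors."


@pytest.fixture(scope="session")
def provider():
    return load_replay_fixture(packaged_data("annotations.json"))


@pytest.fixture(scope="session")
def inventory():
    return load_roleset_inventory(packaged_data("rolesets.tsv"))


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon_tsv(packaged_data("synthetic_lexicon.tsv"))


@pytest.fixture(scope="session")
def ontology_path():
    return packaged_data("synthetic_ontology.ttl")
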