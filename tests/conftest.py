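import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from c2hdx import elemental_composition, natural_envelope, parse_sequence

# The seven-peptide model panel plus the multi-His and angiotensin-like
# sequences used throughout: short, single-exchange-site test subjects.
PANEL_SEQUENCES = ["AARHAF", "AADHAF", "ARAHAF", "ADAHAF", "RAAHAF", "DAAHAF", "AAAHAF"]
EXTRA_SEQUENCES = ["bDRVYIHPF", "NHFWKTHT-NH2", "HYIQNHPLG-NH2"]


@pytest.fixture(scope="session")
def neutral_peptide():
    return parse_sequence("AAAHAF")


@pytest.fixture(scope="session")
def neutral_envelope(neutral_peptide):
    return natural_envelope(elemental_composition(neutral_peptide), 8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)
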