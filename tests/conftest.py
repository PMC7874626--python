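import json
from pathlib import Path

import pytest
from hypothesis import settings

from hacrp import builtin_methodologies, generate_worked_micro_cohort

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def methodologies():
    return builtin_methodologies()


@pytest.fixture(scope="session")
def micro_records():
    return generate_worked_micro_cohort()


@pytest.fixture(scope="session")
def micro_expected():
    """Hand-computed domain scores/totals/penalties for the worked
    micro-cohort (synthetic fixture, frozen from brute-force oracles)."""
    with open(DATA_DIR / "micro_expected.json") as fh:
        return json.load(fh)
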