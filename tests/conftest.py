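import logging

import pytest

from alkcea import default_paper_parameters

# the beta->uniform fallback for sensitivity/specificity is expected and
# logged once; keep test output clean
logging.getLogger("alkcea.sensitivity").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def defaults():
    """The published base-case bundle with calibrated conventions (PAP on)."""
    return default_paper_parameters()


@pytest.fixture(scope="session")
def short_run(defaults):
    """Small-horizon variant for fast engine tests (2-year horizon)."""
    return defaults.with_run(horizon_years=2.0)
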