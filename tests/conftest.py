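import sys
from pathlib import Path

import pytest

from repforge.germline import builtin_toy_reference

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles


@pytest.fixture(scope="session")
def igh_db():
    return builtin_toy_reference("IGH")


@pytest.fixture(scope="session")
def trb_db():
    return builtin_toy_reference("TRB")
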