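import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from opsinminer import fixtures as fx
from opsinminer.seq import bovine_rhodopsin


@pytest.fixture(scope="session")
def bovine():
    return bovine_rhodopsin()


@pytest.fixture(scope="session")
def templates():
    return fx.class_templates()


@pytest.fixture(scope="session")
def ref_db():
    return fx.make_reference_db()
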