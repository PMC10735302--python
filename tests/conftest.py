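import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from markerstitch.pairwise import ScoringScheme


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()
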