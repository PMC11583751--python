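import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # helpers / oracle modules

from hemovigil import ColumnMap, WindowPolicy


@pytest.fixture(scope="session")
def cmap() -> ColumnMap:
    return ColumnMap()


@pytest.fixture(scope="session")
def policy() -> WindowPolicy:
    return WindowPolicy()
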