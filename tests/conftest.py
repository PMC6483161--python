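import sys
from pathlib import Path

import pytest

# make the expected_cells helper importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))

from accurator import load_preset


@pytest.fixture(scope="session")
def rare_vs_common_set():
    return load_preset("rare_vs_common")


@pytest.fixture(scope="session")
def observed_conditions_set():
    return load_preset("observed_conditions")


@pytest.fixture(scope="session")
def all_preset_columns(rare_vs_common_set, observed_conditions_set):
    """Every shipped scenario column, in table order."""
    return list(rare_vs_common_set.columns) + list(observed_conditions_set.columns)
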