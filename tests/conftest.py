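import warnings

import numpy as np
import pytest

from tecurate.msa import Msa

warnings.filterwarnings("ignore", message=".*end_gap_score.*")


def msa_from(*rows: str) -> Msa:
    """Build an alignment from bare row strings with generated ids."""
    return Msa.from_rows([(f"s{i}", row) for i, row in enumerate(rows)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
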