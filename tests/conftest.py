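import numpy as np
import pytest

from selfpath import (
    CACAO_FAMILY_C_PARENT_RULE,
    GenotypeMatrix,
    SelfingFamilyModel,
    load_cacao_counts,
)


@pytest.fixture(scope="session")
def cacao_fit():
    """Counts-only model fitted on the bundled six-family cacao table, with
    the published family-C parent rule (sibling TSH-1188_S1_3)."""
    model = SelfingFamilyModel.from_counts_table(load_cacao_counts())
    return model.fit(alpha=0.05, parent_override=CACAO_FAMILY_C_PARENT_RULE)


@pytest.fixture(scope="session")
def cacao_offspring(cacao_fit):
    return cacao_fit.offspring.set_index("individual")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_matrix():
    """4 samples x 5 markers with one missing call."""
    calls = np.array(
        [
            [0, 0, 2, 1, -1],
            [0, 1, 2, 1, 2],
            [0, 1, 2, 1, 2],
            [2, 2, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(calls, ["s1", "s2", "s3", "s4"], [f"m{i}" for i in range(1, 6)])
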