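import numpy as np
import pandas as pd
import pytest

from chronocomm.io_core import AsvTable, ChronoMeta, FunctionTable, PhyloTree
from chronocomm.rarity import classify_taxa
from chronocomm.synthdata import ScenarioConfig, generate_chronosequence


@pytest.fixture(scope="session")
def default_dataset():
    """One scaled-down chronosequence under the default (drift) regime."""
    return generate_chronosequence(ScenarioConfig(pool_size=400, depth=5000, seed=11))


@pytest.fixture(scope="session")
def default_labels(default_dataset):
    return classify_taxa(default_dataset.table)


@pytest.fixture
def toy_table():
    """4 samples x 6 ASVs with a skewed abundance spectrum."""
    counts = pd.DataFrame(
        [
            [50, 20, 5, 2, 1, 0],
            [45, 25, 4, 0, 2, 1],
            [60, 10, 6, 3, 0, 0],
            [55, 15, 2, 1, 1, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"a{i}" for i in range(1, 7)],
    )
    return AsvTable(counts)


@pytest.fixture
def toy_tree():
    """The 3-tip tree (A:1,(B:1,C:1):1); d(A,B)=3, d(B,C)=2."""
    return PhyloTree.from_string("(A:1,(B:1,C:1):1);")


@pytest.fixture
def toy_meta():
    return ChronoMeta(
        pd.DataFrame(
            {
                "duration": [0.0, 0.0, 5.0, 5.0],
                "stage": ["s0", "s0", "s1", "s1"],
                "replicate": [1, 2, 1, 2],
            },
            index=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def toy_functions():
    rng = np.random.default_rng(3)
    from chronocomm.io_core import FUNCTION_NAMES

    vals = rng.lognormal(0, 0.5, (4, len(FUNCTION_NAMES)))
    return FunctionTable(
        pd.DataFrame(vals, index=["s1", "s2", "s3", "s4"], columns=FUNCTION_NAMES)
    )
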