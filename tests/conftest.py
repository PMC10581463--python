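import numpy as np
import pandas as pd
import pytest

from guidekit.simulate import ScreenConfig, generate_screen


@pytest.fixture(scope="session")
def screen_sim():
    """Default mini-human-like screen simulation, shared across tests."""
    return generate_screen(ScreenConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_alleles():
    """Hand-written allele table used by several outcome tests."""
    return pd.DataFrame(
        [
            # target_id, variant_type, length, position, outcome_base, read_count
            ("t1", "deletion", 1, 20, None, 6),
            ("t1", "deletion", 2, 21, None, 3),
            ("t1", "insertion", 1, 22, None, 3),
            ("t1", "SNV", 1, 26, "G", 2),
            ("t1", "WT", 0, 0, None, 86),
            ("t2", "deletion", 1, 19, None, 6),
            ("t2", "insertion", 2, 20, None, 3),
            ("t2", "WT", 0, 0, None, 91),
        ],
        columns=[
            "target_id", "variant_type", "length", "position",
            "outcome_base", "read_count",
        ],
    )
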