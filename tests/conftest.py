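import numpy as np
import pandas as pd
import pytest

from petscreen.seqio import Alignment, SequenceRecord
from petscreen.simulate import WorldConfig, generate_world, simulate_assay


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        [
            SequenceRecord("a", "MKV-A"),
            SequenceRecord("b", "MKVLA"),
            SequenceRecord("c", "MRV-A"),
        ]
    )


@pytest.fixture(scope="session")
def small_world():
    cfg = WorldConfig(n_enzymes=80, seed=7)
    sequences, truth = generate_world(cfg)
    return cfg, sequences, truth


@pytest.fixture(scope="session")
def small_world_assay(small_world):
    cfg, sequences, truth = small_world
    return simulate_assay(truth, cfg)


def make_assay_rows(entries):
    """entries: (enzyme_id, substrate, pH, temp, A260, blank) -> well table."""
    rows = []
    for eid, sub, ph, temp, a260, blank in entries:
        rows.append(
            {
                "enzyme_id": eid,
                "round": eid[:2] if eid[2].isdigit() else eid[:3],
                "substrate": sub,
                "pH": ph,
                "temperature": temp,
                "replicate": 1,
                "A260": a260,
                "A280": 0.5 * a260,
                "blank_A260": blank,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
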