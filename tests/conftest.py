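import numpy as np
import pytest

from bzipspec.registers import assign_register
from bzipspec.synthetic import SimulationConfig, simulate, simulate_coils


@pytest.fixture(scope="session")
def toy_dataset():
    """Small censored dataset with a planted model (12 proteins, ~40 pairs)."""
    from bzipspec.synthetic import worked_toy

    return worked_toy()


@pytest.fixture(scope="session")
def small_sim():
    """Mid-size synthetic dataset for validation-level tests."""
    # stronger planted weights so all three affinity strata are populated
    # even with short (4-block) coils
    cfg = SimulationConfig(n_proteins=24, blocks_per_protein=4, weight_scale=1.2, seed=11)
    ds, model = simulate(cfg)
    return ds, model, cfg


def random_coil(rng, n_blocks=2, phase="f", cid="C"):
    """A random registered coil over the full amino-acid alphabet."""
    from bzipspec.registers import AMINO_ACIDS

    length = 7 * n_blocks
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return assign_register(cid, seq, phase)
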