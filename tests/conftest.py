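import numpy as np
import pytest

import omicblup as ob


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale simulated panel: 60 inbred lines, additive + mediated trait."""
    cfg = ob.SimulationConfig(n_lines=60, n_markers=300, n_genes=40, seed=11)
    ds, truth = ob.simulate_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def tiny_genotypes():
    """5 lines x 6 markers with some heterozygotes and missing calls."""
    d = np.array(
        [
            [0, 2, 1, 0, 2, 0],
            [2, 0, 0, 0, 2, 0],
            [0, 2, 2, 0, 0, 0],
            [2, 2, 1, 0, np.nan, 0],
            [0, 0, 0, 0, 2, 0],
        ],
        dtype=float,
    )
    return ob.GenotypeMatrix.from_dosages(
        d, [f"l{i}" for i in range(5)], [f"m{j}" for j in range(6)]
    )
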