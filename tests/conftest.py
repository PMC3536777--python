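import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import trsubtype.matrixio as mio
import trsubtype.simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_matrix(rng):
    """50 probes x 6 samples of continuous log2-like values (no ties)."""
    data = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(50, 6)),
        index=[f"p{i:02d}" for i in range(50)],
        columns=[f"s{j}" for j in range(6)],
    )
    return mio.ExpressionMatrix(data)


@pytest.fixture
def small_config():
    return sim.SimulationConfig(n_genes=60, seed=7)


def make_designs(cells, cell_line="HepG2", time_hr=3.0):
    """Build SampleDesign lists from {(receptor, ligand): [sample ids]}."""
    designs = []
    for (receptor, ligand), ids in cells.items():
        for k, sid in enumerate(ids, start=1):
            designs.append(
                mio.SampleDesign(
                    sample_id=sid, cell_line=cell_line, receptor=receptor,
                    ligand=ligand, dose_nM=100.0 if ligand == "T3" else 0.0,
                    time_hr=time_hr, chx=False, replicate=k,
                )
            )
    return designs
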