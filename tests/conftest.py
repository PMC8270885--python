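import numpy as np
import pandas as pd
import pytest

from sgfound.synthetic import SceneConfig, simulate_sg_scene


@pytest.fixture(scope="session")
def noiseless_scene():
    """20 interior cells, no noise: detection should be exact."""
    return simulate_sg_scene(SceneConfig(n_cells=20, noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_scene():
    return simulate_sg_scene(SceneConfig(n_cells=25, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_well_table(rng, n_reps=4, constructs=("WT", "M1", "M2"),
                    treatments=("NT", "MG", "ARS", "R1", "R3"),
                    effects=None, sd=0.05, base=0.3):
    """Balanced replicate-level table of SG readouts with optional planted
    construct effects (dict construct -> additive shift)."""
    effects = effects or {}
    rows = []
    for rep in range(1, n_reps + 1):
        for con in constructs:
            for trt in treatments:
                rows.append(
                    dict(replicate=rep, construct=con, treatment=trt,
                         prop_sg_cells=base + effects.get(con, 0.0) + rng.normal(0, sd))
                )
    return pd.DataFrame(rows)
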