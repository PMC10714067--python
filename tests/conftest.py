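import numpy as np
import pytest

from sealforage import SimulationConfig
from sealforage.pipeline import run_pipeline
from sealforage.simulate import simulate_deployment


@pytest.fixture(scope="session")
def small_cfg():
    """A compact 3-individual deployment: fast to simulate, but with enough
    dives and capture attempts to exercise every stage."""
    return SimulationConfig(
        seed=0,
        dives_per_individual=(14, 6, 10),
        foraging_dives_per_individual=(4, 1, 2),
        prcas_per_individual=(14, 1, 4),
    )


@pytest.fixture(scope="session")
def small_deployment(small_cfg):
    return simulate_deployment(small_cfg)


@pytest.fixture(scope="session")
def small_result(small_deployment, small_cfg):
    bundles, truth = small_deployment
    return run_pipeline(bundles, truth=truth, config=small_cfg,
                        cluster=False, approach=True)


def overlap_fraction(a_start, a_end, b_start, b_end):
    ov = min(a_end, b_end) - max(a_start, b_start)
    return max(ov, 0.0) / (a_end - a_start)
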