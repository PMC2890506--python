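import pytest

from polyprime.io_utils import RunConfig
from polyprime.pipeline import design_family
from polyprime.synthetic_data import SimulationParams, simulate_family


@pytest.fixture(scope="session")
def sim_family():
    """Default simulated 3-copy homoeolog family (seeded)."""
    return simulate_family(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def small_family():
    """Compact family for oracle tests that scan every column."""
    return simulate_family(
        SimulationParams(
            seed=7,
            n_exons=3,
            exon_length_range=(40, 60),
            intron_length_range=(60, 120),
        )
    )


@pytest.fixture(scope="session")
def design_result(sim_family):
    """End-to-end design on the default family using its true alignment."""
    return design_family(
        sim_family.copies,
        RunConfig(),
        precomputed_alignment=sim_family.alignment.rows,
    )
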