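import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pioneerclass.core import FragmentSet, PeakSet, SignalTrack
from pioneerclass.simulate import SimulationConfig, plant_layout

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A miniature planted dataset: 32 peaks on 150 kb, shallow depths."""
    return SimulationConfig(
        genome_length=150_000,
        n_peaks_per_class=8,
        depth_atac=150_000,
        depth_mnase=120_000,
        depth_chip=40_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_layout(small_config):
    return plant_layout(small_config)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return {small_config.chrom: small_config.genome_length}


@pytest.fixture
def uniform_track():
    """Constant-density track factory: value per bp over one chromosome."""

    def make(length=10_000, value=1.0, chrom="chr1"):
        return SignalTrack.from_dense({chrom: length}, {chrom: np.full(length, value)})

    return make


@pytest.fixture
def make_fragments():
    def make(rows, assay="MNASE", condition="control", is_paired=False):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        return FragmentSet(assay, condition, df, is_paired=is_paired)

    return make


@pytest.fixture
def three_peaks():
    return PeakSet(
        pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [900, 2900, 4900],
                "end": [1100, 3100, 5100],
            }
        )
    )
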