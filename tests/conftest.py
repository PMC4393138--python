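import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from paleosel.core_data import AbundanceSeries, SpeciesRecord
from paleosel.synth import SynthConfig, synth_assembly


def make_series(values, core_id="c1", species_id="sp", depths=None):
    """AbundanceSeries from a value list; depths default to 1 m spacing."""
    n = len(values)
    if depths is None:
        depths = tuple(float(100 + n - i) for i in range(n))  # strictly decreasing
    return AbundanceSeries(
        core_id=core_id, species_id=species_id, depths=tuple(depths), values=tuple(values)
    )


def make_record(*value_lists, survival=0, species_id="sp"):
    series = tuple(
        make_series(vals, core_id=f"c{i}", species_id=species_id)
        for i, vals in enumerate(value_lists)
    )
    return SpeciesRecord(species_id=species_id, survival=survival, series=series)


@pytest.fixture(scope="session")
def synth_default():
    """One default-condition synthetic dataset shared across tests."""
    return synth_assembly(SynthConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
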