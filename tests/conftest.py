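import numpy as np
import pandas as pd
import pytest

from marisdm import make_erm, make_species, make_world, sample_occurrences


@pytest.fixture(scope="session")
def world():
    """A small synthetic ocean world shared across tests (seed-fixed)."""
    return make_world(seed=11, resolution=0.5)


@pytest.fixture(scope="session")
def pelagic_species(world):
    return make_species(world, taxon_id="pel1", habitat_label="pelagic")


@pytest.fixture(scope="session")
def demersal_species(world):
    return make_species(
        world, taxon_id="dem1", habitat_label="demersal", depth_range=(0, 800)
    )


@pytest.fixture(scope="session")
def clean_records(world, pelagic_species):
    """Error-free occurrence table for the pelagic species."""
    rates = {k: 0.0 for k in ("land", "zero_zero", "duplicate", "stray", "missing_date")}
    return sample_occurrences(
        world, pelagic_species, n=400, seed=7, error_profile=rates
    )


@pytest.fixture(scope="session")
def dirty_records(world, pelagic_species):
    """Occurrence table with all error classes injected at default rates."""
    return sample_occurrences(world, pelagic_species, n=400, seed=7)


@pytest.fixture(scope="session")
def erm(world, pelagic_species):
    return make_erm(pelagic_species, world)


def make_table(rows):
    """Build an occurrence DataFrame from compact dict rows."""
    defaults = {
        "taxon_id": "t1",
        "lon": 10.0,
        "lat": 10.0,
        "year": 2000.0,
        "month": 6.0,
        "basis_of_record": "observation",
        "source": "gbif",
        "original_flags": [],
        "flag": np.nan,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])
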