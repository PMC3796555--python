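import numpy as np
import pytest

from pollmap import (
    GridSpec,
    generate_landscape,
    generate_virtual_species,
    grid_records,
    sample_background,
    sample_occurrences,
)
from pollmap.synthetic import make_effort


@pytest.fixture(scope="session")
def spec20():
    return GridSpec(20, 20)


@pytest.fixture(scope="session")
def landscape4(spec20):
    """Four smooth standardized predictor layers."""
    return generate_landscape(spec20, n_layers=4, smoothness=3.0, seed=7)


@pytest.fixture(scope="session")
def strong_species(landscape4):
    """Virtual species driven by env1 only, with a narrow Gaussian response."""
    return generate_virtual_species(
        landscape4,
        {"env1": {"kind": "gaussian", "center": 0.8, "width": 0.5}},
        occupancy_threshold=0.5,
        species_id="Bombus fortis",
    )


@pytest.fixture(scope="session")
def strong_records(strong_species, spec20):
    return sample_occurrences(
        strong_species, 300, make_effort(spec20), seed=5, spec=spec20
    )


@pytest.fixture(scope="session")
def strong_grid(strong_records, spec20):
    return grid_records(strong_records, spec20)


@pytest.fixture(scope="session")
def uniform_background(spec20):
    return sample_background(spec20.all_cells(), n=250, seed=3)
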