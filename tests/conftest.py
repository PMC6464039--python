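import numpy as np
import pytest

from ratestab import AgeGroupScheme, CountCube, StandardPopulation, parse_age_scheme


@pytest.fixture
def four_bin_scheme() -> AgeGroupScheme:
    """0-34, 35-44, 45-64, 65+ — the coarse adult scheme."""
    return parse_age_scheme((0, 35, 45, 65))


@pytest.fixture
def six_bin_scheme() -> AgeGroupScheme:
    """35-44 ... 85+ — the six-bracket scheme used by the simulation study."""
    return parse_age_scheme((35, 45, 55, 65, 75, 85))


@pytest.fixture
def small_cube(four_bin_scheme) -> CountCube:
    """Three regions x four age groups with hand-picked counts."""
    y = np.array([
        [2, 5, 10, 40],
        [0, 1, 3, 12],
        [1, 0, 6, 25],
    ])
    n = np.array([
        [4000.0, 2500.0, 3000.0, 1500.0],
        [900.0, 600.0, 800.0, 400.0],
        [2000.0, 1200.0, 1800.0, 900.0],
    ])
    return CountCube(region_ids=("A", "B", "C"), scheme=four_bin_scheme, y=y, n=n)


@pytest.fixture
def uniform_standard() -> StandardPopulation:
    return StandardPopulation(np.full(4, 0.25))
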