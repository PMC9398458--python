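import numpy as np
import pytest

import promirt as P


@pytest.fixture(scope="session")
def small_bank() -> P.ParameterSet:
    """A 10-item, 5-category bank used across unit tests."""
    return P.simulate_item_bank(10, 5, seed=101)


@pytest.fixture(scope="session")
def toy_item() -> P.ItemParameters:
    return P.ItemParameters("toy", 2.0, (-1.0, 0.0, 1.0, 2.0))


@pytest.fixture(scope="session")
def small_study():
    """A small two-group study with two planted DIF items."""
    design = P.SimulationDesign(
        n_items=10,
        n_reference=2000,
        n_focal=800,
        dif_spec=(
            P.DIFSpec(2, "uniform", threshold_shift=-0.8),
            P.DIFSpec(5, "nonuniform", threshold_shift=-0.7, slope_factor=0.5),
        ),
        seed=202,
    )
    return P.simulate_two_group_study(design)


@pytest.fixture(scope="session")
def grid() -> P.QuadratureGrid:
    return P.QuadratureGrid.normal()
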