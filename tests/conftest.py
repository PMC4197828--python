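import numpy as np
import pytest

from mapktome import ArrayDesign, unit_det_shape


@pytest.fixture(scope="session")
def small_design():
    return ArrayDesign(
        comparisons=("flg_vs_ctrl", "mut_vs_wt"), replicates_per_comparison=3
    )


@pytest.fixture(scope="session")
def shape2():
    """A 2-d unit-determinant shape matrix with correlation."""
    return unit_det_shape(np.array([[1.0, 0.3], [0.3, 1.0]]))


@pytest.fixture(scope="session")
def shape3():
    return unit_det_shape(np.array([[1.0, 0.2, 0.0], [0.2, 1.0, 0.1], [0.0, 0.1, 1.0]]))
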