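import numpy as np
import pytest

from dendrint import morphology as M
from dendrint import synthetic_data as S


@pytest.fixture(scope="session")
def straight_skeleton():
    """Soma at origin plus a straight 100 µm dendrite along +x, fully central."""
    n = 11
    ids = np.arange(1, n + 1)
    parents = np.r_[-1, ids[:-1]]
    xyz = np.column_stack([np.linspace(0, 100, n), np.zeros(n), np.full(n, 25.0)])
    radius = np.full(n, 0.5)
    radius[0] = 5.0
    return M.Skeleton(ids, parents, xyz, radius, ipl_axis=(0.0, 40.0))


@pytest.fixture(scope="session")
def y_skeleton():
    """Soma with one stem that splits into two perpendicular daughters.

    Stem along +x to (20,0); daughter A continues +x to (60,0); daughter B
    goes +y to (20,40). All at central depth."""
    pts = [(0, 0), (10, 0), (20, 0),            # 1..3 stem
           (40, 0), (60, 0),                    # 4,5 daughter A
           (20, 20), (20, 40)]                  # 6,7 daughter B
    parents = [-1, 1, 2, 3, 4, 3, 6]
    xyz = np.array([(x, y, 25.0) for x, y in pts], dtype=float)
    radius = np.full(len(pts), 0.5)
    radius[0] = 5.0
    return M.Skeleton(np.arange(1, len(pts) + 1), parents, xyz, radius,
                      ipl_axis=(0.0, 40.0))


@pytest.fixture(scope="session")
def noise_stimulus():
    return S.gen_dense_noise(duration=300.0, seed=11)


@pytest.fixture(scope="session")
def alpha_skeleton():
    return S.gen_skeleton(S.OFF_TYPE_SPECS["tOff alpha"], seed=5)
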