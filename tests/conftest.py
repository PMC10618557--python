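import numpy as np
import pytest

from bnls import (
    ChainState,
    Dataset,
    Grid,
    HyperParams,
    KernelSpec,
    build_basis,
)


@pytest.fixture(scope="session")
def small_grid():
    return Grid.regular((6, 6))


@pytest.fixture(scope="session")
def small_basis(small_grid):
    return build_basis(small_grid, KernelSpec(), 0.9)


@pytest.fixture()
def tiny_problem():
    """A 3-voxel, 2-subject instance small enough for quadrature oracles."""
    rng = np.random.default_rng(42)
    grid = Grid.from_points(np.array([[-0.5, 0.0], [0.0, 0.0], [0.5, 0.0]]))
    basis = build_basis(grid, KernelSpec(inverse_scale=1.0), 0.999)
    n, m = 2, 2
    Y = rng.normal(0.5, 1.0, size=(n, grid.p))
    S = rng.standard_normal((n, m))
    data = Dataset(Y=Y, S=S, grid=grid)
    state = ChainState(
        beta=0.3 * rng.standard_normal(basis.L),
        mu=np.array([1.2, 0.7]),
        eta=np.array([0.5, -0.2]),
        gamma=np.array([1.0, 0.05]),
        w=0.4,
        sigma2=np.array([0.8, 1.3]),
        tau_mu2=0.9,
        tau2=np.array([1.1, 0.7]),
        tau_eta2=1.5,
    )
    return data, basis, state


@pytest.fixture(scope="session")
def hyper():
    return HyperParams()
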