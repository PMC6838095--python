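import numpy as np
import pytest

from shapeshift import (EvolutionaryParameters, LandmarkSpec, RegimePainting,
                        read_tree, simulate_landmarks, simulate_mvou,
                        simulate_tree, random_painting)
from shapeshift.simulate import spread_thetas


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); -- root age 2, A-B split at age 1."""
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree10():
    return simulate_tree(10, seed=101)


@pytest.fixture
def tree50():
    return simulate_tree(50, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_regime_dataset(n_tips=64, n_shifts=2, alpha=3.0, sigma2=1.0,
                        separation_sd=5.0, n_traits=3, seed=0,
                        convergent_pair=False):
    """Tree + painting + OU traits with known ground truth."""
    r = np.random.default_rng(seed)
    tree = simulate_tree(n_tips, seed=int(r.integers(2 ** 31)))
    painting = random_painting(tree, n_shifts, seed=int(r.integers(2 ** 31)))
    thetas = spread_thetas(n_shifts + 1, separation_sd, alpha, sigma2)
    if convergent_pair and n_shifts >= 2:
        ids = sorted(painting.shift_nodes.values())
        thetas[ids[-1]] = thetas[ids[-2]]
    params = EvolutionaryParameters(alpha=alpha, sigma2=sigma2, thetas=thetas)
    traits = simulate_mvou(tree, painting, params, n_traits=n_traits,
                           seed=int(r.integers(2 ** 31)))
    return tree, painting, params, traits
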