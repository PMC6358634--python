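import numpy as np
import pytest

import beamsel as bs


@pytest.fixture(scope="session")
def phantom_coarse():
    """Default phantom voxelised at 10 mm — fast, still anatomically
    structured (body, PTV, OAR, three annuli)."""
    return bs.default_phantom(10.0)


@pytest.fixture(scope="session")
def nodes12(phantom_coarse):
    return bs.generate_nodeset(12, phantom_coarse.target_point, seed=7)


@pytest.fixture(scope="session")
def dij12(nodes12, phantom_coarse):
    return bs.assemble_dij(nodes12, phantom_coarse)


@pytest.fixture(scope="session")
def objective_coarse(phantom_coarse):
    return bs.PlanObjective.from_phantom(phantom_coarse)


def random_bound_instance(rng, n_vox=None, n_bix=None):
    """A random small dose-penalty instance: matrix, importances, bounds.

    Some voxels act as targets (both bounds), the rest as normal tissue
    (maximum only); the matrix is nonnegative with a sprinkling of
    zeros, mimicking sparse beam geometry.
    """
    n_vox = n_vox or int(rng.integers(5, 31))
    n_bix = n_bix or int(rng.integers(2, 11))
    mat = rng.random((n_vox, n_bix)) * (rng.random((n_vox, n_bix)) > 0.3)
    a = rng.uniform(0.1, 5.0, n_vox)
    is_target = rng.random(n_vox) < 0.4
    d_max = rng.uniform(1.0, 10.0, n_vox)
    d_min = np.where(is_target, d_max * rng.uniform(0.3, 0.95, n_vox),
                     -np.inf)
    obj = bs.PlanObjective(np.arange(n_vox), a, d_min, d_max,
                           np.zeros(n_vox, dtype=np.int32))
    return mat, obj


def dense_objective(mat, obj):
    """Independent dense evaluation of F and its gradient for oracles."""
    def fun(w):
        d = mat @ w
        under = np.maximum(obj.d_min - d, 0.0)
        over = np.maximum(d - obj.d_max, 0.0)
        f = np.sum(obj.importance * (under ** 2 + over ** 2))
        g = mat.T @ (2.0 * obj.importance * (over - under))
        return f, g
    return fun


def beam_cost_fitness(n=8, k=3, penalty=50.0):
    """Deterministic synthetic fitness of the gene set: each candidate
    beam carries a fixed cost, with a block of equally-good (zero-cost)
    directions — mirroring real node sets where several orientations
    are interchangeable.  Genomes wasting slots on duplicate genes pay
    a penalty per missing distinct beam."""
    costs = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0][:n])

    def fitness(genome, _seed=0):
        s = sorted(set(genome))
        return float(costs[s].sum()) + penalty * (k - len(s))
    return fitness


def solver_oracle(mat, obj, w0):
    """Reference minimum from scipy's generic bound-constrained solvers.

    Runs two independent algorithms (trust-constr and L-BFGS-B) at
    tight tolerances and keeps the better optimum.
    """
    from scipy.optimize import minimize
    fun = dense_objective(mat, obj)
    bounds = [(0.0, None)] * mat.shape[1]
    best = np.inf
    for method, opts in (("L-BFGS-B", {"maxiter": 2000, "ftol": 1e-16,
                                       "gtol": 1e-12}),
                         ("trust-constr", {"maxiter": 2000, "gtol": 1e-12,
                                           "xtol": 1e-14})):
        res = minimize(fun, w0, jac=True, method=method, bounds=bounds,
                       options=opts)
        best = min(best, float(fun(res.x)[0]))
    return best
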