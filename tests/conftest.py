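import numpy as np
import pytest

from gci import load_disease_params, load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def disease_params():
    return load_disease_params()


@pytest.fixture(scope="session")
def ra_markers(fixtures):
    return fixtures["ra_table1"][0]


@pytest.fixture(scope="session")
def t2d_markers(fixtures):
    return fixtures["t2d_table1"][0]


def random_conversion_problem(rng: np.random.Generator, max_rr: float = 4.0):
    """A random, guaranteed-feasible odds-ratio conversion problem.

    Built in reverse: draw per-level penetrances in (0, 1), take the average
    lifetime risk as their frequency-weighted mean, and map them forward to
    odds ratios — so a unique penetrance solution always exists.
    """
    from gci import ConversionProblem, PenetranceSolution, odds_ratios_from_penetrances

    m = int(rng.integers(2, 5))
    freqs = rng.dirichlet(np.ones(m))
    x0 = rng.uniform(0.002, 0.2)
    rrs = np.concatenate(([1.0], rng.uniform(1.0, max_rr, m - 1)))
    x = np.minimum(x0 * rrs, 0.95)
    altr = float(freqs @ x)
    alpha = float(rng.uniform(0.0, altr))
    sol = PenetranceSolution(tuple(x), tuple(x / x[0]))
    ors = odds_ratios_from_penetrances(sol, tuple(freqs), altr, alpha)
    return ConversionProblem(ors, tuple(freqs), altr, alpha)
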