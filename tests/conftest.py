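import itertools

import numpy as np
import pytest

from figana.irt import ResponseMatrix
from figana.response_simulator import (
    PUBLISHED_RULE_DIFFICULTIES,
    SimConfig,
    demo_bank,
    qmatrix_from_bank,
    simulate_responses,
)


@pytest.fixture(scope="session")
def bank23():
    """Fixed 23-item demonstration bank (one isomorph per rule set)."""
    return demo_bank(seed=3)


@pytest.fixture(scope="session")
def q9(bank23):
    return qmatrix_from_bank(bank23, 9)


@pytest.fixture(scope="session")
def q5(bank23):
    return qmatrix_from_bank(bank23, 5)


@pytest.fixture(scope="session")
def responses23(q9):
    """2000 simulated persons answering the 23-item bank under the LLTM."""
    beta = q9.weights @ PUBLISHED_RULE_DIFFICULTIES
    return simulate_responses(beta, SimConfig(n_persons=2000, seed=11))


# --------------------------------------------------------------------------
# independent brute-force conditional-likelihood oracle (pattern enumeration)


def brute_conditional_loglik(values: np.ndarray, beta: np.ndarray) -> float:
    """Conditional log-likelihood computed from first principles.

    For each person, P(x | raw score r) = exp(-sum_i x_i beta_i) / gamma_r
    with gamma_r obtained by enumerating every response pattern of score r
    over the person's observed items.  Exponential-time; only for tiny banks.
    """
    ll = 0.0
    for row in values:
        obs = ~np.isnan(row)
        x = row[obs]
        b = beta[obs]
        k = b.size
        r = int(x.sum())
        if r == 0 or r == k:
            continue
        gamma = 0.0
        for pattern in itertools.product((0, 1), repeat=k):
            if sum(pattern) == r:
                gamma += np.exp(-float(np.dot(pattern, b)))
        ll += -float(x @ b) - np.log(gamma)
    return ll


def brute_max_conditional_loglik(values: np.ndarray) -> float:
    """Maximize the brute-force conditional log-likelihood numerically
    (first item anchored at zero), independent of the package's fitter."""
    from scipy.optimize import minimize

    n = values.shape[1]

    def nll(free):
        return -brute_conditional_loglik(values, np.concatenate([[0.0], free]))

    res = minimize(nll, np.zeros(n - 1), method="BFGS", tol=1e-12)
    return -float(res.fun)
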