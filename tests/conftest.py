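import numpy as np
import pytest

from mnvquant import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 300-eye synthetic cohort for table-level tests."""
    return simulate_cohort(CohortConfig(n_eyes=300, seed=42))


def wls_oracle(x, y, w):
    """Textbook weighted-least-squares slope/SE via the normal equations.

    Independent of the package's fitting path: weighted means, the closed
    form slope, residual variance on n-2 df, and the classical slope SE.
    """
    x, y, w = map(np.asarray, (x, y, w))
    n = x.size
    xbar = np.sum(w * x) / np.sum(w)
    ybar = np.sum(w * y) / np.sum(w)
    sxx = np.sum(w * (x - xbar) ** 2)
    beta = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    alpha = ybar - beta * xbar
    resid = y - alpha - beta * x
    sigma2 = np.sum(w * resid**2) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, alpha, se
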