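import numpy as np
import pytest

from gakcca import (
    FitConfig,
    contribution_coefficient,
    fit_gakcca,
    fit_rgcca,
    generate_case2,
    relation_measure,
)

#: Simulation-study conditions: n=100 samples, Gaussian kernel with median
#: bandwidth, Horst scheme, fully connected design, tau=0.1.
N_SAMPLES = 100
TAU = 0.1
N_REPLICATES = 50


@pytest.fixture(scope="session")
def case2_fits():
    """Kernel-model fits on independent Case II replicates (shared across tests)."""
    fits = []
    for seed in range(N_REPLICATES):
        data = generate_case2(N_SAMPLES, seed)
        fits.append(fit_gakcca(data, config=FitConfig(tau=TAU)))
    return fits


@pytest.fixture(scope="session")
def case2_relations(case2_fits):
    """Per-replicate relation measures for the three group pairs."""
    return {
        pair: np.array([relation_measure(f, *pair) for f in case2_fits])
        for pair in [(0, 1), (1, 2), (2, 0)]
    }


@pytest.fixture(scope="session")
def case2_rgcca_fits():
    """Linear-baseline fits (tau=1, standardized) on the same replicates."""
    fits = []
    for seed in range(N_REPLICATES):
        data = generate_case2(N_SAMPLES, seed)
        fits.append(fit_rgcca(data, config=FitConfig(tau=1.0)))
    return fits


def pearson(u, v):
    """Independent correlation oracle used throughout the suite."""
    return float(np.corrcoef(u, v)[0, 1])


def cca_first_correlation(X, Y):
    """Classical first canonical correlation via the generalized eigenproblem.

    Whitened cross-covariance SVD: the top singular value of
    Sxx^{-1/2} Sxy Syy^{-1/2}. Small dense blocks only.
    """
    from scipy.linalg import fractional_matrix_power, svdvals

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = Xc.shape[0]
    Sxx = Xc.T @ Xc / n
    Syy = Yc.T @ Yc / n
    Sxy = Xc.T @ Yc / n
    M = (
        fractional_matrix_power(Sxx, -0.5)
        @ Sxy
        @ fractional_matrix_power(Syy, -0.5)
    )
    return float(svdvals(np.real(M))[0])
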