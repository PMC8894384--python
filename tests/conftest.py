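import numpy as np
import pytest

import overallgene as og


@pytest.fixture
def rng():
    return np.random.default_rng(20230905)


@pytest.fixture
def ar1_23():
    return og.synth_ld(23, "ar1", 0.5)


@pytest.fixture
def weights_23x4(rng, ar1_23):
    raw = rng.standard_normal((23, 4))
    return og.WeightSet.from_raw(raw, labels=["NTR", "YFS", "METSIM", "CMC"])


def mvn_draws(R, n, rng):
    """Z ~ MVN(0, R) draws as an (n, M) matrix."""
    evals, evecs = np.linalg.eigh(R)
    chol = evecs * np.sqrt(np.clip(evals, 0.0, None))
    return rng.standard_normal((n, R.shape[0])) @ chol.T


def imhof_oracle(q, lam):
    """Slow independent tail probability by Imhof integration; returns
    (value, reported error)."""
    from scipy.integrate import quad

    lam = np.asarray(lam, float)

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val, err = quad(integrand, 0, np.inf, limit=4000, epsabs=1e-13, epsrel=1e-11)
    return 0.5 + val / np.pi, err
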