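import numpy as np
import pytest

from vbss.core import GaussianPrior, PriorBundle


@pytest.fixture
def empty_gauss():
    return GaussianPrior(np.zeros(0), np.zeros((0, 0)))


def fixed_gauss(values):
    v = np.atleast_1d(np.asarray(values, dtype=float))
    return GaussianPrior(v, np.zeros((v.size, v.size)))


@pytest.fixture
def static_priors(empty_gauss):
    """Priors for a static model with only observation parameters."""

    def make(n_phi, mean=0.0, var=1.0):
        return PriorBundle(
            theta=empty_gauss,
            phi=GaussianPrior(np.full(n_phi, mean), np.eye(n_phi) * var),
            x0=empty_gauss,
        )

    return make
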