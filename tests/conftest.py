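import numpy as np
import pytest

import subcomm as sc


@pytest.fixture
def panel2():
    return sc.StrainPanel(("A", "B"))


@pytest.fixture
def panel3():
    return sc.default_panel(3)


@pytest.fixture
def panel8():
    return sc.default_panel(8)


@pytest.fixture
def params2(panel2):
    """p=2 worked example: v({})=0, v({A})=3, v({B})=1, v({A,B})=5."""
    return sc.LandscapeParams(
        panel2, beta0=0.0, beta=np.array([3.0, 1.0]), gamma=np.array([[0.0, 1.0], [1.0, 0.0]])
    )


@pytest.fixture
def landscape2(params2):
    return sc.generate_landscape(params2)


def random_params(panel, rng, sigma=0.0, n_reps=1):
    """Random noiseless-capable landscape parameters for property tests."""
    p = panel.p
    beta = rng.normal(0, 2, p)
    g = rng.normal(0, 1, (p, p))
    gamma = np.triu(g, 1)
    gamma = gamma + gamma.T
    return sc.LandscapeParams(
        panel, beta0=rng.normal(), beta=beta, gamma=gamma,
        sigma_noise=sigma, n_reps=n_reps, seed=int(rng.integers(2**31)),
    )
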