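import numpy as np
import pytest

import sociometer as s
from sociometer import config
from sociometer.inference import FitSpec


@pytest.fixture(scope="session")
def design20():
    """Small session: 20 raters per group, 80 trials."""
    return s.GroupDesign(raters_per_group=20, seed=101)


@pytest.fixture(scope="session")
def schedule20(design20):
    return s.make_schedule(design20)


@pytest.fixture(scope="session")
def design200():
    """Recovery-scale session: 50 raters per group, 200 trials."""
    return s.GroupDesign(raters_per_group=50, seed=202)


@pytest.fixture(scope="session")
def schedule200(design200):
    return s.make_schedule(design200)


@pytest.fixture(scope="session")
def assoc_params():
    return s.AssocParams(eta=0.3, gamma=0.6, w0=0.5, w1=0.15, sigma=0.1,
                         B_choice=0.1, tau=0.2)


@pytest.fixture(scope="session")
def belief_params():
    return s.BeliefParams(lambda_acc=0.3, alpha0_min=1.3, alpha0_max=4.0,
                          w=1.5, varsigma=0.8, m_se=1.5, B_se=1.2, T=0.15,
                          B_choice=0.05)


@pytest.fixture(scope="session")
def assoc_record(assoc_params, schedule20):
    return s.simulate_participant("associative", assoc_params, schedule20, seed=7)


@pytest.fixture(scope="session")
def belief_record(belief_params, schedule20):
    return s.simulate_participant("belief", belief_params, schedule20, seed=8)


def fast_spec(model, **kw):
    """Reduced-multistart fit spec for batch tests (documented fast mode)."""
    kw.setdefault("n_starts", config.FAST_N_STARTS)
    kw.setdefault("seed", 0)
    return FitSpec(model=model, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
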