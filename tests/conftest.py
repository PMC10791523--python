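import numpy as np
import pytest

from myosim import (BehaviourMetrics, FusionParams, MechanicsParams,
                    SimParams)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def small_params():
    """A fast, fully featured run: small domain, one simulated day."""
    return SimParams(
        behaviour=BehaviourMetrics(s_mb_mean=0.5, s_mb_sd=0.2,
                                   omega_mb_sd=10.0, p_rate=2e-4),
        fusion=FusionParams(aoi_radius=15.0, t_rmax=30.0, t_mtfuse=1.5),
        mechanics=MechanicsParams(k_lat=0.1, k_nuc=0.5),
        domain_width=400.0, domain_height=400.0,
        duration=1440.0, n_myoblasts_t0=80, myotube_proportion_t0=0.1,
        seed=42)
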