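import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emanet as e

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def homogeneous_population(B=None, Sigma=None, mu=None, compliance=1.0):
    """Population model with no between-person heterogeneity, no trends, no
    occasion effects — the exact model the pooled estimator assumes."""
    k = 6
    pop = e.default_population_model()
    pop.B = np.zeros((k, k)) if B is None else np.asarray(B, dtype=float)
    pop.Sigma = np.eye(k) if Sigma is None else np.asarray(Sigma, dtype=float)
    if mu is not None:
        pop.mu = np.asarray(mu, dtype=float)
    pop.tau_B = np.zeros((k, k))
    pop.tau_mu = np.zeros(k)
    pop.trend_sd = 0.0
    pop.occasion_effects = np.zeros(5)
    pop.compliance_mean = compliance
    pop.compliance_sd = 0.0
    pop.speeder_fraction = 0.0
    pop.validate()
    return pop


@pytest.fixture(scope="session")
def small_realistic_ds():
    """10-person, 7-day study on the bounded 0-100 scale with missing prompts
    and speeder contamination — the 'looks like real data' fixture."""
    pop = e.default_population_model()
    pop.speeder_fraction = 0.05
    design = e.StudyDesign(n_participants=10, n_days=7)
    return e.simulate_study(design, pop=pop, seed=42, clip=True)


@pytest.fixture(scope="session")
def white_noise_lagged():
    """Lag table from a null study: B = 0, identity innovations."""
    pop = homogeneous_population()
    ds = e.simulate_study(e.StudyDesign(n_participants=30, n_days=10),
                          pop=pop, seed=7, clip=False)
    return e.build_lagged_table(ds)
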