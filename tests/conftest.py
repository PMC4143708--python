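import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trioskat import SimConfig, generate_cohort, run_test

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


NULL_SIM_REPS = 2000


@pytest.fixture(scope="session")
def null_pvalues():
    """P-values of both tests on fresh null cohorts (93 trios x 30 variants).

    The pure-noise trait is tested with SKAT (rho=0) and burden (rho=1),
    Beta(1,25) weights, all variants; genotypes and traits are regenerated
    each replicate.
    """
    config = SimConfig(causal_fraction=0.0, effect_scale=0.0)
    seqs = np.random.SeedSequence(20240501).spawn(NULL_SIM_REPS)
    out = {"skat": np.empty(NULL_SIM_REPS), "burden": np.empty(NULL_SIM_REPS)}
    for b, seq in enumerate(seqs):
        cohort, _ = generate_cohort(config, rng=np.random.default_rng(seq))
        for method in ("skat", "burden"):
            res = run_test(cohort, "null_trait", method=method)
            out[method][b] = res.p_value
    return out


@pytest.fixture(scope="session")
def toy_cohort():
    """Small deterministic cohort for structural tests."""
    config = SimConfig(n_trios=25, n_variants=8, seed=4242)
    cohort, truth = generate_cohort(config)
    return cohort, truth
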