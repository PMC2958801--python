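import pytest

from trustmix.design import ModelSpec, build_designs
from trustmix.mixture_gibbs import default_priors, run_chain
from trustmix.synthetic_data import default_config, generate_population


@pytest.fixture(scope="session")
def small_population():
    """60-dyad default-structure population (fast shared fixture)."""
    cfg = default_config(n_dyads=60, seed=42)
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def study_population():
    """Full 287-dyad default population."""
    cfg = default_config(seed=7)
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def fitted_chain(study_population):
    """A converged K=4 fit of the study population (shared, read-only)."""
    cfg, records = study_population
    spec = ModelSpec(K=4, P=1, D=2)
    data = build_designs(records, spec)
    chain = run_chain(data, spec, default_priors(spec),
                      n_draws=600, burn_in=400, seed=11)
    return chain, data, records
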