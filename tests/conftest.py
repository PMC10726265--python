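import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from streamocc.design import DesignMatrices, ModelSpec
from streamocc.occupancy_model import Parameters
from streamocc.synthetic_data import GeneratorConfig, TrueEffects, generate

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_toy_design(S=2, J=3, K=4, mask=None, seed=0, n_reaches=2):
    """A small hand-built design with random covariates and detections,
    for likelihood-oracle tests."""
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones((J, K), dtype=bool)
    obs = [(j, k) for j in range(J) for k in range(K) if mask[j, k]]
    obs_site = np.array([j for j, _ in obs], dtype=int)
    n_obs = len(obs)
    return DesignMatrices(
        X_det=np.column_stack([np.ones(n_obs), rng.normal(size=n_obs)]),
        det_columns=["intercept", "x"],
        det_shared=np.array([False, False]),
        X_occ=np.column_stack([np.ones(J), rng.normal(size=J)]),
        occ_columns=["intercept", "w"],
        obs_site=obs_site,
        y_obs=rng.integers(0, 2, (S, n_obs)).astype(np.int8),
        reach_index=rng.integers(0, n_reaches, J),
        site_ecoregion=np.zeros(J, dtype=int),
        n_reaches=n_reaches,
        species=tuple(f"sp{i}" for i in range(S)),
        records={},
        spec=None,
    )


def rand_params(design, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    p = Parameters.zeros(design)
    p.alpha = rng.normal(0, scale, p.alpha.shape)
    p.gamma = rng.normal(0, scale, p.gamma.shape)
    p.beta = rng.normal(0, scale, p.beta.shape)
    p.mu_alpha = rng.normal(0, scale, p.mu_alpha.shape)
    p.mu_beta = rng.normal(0, scale, p.mu_beta.shape)
    p.sigma_alpha = rng.uniform(0.2, 1.5, p.sigma_alpha.shape)
    p.sigma_beta = rng.uniform(0.2, 1.5, p.sigma_beta.shape)
    p.u = rng.normal(0, scale, p.u.shape)
    p.sigma_u = float(rng.uniform(0.2, 1.5))
    return p


def small_spec():
    """A reduced model: one detection covariate plus gear, two occurrence
    covariates, no interactions or ecoregion structure."""
    return ModelSpec(
        det_covariates=("depth",), det_quadratic=(), det_gear=True,
        det_ecoregion=False, gear_by_covariate=False,
        occ_covariates=("temperature", "rpd"), occ_interactions=(),
        occ_ecoregion=False, occ_year=False, vary_by_ecoregion=(),
    )


def small_config(seed=0, **kw):
    """A compact nested design (40 sites / 16 reaches, 2 species) for fast
    end-to-end tests."""
    defaults = dict(
        n_sites=40, n_reaches=16, site_split=(18, 22), reach_split=(7, 9),
        year_split=(8, 8), species=("sp1", "sp2"), spec=small_spec(),
        effects=TrueEffects(
            det=(("intercept", 0.0), ("gear", 1.0)),
            occ=(("intercept", 0.0), ("temperature", 0.8), ("rpd", -0.8)),
        ),
        seed=seed,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_synthetic():
    return generate(small_config(), seed=11)


@pytest.fixture(scope="session")
def default_synthetic():
    from streamocc.synthetic_data import default_config
    return generate(default_config(), seed=5)
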