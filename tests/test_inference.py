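"""HDI, posterior mode, convergence diagnostics, and the MCMC sampler."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from streamocc.design import ModelSpec
from streamocc.inference import (
    diagnostics,
    effective_sample_size,
    hdi,
    posterior_mode,
    run_mcmc,
    sample_logdensity,
    split_rhat,
)
from streamocc.synthetic_data import TrueEffects, generate

from conftest import small_config, small_spec


def hdi_oracle(x, prob):
    """All-intervals brute force: the narrowest (i, j) window holding at
    least prob of the sorted draws."""
    x = np.sort(np.asarray(x))
    n = x.size
    m = int(np.ceil(prob * n))
    best = (np.inf, None)
    for i in range(n):
        j = i + m - 1
        if j >= n:
            break
        w = x[j] - x[i]
        if w < best[0]:
            best = (w, (x[i], x[j]))
    return best[1]


class TestHDI:
    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300) if seed % 2 else rng.exponential(size=300)
        assert hdi(x, 0.9) == pytest.approx(hdi_oracle(x, 0.9), abs=0)

    def test_uniform_width(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 20000)
        lo, hi = hdi(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_symmetric_sample_close_to_equal_tailed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(np.quantile(x, 0.025), abs=0.05)
        assert hi == pytest.approx(np.quantile(x, 0.975), abs=0.05)

    def test_prob_one_spans_range(self):
        x = np.array([3.0, -1.0, 2.0, 5.0])
        assert hdi(x, 1.0) == (-1.0, 5.0)

    def test_invalid_prob_rejected(self):
        with pytest.raises(ValueError):
            hdi([1.0, 2.0], 1.5)


class TestPosteriorMode:
    def test_normal_sample_mode_near_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3, 1, 5000)
        assert posterior_mode(x) == pytest.approx(3, abs=3 / np.sqrt(5000) * 3 + 0.1)

    def test_point_mass(self):
        assert posterior_mode(np.full(200, 1.7)) == 1.7

    def test_bimodal_mode_in_heavier_component(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-2, 0.3, 7000), rng.normal(2, 0.3, 3000)])
        assert posterior_mode(x) == pytest.approx(-2, abs=0.3)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=1000)
        assert posterior_mode(x) == posterior_mode(x)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(5)
        half = rng.normal(size=200)
        chain = np.concatenate([half, half])  # identical split halves
        draws = np.tile(chain, (3, 1))
        assert split_rhat(draws) == 1.0

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(6)
        draws = np.stack([rng.normal(0, 1, 500), rng.normal(3, 1, 500)])
        assert split_rhat(draws) > 1.1

    def test_white_noise_ess_close_to_n(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(size=(2, 2000))
        ess = effective_sample_size(draws)
        assert ess == pytest.approx(4000, rel=0.2)

    def test_autocorrelated_chain_has_reduced_ess(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = np.empty((1, n))
        x[0, 0] = 0
        for t in range(1, n):
            x[0, t] = 0.9 * x[0, t - 1] + rng.normal()
        assert effective_sample_size(x) < n / 5

    def test_single_chain_warns_and_reports_nan_rhat(self):
        from streamocc.inference import PosteriorSamples
        rng = np.random.default_rng(9)
        ps = PosteriorSamples(draws=rng.normal(size=(1, 300, 2)),
                              names=["a", "b"], seed=0)
        with pytest.warns(UserWarning):
            summ = diagnostics(ps)
        assert summ["rhat"].isna().all()
        assert {"mode", "median", "hdi_low", "hdi_high"} <= set(summ.columns)


class TestAgainstArviz:
    """Cross-check the in-house diagnostics against arviz's implementations."""

    def test_split_rhat_matches_arviz_split_method(self):
        import arviz as az
        rng = np.random.default_rng(11)
        draws = np.stack([rng.normal(0, 1, 400), rng.normal(0.8, 1.1, 400)])
        ours = split_rhat(draws)
        theirs = float(az.rhat(az.convert_to_dataset(draws), method="split")["x"])
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_ess_agrees_with_arviz_on_white_noise(self):
        import arviz as az
        rng = np.random.default_rng(12)
        draws = rng.normal(size=(2, 1500))
        ours = effective_sample_size(draws)
        theirs = float(az.ess(az.convert_to_dataset(draws))["x"])
        assert ours == pytest.approx(theirs, rel=0.25)


class TestGenericSampler:
    def test_matches_dense_grid_posterior(self):
        """Kolmogorov-Smirnov distance to the exact density below 0.05."""
        logpdf = lambda x: gamma_dist.logpdf(x, a=3.0) if x > 0 else -np.inf
        draws = sample_logdensity(logpdf, x0=2.0, n_iter=22000, n_warmup=2000,
                                  seed=10)
        # dense-grid CDF oracle by trapezoid integration
        grid = np.linspace(1e-6, 25, 4001)
        dens = np.exp([gamma_dist.logpdf(g, a=3.0) for g in grid])
        cdf = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2
                                             * np.diff(grid))])
        cdf /= cdf[-1]
        xs = np.sort(draws)
        emp = np.arange(1, xs.size + 1) / xs.size
        ks = np.max(np.abs(emp - np.interp(xs, grid, cdf)))
        assert ks < 0.05


class TestRunMCMC:
    def test_same_seed_identical_draws(self, small_synthetic):
        kw = dict(n_chains=2, n_iter=60, n_warmup=30, seed=3,
                  check_convergence=False)
        a = run_mcmc(small_spec(), small_synthetic.dataset, **kw)
        b = run_mcmc(small_spec(), small_synthetic.dataset, **kw)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.names == b.names

    def test_iterations_must_exceed_warmup(self, small_synthetic):
        with pytest.raises(ValueError):
            run_mcmc(small_spec(), small_synthetic.dataset,
                     n_iter=100, n_warmup=100)

    def test_intercept_recovery_at_known_truth(self):
        """psi = p = 0.5 truth: posterior intercepts near logit 0."""
        spec = ModelSpec(det_covariates=(), det_quadratic=(), det_gear=False,
                         det_ecoregion=False, gear_by_covariate=False,
                         occ_covariates=(), occ_interactions=(),
                         occ_ecoregion=False, occ_year=False,
                         vary_by_ecoregion=())
        cfg = small_config(
            n_sites=200, n_reaches=40, site_split=(100, 100),
            reach_split=(20, 20), year_split=(20, 20), species=("sp1",),
            spec=spec, gear_missing_rate=0.0,
            effects=TrueEffects(det=(("intercept", 0.0),),
                                occ=(("intercept", 0.0),),
                                det_sd=0.0, occ_sd=0.0, sigma_u=1e-6))
        syn = generate(cfg, seed=21)
        ps = run_mcmc(spec, syn.dataset, n_chains=2, n_iter=1200,
                      n_warmup=600, seed=4, check_convergence=False)
        for name in ("mu_alpha[intercept]", "mu_beta[intercept]"):
            pooled = ps.pooled(name)
            assert abs(pooled.mean()) < 3 * pooled.std()

    def test_degenerate_all_detected_data(self, small_synthetic):
        ds = small_synthetic.dataset
        surveys = ds.surveys.copy()
        for sp in ds.species:
            surveys[f"det_{sp}"] = 1
        from streamocc.field_data import Dataset, build_encounters
        enc = build_encounters(surveys, species=ds.species,
                               site_ids=tuple(ds.sites["site_id"]))
        full = Dataset(encounters=enc, surveys=surveys, sites=ds.sites,
                       reaches=ds.reaches, species=ds.species)
        ps = run_mcmc(small_spec(), full, n_chains=2, n_iter=300,
                      n_warmup=150, seed=5, check_convergence=False)
        # occupancy intercept pushed high: median psi at mean covariates > 0.8
        from scipy.special import expit
        for sp in ds.species:
            med = np.median(ps.pooled(f"beta[{sp},intercept]"))
            assert expit(med) > 0.8

    def test_draws_dataframe_is_tidy(self, small_synthetic):
        ps = run_mcmc(small_spec(), small_synthetic.dataset, n_chains=2,
                      n_iter=40, n_warmup=20, seed=6,
                      check_convergence=False)
        df = ps.to_dataframe()
        assert set(df.columns) == {"chain", "iter", "parameter", "value"}
        assert len(df) == 2 * 20 * len(ps.names)
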