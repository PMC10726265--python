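"""Marginalized likelihood, priors, and conditional occupancy.

The central checks are against independent brute-force oracles: full
enumeration of the latent occupancy states for the likelihood, and a
scipy-based density summation for the prior.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import halfnorm, norm

from streamocc.occupancy_model import (
    PriorConfig,
    conditional_occupancy,
    detection_prob,
    log_prior,
    occurrence_prob,
    site_marginal_loglik,
    total_loglik,
)

from conftest import make_toy_design, rand_params


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_loglik(params, design):
    """Likelihood by explicit summation over every latent-state configuration."""
    psi = occurrence_prob(params, design)
    p = detection_prob(params, design)
    S, J = psi.shape
    y = design.y_obs
    lik = 0.0
    for zs in itertools.product((0, 1), repeat=S * J):
        z = np.array(zs).reshape(S, J)
        prob = 1.0
        for i in range(S):
            for j in range(J):
                prob *= psi[i, j] if z[i, j] else 1 - psi[i, j]
        for i in range(S):
            for o in range(y.shape[1]):
                j = design.obs_site[o]
                pz = z[i, j] * p[i, o]
                prob *= pz if y[i, o] else 1 - pz
        lik += prob
    return np.log(lik)


def scipy_log_prior(params, prior):
    """Prior density summed term by term with scipy distributions."""
    lp = 0.0
    for i in range(params.alpha.shape[0]):
        lp += norm.logpdf(params.alpha[i], params.mu_alpha,
                          params.sigma_alpha).sum()
        lp += norm.logpdf(params.beta[i], params.mu_beta,
                          params.sigma_beta).sum()
    lp += norm.logpdf(params.gamma, 0, prior.shared_sd).sum()
    lp += norm.logpdf(params.mu_alpha, 0, prior.hypermean_sd).sum()
    lp += norm.logpdf(params.mu_beta, 0, prior.hypermean_sd).sum()
    lp += halfnorm.logpdf(params.sigma_alpha, scale=prior.hypersd_scale).sum()
    lp += halfnorm.logpdf(params.sigma_beta, scale=prior.hypersd_scale).sum()
    lp += norm.logpdf(params.u, 0, params.sigma_u).sum()
    lp += halfnorm.logpdf(params.sigma_u, scale=prior.sigma_u_scale)
    return float(lp)


# ---------------------------------------------------------------------------
# Site marginal
# ---------------------------------------------------------------------------

class TestSiteMarginal:
    def test_certain_detection(self):
        assert site_marginal_loglik([1], 1.0, [1.0]) == pytest.approx(0.0)

    def test_uninformative_surveys(self):
        assert site_marginal_loglik([0, 0], 0.37, [0.0, 0.0]) == pytest.approx(0.0)

    def test_mixed_history(self):
        # by hand: z=1 term 0.6*0.5*0.5, z=0 term 0
        got = site_marginal_loglik([1, 0], 0.6, [0.5, 0.5])
        assert got == pytest.approx(np.log(0.15), abs=1e-12)

    def test_detection_with_zero_psi_is_minus_inf(self):
        assert site_marginal_loglik([1], 0.0, [0.5]) == -np.inf

    def test_mask_excludes_surveys(self):
        full = site_marginal_loglik([1, 0], 0.6, [0.5, 0.5])
        masked = site_marginal_loglik([1, 0, 1], 0.6, [0.5, 0.5, 0.9],
                                      mask=[True, True, False])
        assert masked == pytest.approx(full)

    def test_monotone_in_psi(self):
        # all-zero history with informative surveys: likelihood falls with psi
        grid = np.linspace(0.01, 0.99, 20)
        lls = [site_marginal_loglik([0, 0], s, [0.6, 0.7]) for s in grid]
        assert np.all(np.diff(lls) < 0)
        # any detection: likelihood rises with psi
        lls = [site_marginal_loglik([1, 0], s, [0.6, 0.7]) for s in grid]
        assert np.all(np.diff(lls) > 0)


# ---------------------------------------------------------------------------
# Total likelihood vs enumeration
# ---------------------------------------------------------------------------

class TestTotalLoglik:
    @pytest.mark.parametrize("S,J,seed", [(1, 1, 0), (1, 2, 1), (2, 2, 2),
                                          (2, 3, 3), (2, 3, 4)])
    def test_matches_enumeration_oracle(self, S, J, seed):
        design = make_toy_design(S=S, J=J, K=4, seed=seed)
        params = rand_params(design, seed=seed + 100)
        assert total_loglik(params, design) == pytest.approx(
            brute_force_loglik(params, design), abs=1e-12)

    def test_matches_enumeration_with_masked_surveys(self):
        mask = np.array([[True, True, False, False],
                         [True, False, True, False],
                         [True, True, True, True]])
        design = make_toy_design(S=2, J=3, K=4, mask=mask, seed=9)
        params = rand_params(design, seed=42)
        assert total_loglik(params, design) == pytest.approx(
            brute_force_loglik(params, design), abs=1e-12)

    def test_single_site_single_species_reduces_to_site_marginal(self):
        design = make_toy_design(S=1, J=1, K=4, seed=5)
        params = rand_params(design, seed=6)
        psi = occurrence_prob(params, design)[0, 0]
        p = detection_prob(params, design)[0]
        assert total_loglik(params, design) == pytest.approx(
            site_marginal_loglik(design.y_obs[0], psi, p), abs=1e-10)

    def test_probability_conservation(self):
        # 1 species, 2 sites, 2 surveys each: exp(loglik) sums to one over
        # every possible encounter array
        design = make_toy_design(S=1, J=2, K=2, seed=7)
        params = rand_params(design, seed=8)
        total = 0.0
        for ys in itertools.product((0, 1), repeat=4):
            design.y_obs = np.array(ys, dtype=np.int8).reshape(1, 4)
            total += np.exp(total_loglik(params, design))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_species_relabeling_equivariance(self):
        design = make_toy_design(S=3, J=4, K=4, seed=10)
        params = rand_params(design, seed=11)
        base = total_loglik(params, design)
        perm = [2, 0, 1]
        design.y_obs = design.y_obs[perm]
        params.alpha = params.alpha[perm]
        params.beta = params.beta[perm]
        params.u = params.u[:, perm]
        assert total_loglik(params, design) == pytest.approx(base, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        design = make_toy_design(S=2, J=2, seed=1)
        params = rand_params(make_toy_design(S=3, J=2, seed=1), seed=2)
        with pytest.raises(ValueError):
            total_loglik(params, design)


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------

class TestLogPrior:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_oracle(self, seed):
        design = make_toy_design(S=3, J=4, seed=seed)
        params = rand_params(design, seed=seed + 50)
        prior = PriorConfig()
        assert log_prior(params, prior) == pytest.approx(
            scipy_log_prior(params, prior), abs=1e-10)

    def test_maximized_at_hypermeans(self):
        design = make_toy_design(S=2, J=3, seed=0)
        params = rand_params(design, seed=1)
        params.alpha = np.tile(params.mu_alpha, (2, 1))
        params.beta = np.tile(params.mu_beta, (2, 1))
        params.u[:] = 0.0
        at_mode = log_prior(params)
        shifted = params.copy()
        shifted.alpha[0, 0] += 1.0
        assert log_prior(shifted) < at_mode
        # doubling a deflection moves further down the density
        shifted2 = params.copy()
        shifted2.alpha[0, 0] += 2.0
        assert log_prior(shifted2) < log_prior(shifted)

    def test_nonpositive_sigma_is_minus_inf(self):
        design = make_toy_design(S=2, J=3, seed=0)
        params = rand_params(design, seed=1)
        params.sigma_u = -0.5
        assert log_prior(params) == -np.inf


class TestConditionalOccupancy:
    def test_any_detection_gives_one(self):
        assert conditional_occupancy([0, 1], 0.3, [0.5, 0.5]) == 1.0

    def test_bayes_update_all_zero(self):
        got = conditional_occupancy([0, 0], 0.5, [0.5, 0.5])
        assert got == pytest.approx(0.2)

    def test_uninformative_surveys_return_psi(self):
        assert conditional_occupancy([0, 0], 0.37, [0.0, 0.0]) == pytest.approx(0.37)
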