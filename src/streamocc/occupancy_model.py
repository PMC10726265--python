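"""Single-season multispecies occupancy likelihood and priors.

The latent occurrence state z[i, j] of species i at site j is Bernoulli(psi_ij)
and each survey detection y[i, j, k] is Bernoulli(z_ij * p_ijk): an observed 1
proves presence, an all-zero history is ambiguous between absence and missed
detection.  Both probabilities are logistic regressions on the design
matrices; species coefficients are deflections around community hypermeans
(alpha_ic ~ Normal(mu_alpha_c, sigma_alpha_c), likewise beta), gear x covariate
detection coefficients are shared among species, and a reach random intercept
u ~ Normal(0, sigma_u) absorbs spatial correlation of sites nested in a reach.

The latent z is marginalized analytically: for one site,

    L = psi * prod_k p^y (1-p)^(1-y) + (1 - psi) * 1[all y = 0],

summed over conducted surveys only (masked slots contribute nothing).
Sampling z is never required; ``conditional_occupancy`` recovers
Pr(z=1 | data) when a posterior occupancy state is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .design import DesignMatrices

__all__ = [
    "Parameters",
    "PriorConfig",
    "site_marginal_loglik",
    "total_loglik",
    "log_prior",
    "conditional_occupancy",
]

_PCLIP = 1e-12

_HALFNORM_CONST = 0.5 * np.log(2.0 / np.pi)


def _norm_logpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _halfnorm_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return np.sum(_HALFNORM_CONST - np.log(scale) - 0.5 * (x / scale) ** 2)


@dataclass
class PriorConfig:
    """Weakly informative defaults on the logit scale.

    Hypermeans ~ Normal(0, 2); hyper-SDs and the reach-intercept SD ~
    half-Normal(1); shared gear x covariate coefficients ~ Normal(0, 2).
    All four scales are configurable.
    """

    hypermean_sd: float = 2.0
    hypersd_scale: float = 1.0
    shared_sd: float = 2.0
    sigma_u_scale: float = 1.0


@dataclass
class Parameters:
    """All model parameters for one spec/design.

    alpha[i, c]  species detection coefficients (species-varying columns)
    gamma[c']    shared gear x covariate detection coefficients
    beta[i, c]   species occurrence coefficients
    mu_/sigma_*  community hypermean and hyper-SD per column
    u[r, i]      reach random intercept (each reach lies in one ecoregion, so
                 the reach x species grid already carries the ecoregion split)
    sigma_u      reach-intercept SD
    """

    alpha: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    mu_alpha: np.ndarray
    sigma_alpha: np.ndarray
    mu_beta: np.ndarray
    sigma_beta: np.ndarray
    u: np.ndarray
    sigma_u: float

    @classmethod
    def zeros(cls, design: DesignMatrices) -> "Parameters":
        S = design.n_species
        cd = int((~design.det_shared).sum())
        csh = int(design.det_shared.sum())
        co = design.X_occ.shape[1]
        return cls(
            alpha=np.zeros((S, cd)),
            gamma=np.zeros(csh),
            beta=np.zeros((S, co)),
            mu_alpha=np.zeros(cd),
            sigma_alpha=np.full(cd, 0.5),
            mu_beta=np.zeros(co),
            sigma_beta=np.full(co, 0.5),
            u=np.zeros((design.n_reaches, S)),
            sigma_u=0.5,
        )

    def copy(self) -> "Parameters":
        return Parameters(
            alpha=self.alpha.copy(), gamma=self.gamma.copy(),
            beta=self.beta.copy(), mu_alpha=self.mu_alpha.copy(),
            sigma_alpha=self.sigma_alpha.copy(), mu_beta=self.mu_beta.copy(),
            sigma_beta=self.sigma_beta.copy(), u=self.u.copy(),
            sigma_u=float(self.sigma_u),
        )

    # -- flat named-vector view (serialization, posterior storage) ----------
    def flatten(self) -> np.ndarray:
        return np.concatenate([
            self.alpha.ravel(), self.gamma.ravel(), self.beta.ravel(),
            self.mu_alpha, self.sigma_alpha, self.mu_beta, self.sigma_beta,
            self.u.ravel(), [self.sigma_u],
        ])

    def names(self, design: DesignMatrices) -> list:
        sp = design.species
        det_sp = [c for c, sh in zip(design.det_columns, design.det_shared) if not sh]
        det_sh = [c for c, sh in zip(design.det_columns, design.det_shared) if sh]
        occ = design.occ_columns
        out = []
        out += [f"alpha[{s},{c}]" for s in sp for c in det_sp]
        out += [f"gamma[{c}]" for c in det_sh]
        out += [f"beta[{s},{c}]" for s in sp for c in occ]
        out += [f"mu_alpha[{c}]" for c in det_sp]
        out += [f"sigma_alpha[{c}]" for c in det_sp]
        out += [f"mu_beta[{c}]" for c in occ]
        out += [f"sigma_beta[{c}]" for c in occ]
        out += [f"u[{r},{s}]" for r in range(self.u.shape[0]) for s in sp]
        out += ["sigma_u"]
        return out


# ---------------------------------------------------------------------------
# Linear predictors
# ---------------------------------------------------------------------------

def detection_prob(params: Parameters, design: DesignMatrices) -> np.ndarray:
    """p[i, obs]: per-species detection probability for every conducted survey."""
    Xsp = design.X_det[:, ~design.det_shared]
    Xsh = design.X_det[:, design.det_shared]
    eta = params.alpha @ Xsp.T + (Xsh @ params.gamma)[None, :]
    return expit(eta)


def occurrence_prob(params: Parameters, design: DesignMatrices) -> np.ndarray:
    """psi[i, j]: per-species occurrence probability at every site."""
    eta = params.beta @ design.X_occ.T + params.u[design.reach_index, :].T
    return expit(eta)


# ---------------------------------------------------------------------------
# Marginal likelihood
# ---------------------------------------------------------------------------

def site_marginal_loglik(y_row, psi: float, p_row, mask=None) -> float:
    """Log-likelihood of one species' encounter history at one site.

    Marginalizes the latent occupancy state exactly.  Impossible data
    (a detection with psi = 0 or p = 0) yields -inf rather than an exception.
    """
    y = np.asarray(y_row, dtype=float)
    p = np.asarray(p_row, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        y, p = y[m], p[m]
    if np.any((p < 0) | (p > 1)) or not (0 <= psi <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        det = np.sum(np.where(y > 0, np.log(p), np.log1p(-p)))
        occupied = np.log(psi) + det if psi > 0 else -np.inf
        if y.sum() > 0:
            return float(occupied)
        empty = np.log1p(-psi) if psi < 1 else -np.inf
    return float(np.logaddexp(occupied, empty))


def _species_site_logliks(y, psi, p, obs_site, n_sites) -> np.ndarray:
    """Vectorized per-site marginal log-likelihood for one species."""
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    psi = np.clip(psi, _PCLIP, 1 - _PCLIP)
    det_terms = y * np.log(p) + (1 - y) * np.log1p(-p)
    sum_det = np.bincount(obs_site, weights=det_terms, minlength=n_sites)
    n_det = np.bincount(obs_site, weights=y.astype(float), minlength=n_sites)
    occupied = np.log(psi) + sum_det
    return np.where(n_det > 0, occupied,
                    np.logaddexp(occupied, np.log1p(-psi)))


def total_loglik(params: Parameters, design: DesignMatrices) -> float:
    """Marginal log-likelihood summed over species and sites."""
    p = detection_prob(params, design)
    psi = occurrence_prob(params, design)
    S, J = psi.shape
    if design.y_obs.shape[0] != S:
        raise ValueError("species dimension mismatch between data and parameters")
    total = 0.0
    for i in range(S):
        total += _species_site_logliks(
            design.y_obs[i], psi[i], p[i], design.obs_site, J
        ).sum()
    return float(total)


def log_prior(params: Parameters, prior: PriorConfig | None = None) -> float:
    """Log prior density: species deflections around hypermeans, reach
    intercepts around zero, weakly informative hyperpriors."""
    prior = prior or PriorConfig()
    if (np.any(params.sigma_alpha <= 0) or np.any(params.sigma_beta <= 0)
            or params.sigma_u <= 0):
        return -np.inf
    lp = 0.0
    lp += np.sum(_norm_logpdf(params.alpha, params.mu_alpha[None, :],
                              params.sigma_alpha[None, :]))
    lp += np.sum(_norm_logpdf(params.beta, params.mu_beta[None, :],
                              params.sigma_beta[None, :]))
    lp += np.sum(_norm_logpdf(params.gamma, 0.0, prior.shared_sd))
    lp += np.sum(_norm_logpdf(params.mu_alpha, 0.0, prior.hypermean_sd))
    lp += np.sum(_norm_logpdf(params.mu_beta, 0.0, prior.hypermean_sd))
    lp += _halfnorm_logpdf(params.sigma_alpha, prior.hypersd_scale)
    lp += _halfnorm_logpdf(params.sigma_beta, prior.hypersd_scale)
    lp += np.sum(_norm_logpdf(params.u, 0.0, params.sigma_u))
    lp += _halfnorm_logpdf(params.sigma_u, prior.sigma_u_scale)
    return float(lp)


def conditional_occupancy(y_row, psi: float, p_row, mask=None) -> float:
    """Pr(z = 1 | encounter history): 1 after any detection, otherwise the
    Bayes update of psi against the all-zero history."""
    y = np.asarray(y_row, dtype=float)
    p = np.asarray(p_row, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        y, p = y[m], p[m]
    if np.any((p < 0) | (p > 1)) or not (0 <= psi <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if y.sum() > 0:
        return 1.0
    q = float(np.prod(1 - p))
    return psi * q / (psi * q + (1 - psi))
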