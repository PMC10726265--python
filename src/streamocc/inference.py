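"""Posterior sampling and summarization.

The posterior is explored with a component-wise adaptive random-walk
Metropolis sampler operating on the marginalized likelihood: species
coefficients, shared gear x covariate coefficients and reach intercepts get
scalar random-walk updates with per-parameter scales adapted during warmup
toward a 0.35 acceptance rate; community hypermeans are updated by their
conjugate Gibbs draw; hyper-SDs take log-scale random-walk steps.  Cached
linear predictors make each scalar update touch only the affected species'
likelihood, so a sweep costs O(parameters x surveys).

Summaries follow the reporting conventions for this model class: posterior
mode ("most likely value") from a Gaussian-kernel density with Silverman
bandwidth on the pooled chains, and 95% highest density intervals (the
shortest interval holding the mass).  Convergence is monitored with split
R-hat (floored at 1.0) and effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from .design import DesignMatrices, ModelSpec, build_design
from .field_data import Dataset
from .occupancy_model import Parameters, PriorConfig, _norm_logpdf

__all__ = [
    "PosteriorSamples",
    "run_mcmc",
    "hdi",
    "posterior_mode",
    "diagnostics",
    "split_rhat",
    "effective_sample_size",
    "sample_logdensity",
]

_TARGET_ACCEPT = 0.35
_ADAPT_BATCH = 50


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Per-chain posterior draws with a bijective parameter-name map."""

    draws: np.ndarray           # (chains, kept iterations, parameters)
    names: list
    seed: int
    accept_rates: dict = field(default_factory=dict)
    design: DesignMatrices | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, iterations)."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: chain, iter, parameter, value."""
        C, N, P = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(C), N * P),
            "iter": np.tile(np.repeat(np.arange(N), P), C),
            "parameter": np.tile(self.names, C * N),
            "value": self.draws.ravel(),
        })


# ---------------------------------------------------------------------------
# Interval and point summaries
# ---------------------------------------------------------------------------

def hdi(samples, prob: float = 0.95):
    """Highest density interval: the shortest interval containing
    ``ceil(prob * n)`` of the sorted draws."""
    if not (0 < prob <= 1):
        raise ValueError("prob must lie in (0, 1]")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least two draws")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + m - 1])


def posterior_mode(samples) -> float:
    """Argmax of a Gaussian-KDE (Silverman bandwidth) over the pooled draws,
    evaluated on a fixed 512-point grid — a deterministic 'most likely value'."""
    x = np.asarray(samples, dtype=float).ravel()
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(chains, n) -> (2*chains, n//2), dropping an odd trailing draw."""
    C, N = draws.shape
    half = N // 2
    return np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)


def split_rhat(draws: np.ndarray) -> float:
    """Split potential-scale-reduction factor, floored at 1.0.

    ``draws`` has shape (chains, iterations).  Values above ~1.1 indicate the
    chains have not mixed.
    """
    x = _split_chains(np.asarray(draws, dtype=float))
    m, n = x.shape
    if n < 2:
        return np.nan
    chain_means = x.mean(axis=1)
    B = n * chain_means.var(ddof=1)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(max(1.0, np.sqrt(var_plus / W)))


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk effective sample size from summed autocorrelations (Geyer initial
    positive sequence), over split chains."""
    x = _split_chains(np.asarray(draws, dtype=float))
    m, n = x.shape
    if n < 4:
        return np.nan
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        return np.nan
    B = n * x.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    # mean autocovariance across chains per lag
    acov = np.empty((m, n))
    for c in range(m):
        d = x[c] - x[c].mean()
        full = np.correlate(d, d, mode="full")[n - 1:]
        acov[c] = full / n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
        t += 2
    return float(min(m * n, m * n / tau))


def diagnostics(ps: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter summary: mode, median, 95% HDI, split R-hat, ESS.

    With a single chain R-hat cannot be computed and is reported as NaN with
    a convergence flag raised.
    """
    rows = []
    single = ps.n_chains < 2
    if single:
        warnings.warn("single chain: R-hat unavailable", stacklevel=2)
    for idx, name in enumerate(ps.names):
        d = ps.draws[:, :, idx]
        pooled = d.ravel()
        lo, hi = hdi(pooled, 0.95)
        rhat = np.nan if single else split_rhat(d)
        rows.append({
            "parameter": name,
            "mode": posterior_mode(pooled),
            "median": float(np.median(pooled)),
            "hdi_low": lo,
            "hdi_high": hi,
            "rhat": rhat,
            "ess": effective_sample_size(d),
        })
    out = pd.DataFrame(rows)
    out["converged"] = out["rhat"] <= 1.1
    return out


# ---------------------------------------------------------------------------
# Generic 1-D sampler (used for sampler-correctness checks and toy posteriors)
# ---------------------------------------------------------------------------

def sample_logdensity(logpdf, x0: float, n_iter: int, n_warmup: int,
                      seed: int = 0, scale: float = 1.0) -> np.ndarray:
    """Adaptive random-walk Metropolis on one scalar log-density."""
    rng = np.random.default_rng(seed)
    x = float(x0)
    lp = logpdf(x)
    out = np.empty(n_iter - n_warmup)
    acc = 0
    for it in range(n_iter):
        prop = x + rng.normal(0, scale)
        lpp = logpdf(prop)
        if np.log(rng.uniform()) < lpp - lp:
            x, lp = prop, lpp
            acc += 1
        if it < n_warmup and (it + 1) % _ADAPT_BATCH == 0:
            rate = acc / _ADAPT_BATCH
            scale *= np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
            acc = 0
        if it >= n_warmup:
            out[it - n_warmup] = x
    return out


# ---------------------------------------------------------------------------
# The occupancy-model sampler
# ---------------------------------------------------------------------------

_CLIP = 1e-12


class _Chain:
    """One chain's state: parameters, cached per-site likelihood pieces,
    per-parameter step scales.

    The marginal site likelihood factorizes into a detection part (sum of
    Bernoulli log-terms over a site's surveys, depending only on eta_det) and
    an occupancy part (psi, depending only on eta_occ), so each scalar update
    recomputes only the piece it perturbs: occurrence-coefficient updates
    reuse the cached detection sums, reach-intercept updates touch only the
    sites of that reach.
    """

    def __init__(self, design: DesignMatrices, prior: PriorConfig,
                 rng: np.random.Generator, jitter: float = 0.1):
        self.d = design
        self.prior = prior
        self.rng = rng
        self.Xsp = np.ascontiguousarray(design.X_det[:, ~design.det_shared])
        self.Xsh = np.ascontiguousarray(design.X_det[:, design.det_shared])
        self.Xocc = design.X_occ
        self.y = design.y_obs.astype(float)
        self.obs_site = design.obs_site
        self.J = design.n_sites
        self.S = design.n_species
        self.R = design.n_reaches
        self.site_eta_reach = design.reach_index
        # per-site detection count (data, fixed)
        self.n_det = np.stack([
            np.bincount(self.obs_site, weights=self.y[i], minlength=self.J)
            for i in range(self.S)])

        p = Parameters.zeros(design)
        p.alpha += rng.normal(0, jitter, p.alpha.shape)
        p.gamma += rng.normal(0, jitter, p.gamma.shape)
        p.beta += rng.normal(0, jitter, p.beta.shape)
        p.u += rng.normal(0, jitter, p.u.shape)
        p.mu_alpha += rng.normal(0, jitter, p.mu_alpha.shape)
        p.mu_beta += rng.normal(0, jitter, p.mu_beta.shape)
        p.sigma_alpha = np.abs(p.sigma_alpha + rng.normal(0, jitter, p.sigma_alpha.shape))
        p.sigma_beta = np.abs(p.sigma_beta + rng.normal(0, jitter, p.sigma_beta.shape))
        self.p = p

        self.eta_det = p.alpha @ self.Xsp.T + (self.Xsh @ p.gamma)[None, :]
        self.eta_occ = p.beta @ self.Xocc.T + p.u[self.site_eta_reach, :].T
        self.psi = np.clip(expit(self.eta_occ), _CLIP, 1 - _CLIP)
        self.sum_det = np.stack([self._det_sums(i, self.eta_det[i])
                                 for i in range(self.S)])
        self.ll_sites = np.stack([
            self._site_ll(i, self.psi[i], self.sum_det[i])
            for i in range(self.S)])
        self.ll = self.ll_sites.sum(axis=1)

        # per-parameter proposal scales and acceptance counters
        self.sc = {
            "alpha": np.full(p.alpha.shape, 0.4),
            "gamma": np.full(p.gamma.shape, 0.4),
            "beta": np.full(p.beta.shape, 0.4),
            "u": np.full(p.u.shape, 0.4),
            "lsig_alpha": np.full(p.sigma_alpha.shape, 0.4),
            "lsig_beta": np.full(p.sigma_beta.shape, 0.4),
            "lsig_u": np.full((), 0.4),
        }
        self.acc = {k: np.zeros(v.shape) for k, v in self.sc.items()}
        self.tries = {k: np.zeros(v.shape) for k, v in self.sc.items()}

    def _det_sums(self, i, eta_det_i) -> np.ndarray:
        """Per-site sum of Bernoulli detection log-terms for one species."""
        pdet = np.clip(expit(eta_det_i), _CLIP, 1 - _CLIP)
        terms = self.y[i] * np.log(pdet) + (1 - self.y[i]) * np.log1p(-pdet)
        return np.bincount(self.obs_site, weights=terms, minlength=self.J)

    def _site_ll(self, i, psi, sum_det) -> np.ndarray:
        occupied = np.log(psi) + sum_det
        return np.where(self.n_det[i] > 0, occupied,
                        np.logaddexp(occupied, np.log1p(-psi)))

    # -- scalar Metropolis helpers -------------------------------------------
    def _accept(self, log_ratio: float) -> bool:
        return np.log(self.rng.uniform()) < log_ratio

    def _set_det(self, i, eta, sums, sites) -> None:
        self.eta_det[i] = eta
        self.sum_det[i] = sums
        self.ll_sites[i] = sites
        self.ll[i] = sites.sum()

    def sweep(self) -> None:
        p, rng = self.p, self.rng
        pr = self.prior

        # species detection coefficients
        for i in range(self.S):
            for c in range(p.alpha.shape[1]):
                delta = rng.normal(0, self.sc["alpha"][i, c])
                new_eta = self.eta_det[i] + delta * self.Xsp[:, c]
                new_sums = self._det_sums(i, new_eta)
                new_sites = self._site_ll(i, self.psi[i], new_sums)
                new_ll = new_sites.sum()
                a = p.alpha[i, c]
                dprior = (_norm_logpdf(a + delta, p.mu_alpha[c], p.sigma_alpha[c])
                          - _norm_logpdf(a, p.mu_alpha[c], p.sigma_alpha[c]))
                self.tries["alpha"][i, c] += 1
                if self._accept(new_ll - self.ll[i] + dprior):
                    p.alpha[i, c] = a + delta
                    self._set_det(i, new_eta, new_sums, new_sites)
                    self.acc["alpha"][i, c] += 1

        # shared gear x covariate coefficients (touch every species)
        for c in range(p.gamma.size):
            delta = rng.normal(0, self.sc["gamma"][c])
            col = self.Xsh[:, c]
            new_eta = self.eta_det + delta * col[None, :]
            new_sums = np.stack([self._det_sums(i, new_eta[i])
                                 for i in range(self.S)])
            new_sites = np.stack([self._site_ll(i, self.psi[i], new_sums[i])
                                  for i in range(self.S)])
            new_ll = new_sites.sum(axis=1)
            g = p.gamma[c]
            dprior = (_norm_logpdf(g + delta, 0.0, pr.shared_sd)
                      - _norm_logpdf(g, 0.0, pr.shared_sd))
            self.tries["gamma"][c] += 1
            if self._accept(new_ll.sum() - self.ll.sum() + dprior):
                p.gamma[c] = g + delta
                self.eta_det = new_eta
                self.sum_det = new_sums
                self.ll_sites = new_sites
                self.ll = new_ll
                self.acc["gamma"][c] += 1

        # species occurrence coefficients (detection sums are unchanged)
        for i in range(self.S):
            for c in range(p.beta.shape[1]):
                delta = rng.normal(0, self.sc["beta"][i, c])
                new_eta = self.eta_occ[i] + delta * self.Xocc[:, c]
                new_psi = np.clip(expit(new_eta), _CLIP, 1 - _CLIP)
                new_sites = self._site_ll(i, new_psi, self.sum_det[i])
                new_ll = new_sites.sum()
                b = p.beta[i, c]
                dprior = (_norm_logpdf(b + delta, p.mu_beta[c], p.sigma_beta[c])
                          - _norm_logpdf(b, p.mu_beta[c], p.sigma_beta[c]))
                self.tries["beta"][i, c] += 1
                if self._accept(new_ll - self.ll[i] + dprior):
                    p.beta[i, c] = b + delta
                    self.eta_occ[i] = new_eta
                    self.psi[i] = new_psi
                    self.ll_sites[i] = new_sites
                    self.ll[i] = new_ll
                    self.acc["beta"][i, c] += 1

        # reach random intercepts: reaches partition the sites, so all of a
        # species' intercepts are independent scalar updates done in one
        # vectorized pass (accept/reject per reach)
        ridx = self.site_eta_reach
        for i in range(self.S):
            delta = rng.normal(0, self.sc["u"][:, i])
            new_eta = self.eta_occ[i] + delta[ridx]
            new_psi = np.clip(expit(new_eta), _CLIP, 1 - _CLIP)
            occ = np.log(new_psi) + self.sum_det[i]
            new_sites = np.where(self.n_det[i] > 0, occ,
                                 np.logaddexp(occ, np.log1p(-new_psi)))
            dll_r = np.bincount(ridx, weights=new_sites - self.ll_sites[i],
                                minlength=self.R)
            v = p.u[:, i]
            dprior = (_norm_logpdf(v + delta, 0.0, p.sigma_u)
                      - _norm_logpdf(v, 0.0, p.sigma_u))
            accept_r = np.log(rng.uniform(size=self.R)) < dll_r + dprior
            self.tries["u"][:, i] += 1
            if accept_r.any():
                m = accept_r[ridx]
                self.eta_occ[i, m] = new_eta[m]
                self.psi[i, m] = new_psi[m]
                self.ll_sites[i, m] = new_sites[m]
                self.ll[i] = self.ll_sites[i].sum()
                p.u[accept_r, i] = v[accept_r] + delta[accept_r]
                self.acc["u"][accept_r, i] += 1

        # hypermeans: conjugate Gibbs given deflections and hyper-SDs
        s0 = pr.hypermean_sd
        for mu, sig, coef in ((p.mu_alpha, p.sigma_alpha, p.alpha),
                              (p.mu_beta, p.sigma_beta, p.beta)):
            S = coef.shape[0]
            prec = S / sig ** 2 + 1.0 / s0 ** 2
            mean = (coef.sum(axis=0) / sig ** 2) / prec
            mu[:] = mean + rng.normal(size=mu.size) / np.sqrt(prec)

        # hyper-SDs: log-scale random walk (half-Normal prior + Jacobian)
        for key, sig_arr, mu_arr, coef, scale0 in (
                ("lsig_alpha", p.sigma_alpha, p.mu_alpha, p.alpha, pr.hypersd_scale),
                ("lsig_beta", p.sigma_beta, p.mu_beta, p.beta, pr.hypersd_scale)):
            for c in range(sig_arr.size):
                ls = np.log(sig_arr[c])
                lsp = ls + rng.normal(0, self.sc[key][c])
                new_sig = np.exp(lsp)
                old = np.sum(_norm_logpdf(coef[:, c], mu_arr[c], sig_arr[c]))
                new = np.sum(_norm_logpdf(coef[:, c], mu_arr[c], new_sig))
                dprior = (-0.5 * (new_sig / scale0) ** 2
                          + 0.5 * (sig_arr[c] / scale0) ** 2)
                self.tries[key][c] += 1
                if self._accept(new - old + dprior + (lsp - ls)):
                    sig_arr[c] = new_sig
                    self.acc[key][c] += 1

        # reach-intercept SD
        ls = np.log(p.sigma_u)
        lsp = ls + rng.normal(0, self.sc["lsig_u"])
        new_sig = np.exp(lsp)
        old = np.sum(_norm_logpdf(p.u, 0.0, p.sigma_u)) - 0.5 * (p.sigma_u / pr.sigma_u_scale) ** 2
        new = np.sum(_norm_logpdf(p.u, 0.0, new_sig)) - 0.5 * (new_sig / pr.sigma_u_scale) ** 2
        self.tries["lsig_u"] += 1
        if self._accept(new - old + (lsp - ls)):
            p.sigma_u = float(new_sig)
            self.acc["lsig_u"] += 1

    def adapt(self) -> None:
        """Batch adaptation of proposal scales toward the target rate."""
        for k in self.sc:
            tries = np.maximum(self.tries[k], 1)
            rate = self.acc[k] / tries
            self.sc[k] = self.sc[k] * np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
            self.acc[k][...] = 0
            self.tries[k][...] = 0

    def acceptance(self) -> dict:
        return {k: float(self.acc[k].sum() / max(self.tries[k].sum(), 1))
                for k in self.sc}


def run_mcmc(spec: ModelSpec, data: Dataset, n_chains: int = 3,
             n_iter: int = 4000, n_warmup: int = 2000, seed: int = 0,
             prior: PriorConfig | None = None, thin: int = 1,
             design: DesignMatrices | None = None,
             check_convergence: bool = True) -> PosteriorSamples:
    """Fit the occupancy model by MCMC; reproducible given ``seed``.

    ``n_iter`` is the total iteration count per chain and ``n_warmup`` of
    those are discarded (and used for step-size adaptation).  A warning is
    emitted when any split R-hat exceeds 1.1.
    """
    if n_iter <= n_warmup:
        raise ValueError("n_iter must exceed n_warmup")
    prior = prior or PriorConfig()
    if design is None:
        design = build_design(data, spec)

    template = Parameters.zeros(design)
    names = template.names(design)
    P = template.flatten().size
    kept = (n_iter - n_warmup) // thin
    draws = np.empty((n_chains, kept, P))
    acc_all = {}

    seed_seq = np.random.SeedSequence(seed)
    for c, child in enumerate(seed_seq.spawn(n_chains)):
        rng = np.random.default_rng(child)
        chain = None
        for _attempt in range(10):
            chain = _Chain(design, prior, rng)
            if np.all(np.isfinite(chain.ll)):
                break
        else:
            raise RuntimeError("non-finite log-posterior at initialization")
        kept_i = 0
        for it in range(n_iter):
            chain.sweep()
            if it < n_warmup:
                if (it + 1) % _ADAPT_BATCH == 0:
                    chain.adapt()
            elif (it - n_warmup) % thin == 0 and kept_i < kept:
                draws[c, kept_i] = chain.p.flatten()
                kept_i += 1
        acc_all[f"chain{c}"] = chain.acceptance()

    ps = PosteriorSamples(draws=draws, names=names, seed=seed,
                          accept_rates=acc_all, design=design)
    if check_convergence and n_chains >= 2:
        rhats = np.array([split_rhat(draws[:, :, j]) for j in range(P)])
        bad = int(np.sum(rhats > 1.1))
        if bad:
            warnings.warn(
                f"{bad}/{P} parameters have split R-hat > 1.1; "
                "consider longer chains", stacklevel=2)
    return ps
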