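"""Synthetic datasets with the study's nested design and known parameters.

The generator emulates the field design: 153 riffle-run-pool sites nested in
61 stream reaches split between the Arbuckle Uplift (64 sites) and Ozark
Highlands (89 sites) ecoregions, up to two gears (seining, snorkeling) x two
temporal occasions per site, and five taxa.  Covariates are drawn as
truncated Normals matched to the per-ecoregion means/SDs/ranges of the field
covariate summary table (drainage area is drawn log-normal, moment-matched
and rejection-truncated to its observed range).  Detections are then the
occupancy model run forward: reach intercepts ~ Normal(0, sigma_u), species
coefficients ~ Normal(hypermean, deflection SD), z ~ Bernoulli(psi),
y ~ Bernoulli(z * p) per conducted survey.

Every recovery test in the package draws its data here, so the true
parameters behind each dataset are always returned alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .design import ModelSpec, build_design, full_spec
from .field_data import (
    ARBUCKLE,
    OZARK,
    Dataset,
    SPECIES_DEFAULT,
    ValidationError,
    build_encounters,
    compute_seepage,
    validate_dataset,
)
from .occupancy_model import Parameters, detection_prob, occurrence_prob

__all__ = [
    "CovariateDist",
    "TrueEffects",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_config",
    "generate",
    "summarize_design",
]


@dataclass(frozen=True)
class CovariateDist:
    """Mean/SD/range of one covariate in one ecoregion (natural units)."""

    mean: float
    sd: float
    lo: float
    hi: float
    lognormal: bool = False


# Per-ecoregion covariate summaries (mean, SD, range) from the field study.
# Two entries are corrected obvious misprints: the Ozark pool row (54 +/- 26 %,
# not 0.54 +/- 0.26) and the Ozark detection-temperature upper bound (28.80,
# not 8.80).
_D = CovariateDist
DETECTION_COVARIATES = {
    "wood_pct": {ARBUCKLE: _D(14.00, 13.18, 0.00, 65.00), OZARK: _D(16.00, 16.51, 0.00, 75.00)},
    "coarse_substrate_pct": {ARBUCKLE: _D(25.00, 18.71, 0.00, 70.00), OZARK: _D(28.00, 20.40, 5.00, 85.00)},
    "vegetation_pct": {ARBUCKLE: _D(25.00, 29.17, 0.00, 95.00), OZARK: _D(14.00, 18.60, 0.00, 95.00)},
    "velocity": {ARBUCKLE: _D(0.17, 0.11, 0.00, 0.47), OZARK: _D(0.16, 0.13, 0.00, 0.64)},
    "depth": {ARBUCKLE: _D(0.30, 0.16, 0.09, 0.97), OZARK: _D(0.27, 0.14, 0.06, 0.72)},
    "clarity": {ARBUCKLE: _D(2.70, 2.08, 0.20, 11.50), OZARK: _D(4.40, 1.61, 1.60, 11.20)},
    "temperature": {ARBUCKLE: _D(22.96, 3.87, 14.20, 30.80), OZARK: _D(23.84, 2.73, 17.00, 28.80)},
}
OCCURRENCE_COVARIATES = {
    "fine_substrate_pct": {ARBUCKLE: _D(39.00, 26.65, 0.00, 90.00), OZARK: _D(10.00, 11.78, 0.00, 85.00)},
    "rpd": {ARBUCKLE: _D(0.54, 0.40, 0.00, 1.95), OZARK: _D(0.74, 0.53, 0.02, 2.20)},
    "seepage": {ARBUCKLE: _D(0.02, 0.09, -0.14, 0.45), OZARK: _D(0.03, 0.15, -0.24, 1.26)},
    "temperature": {ARBUCKLE: _D(23.40, 3.56, 17.07, 28.85), OZARK: _D(23.15, 2.52, 16.14, 27.77)},
    "drainage_area": {ARBUCKLE: _D(73.65, 110.25, 1.00, 329.08, lognormal=True),
                      OZARK: _D(92.56, 94.90, 15.82, 543.90, lognormal=True)},
    "agriculture_pct": {ARBUCKLE: _D(18.31, 8.75, 0.01, 33.57), OZARK: _D(43.30, 17.14, 5.70, 74.18)},
    "pool_pct": {ARBUCKLE: _D(59.00, 24.00, 0.00, 98.00), OZARK: _D(54.00, 26.00, 0.00, 96.00)},
    "vegetation_pct": {ARBUCKLE: _D(25.00, 29.39, 0.00, 93.00), OZARK: _D(14.73, 18.63, 0.00, 90.00)},
    "wood_pct": {ARBUCKLE: _D(14.00, 12.56, 0.00, 52.00), OZARK: _D(15.67, 16.13, 0.00, 70.00)},
}


@dataclass(frozen=True)
class TrueEffects:
    """Generating values on the standardized logit scale.

    ``det``/``occ`` map design-column names to community hypermeans (columns
    not listed are 0); species coefficients are drawn around those with the
    deflection SDs.  The detection intercept defaults to 0 — average
    detection probability .50, the value the survey design anticipated —
    and the gear indicator to 1.0 (snorkeling detects better).
    """

    det: tuple = (("intercept", 0.0), ("gear", 1.0))
    occ: tuple = (("intercept", 0.0),)
    gear_by_cov: tuple = ()
    det_sd: float = 0.5
    occ_sd: float = 0.5
    sigma_u: float = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs; defaults reproduce the field design."""

    n_reaches: int = 61
    n_sites: int = 153
    site_split: tuple = (64, 89)          # (Arbuckle, Ozark) sites
    reach_split: tuple = (25, 36)         # (Arbuckle, Ozark) reaches
    year_split: tuple = (30, 31)          # reaches sampled in 2018 / 2019
    n_occasions: int = 2
    gear_missing_rate: float = 0.2        # P(site loses one gear)
    species: tuple = SPECIES_DEFAULT
    spec: ModelSpec = field(default_factory=full_spec)
    effects: TrueEffects = field(default_factory=TrueEffects)
    det_covariates: tuple = tuple(sorted(DETECTION_COVARIATES.items()))
    occ_covariates: tuple = tuple(sorted(OCCURRENCE_COVARIATES.items()))
    force_psi: float | None = None        # override occupancy (e.g. 1.0)
    seed: int = 0

    def __post_init__(self):
        if sum(self.site_split) != self.n_sites:
            raise ValidationError("site split must sum to n_sites")
        if sum(self.reach_split) != self.n_reaches:
            raise ValidationError("reach split must sum to n_reaches")


@dataclass
class SyntheticDataset:
    """A generated dataset plus everything needed to score recovery."""

    dataset: Dataset
    params: Parameters
    z: np.ndarray          # (S, J) true occupancy states
    psi: np.ndarray        # (S, J)
    p: np.ndarray          # (S, n_obs)
    config: GeneratorConfig


def default_config() -> GeneratorConfig:
    """The study design: 153 sites / 61 reaches (64/89 ecoregion split), two
    gears x two occasions, five taxa, field covariate moments, detection
    intercept at logit 0 (average p = .50)."""
    return GeneratorConfig()


def _draw_trunc(rng, dist: CovariateDist, size: int) -> np.ndarray:
    if dist.lo > dist.hi:
        raise ValidationError("infeasible truncation bounds")
    if dist.lognormal:
        # moment-match a log-normal, reject outside the observed range
        s2 = np.log1p((dist.sd / dist.mean) ** 2)
        mu = np.log(dist.mean) - s2 / 2
        out = np.empty(size)
        filled = 0
        for _ in range(1000):
            cand = rng.lognormal(mu, np.sqrt(s2), size=size)
            ok = cand[(cand >= dist.lo) & (cand <= dist.hi)]
            take = min(ok.size, size - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
            if filled == size:
                return out
        raise ValidationError("truncation bounds reject nearly all draws")
    if dist.sd == 0:
        return np.full(size, dist.mean)
    a = (dist.lo - dist.mean) / dist.sd
    b = (dist.hi - dist.mean) / dist.sd
    return truncnorm.rvs(a, b, loc=dist.mean, scale=dist.sd,
                         size=size, random_state=rng)


def generate(config: GeneratorConfig | None = None,
             seed: int | None = None) -> SyntheticDataset:
    """Draw one dataset from the generative model; bitwise reproducible
    given (config, seed)."""
    config = config or default_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    det_dists = dict(config.det_covariates)
    occ_dists = dict(config.occ_covariates)

    # -- reaches ---------------------------------------------------------------
    R = config.n_reaches
    eco_r = np.array([ARBUCKLE] * config.reach_split[0]
                     + [OZARK] * config.reach_split[1])
    year_r = np.zeros(R, dtype=int)
    year_r[rng.permutation(R)[: config.year_split[1]]] = 1
    reaches = pd.DataFrame({
        "reach_id": [f"R{r:03d}" for r in range(R)],
        "ecoregion": eco_r,
        "year": year_r,
    })
    for col in ("temperature", "drainage_area", "agriculture_pct"):
        vals = np.empty(R)
        for e in (ARBUCKLE, OZARK):
            m = eco_r == e
            vals[m] = _draw_trunc(rng, occ_dists[col][e], int(m.sum()))
        reaches[col] = vals
    clarity_r = np.empty(R)
    for e in (ARBUCKLE, OZARK):
        m = eco_r == e
        clarity_r[m] = _draw_trunc(rng, det_dists["clarity"][e], int(m.sum()))

    # -- sites: round-robin over same-ecoregion reaches ------------------------
    site_reach = []
    for e, n_sites_e in zip((ARBUCKLE, OZARK), config.site_split):
        reach_idx = np.flatnonzero(eco_r == e)
        site_reach += [reach_idx[s % reach_idx.size] for s in range(n_sites_e)]
    site_reach = np.array(site_reach)
    J = config.n_sites
    eco_j = eco_r[site_reach]
    sites = pd.DataFrame({
        "site_id": [f"S{j:03d}" for j in range(J)],
        "reach_id": [f"R{r:03d}" for r in site_reach],
    })
    for col in ("fine_substrate_pct", "pool_pct", "vegetation_pct",
                "wood_pct", "rpd", "seepage"):
        vals = np.empty(J)
        for e in (ARBUCKLE, OZARK):
            m = eco_j == e
            vals[m] = _draw_trunc(rng, occ_dists[col][e], int(m.sum()))
        sites[col] = vals
    sites["seepage"] = np.round(sites["seepage"], 2)  # measured to 0.01 m³/s
    # raw field measurements kept consistent with the derived covariates
    sites["riffle_crest_depth"] = np.round(rng.uniform(0.05, 0.60, J), 2)
    sites["max_pool_depth"] = np.round(sites["riffle_crest_depth"] + sites["rpd"], 4)
    q_up = np.round(rng.uniform(0.0, 1.0, J) + np.maximum(0.0, -sites["seepage"]), 2)
    sites["q_up"] = q_up
    sites["q_down"] = np.round(q_up + sites["seepage"], 2)
    sites["seepage"] = compute_seepage(sites["q_down"].to_numpy(),
                                       sites["q_up"].to_numpy())

    # -- survey rows (covariates drawn vectorized per ecoregion) ---------------
    svy_site, svy_gear, svy_occ = [], [], []
    for j in range(J):
        gears = [0, 1]
        if rng.uniform() < config.gear_missing_rate:
            gears = [int(rng.integers(2))]
        for g in gears:
            for occ in range(1, config.n_occasions + 1):
                svy_site.append(j)
                svy_gear.append(g)
                svy_occ.append(occ)
    svy_site = np.array(svy_site)
    surveys = pd.DataFrame({
        "site_id": [f"S{j:03d}" for j in svy_site],
        "gear": svy_gear,
        "occasion": svy_occ,
    })
    svy_eco = eco_j[svy_site]
    for col in ("wood_pct", "coarse_substrate_pct", "vegetation_pct",
                "velocity", "depth", "temperature"):
        vals = np.empty(len(surveys))
        for e in (ARBUCKLE, OZARK):
            m = svy_eco == e
            vals[m] = _draw_trunc(rng, det_dists[col][e], int(m.sum()))
        surveys[col] = vals
    surveys["clarity"] = clarity_r[site_reach[svy_site]]
    for sp in config.species:
        surveys[f"det_{sp}"] = 0

    enc = build_encounters(surveys, species=config.species,
                           site_ids=tuple(sites["site_id"]))
    ds = Dataset(encounters=enc, surveys=surveys, sites=sites,
                 reaches=reaches, species=config.species)

    # -- model run forward -----------------------------------------------------
    design = build_design(ds, config.spec)
    S = len(config.species)
    eff = config.effects
    params = Parameters.zeros(design)
    det_sp_cols = [c for c, sh in zip(design.det_columns, design.det_shared) if not sh]
    det_sh_cols = [c for c, sh in zip(design.det_columns, design.det_shared) if sh]
    det_mu = dict(eff.det)
    for c, name in enumerate(det_sp_cols):
        params.mu_alpha[c] = det_mu.get(name, 0.0)
    gear_mu = dict(eff.gear_by_cov)
    for c, name in enumerate(det_sh_cols):
        params.gamma[c] = gear_mu.get(name, 0.0)
    occ_mu = dict(eff.occ)
    for c, name in enumerate(design.occ_columns):
        params.mu_beta[c] = occ_mu.get(name, 0.0)
    params.sigma_alpha[:] = eff.det_sd
    params.sigma_beta[:] = eff.occ_sd
    params.sigma_u = eff.sigma_u
    params.alpha = params.mu_alpha[None, :] + rng.normal(0, eff.det_sd, (S, params.mu_alpha.size))
    params.beta = params.mu_beta[None, :] + rng.normal(0, eff.occ_sd, (S, params.mu_beta.size))
    params.u = rng.normal(0, eff.sigma_u, (design.n_reaches, S))

    psi = occurrence_prob(params, design)
    if config.force_psi is not None:
        psi = np.full_like(psi, config.force_psi)
    p = detection_prob(params, design)
    z = (rng.uniform(size=psi.shape) < psi).astype(np.int8)
    y_obs = (rng.uniform(size=p.shape) < z[:, design.obs_site] * p).astype(np.int8)

    # write detections back into the survey table and rebuild encounters;
    # survey rows were emitted in ascending (site, gear, occasion) order which
    # matches the observed-slot enumeration of the design matrices
    slot = svy_site * 4 + 2 * surveys["gear"].to_numpy() + surveys["occasion"].to_numpy() - 1
    if not np.all(np.diff(slot) > 0):
        raise AssertionError("survey rows out of design order")
    for i, sp in enumerate(config.species):
        surveys[f"det_{sp}"] = y_obs[i].astype(int)
    enc = build_encounters(surveys, species=config.species,
                           site_ids=tuple(sites["site_id"]))
    ds = Dataset(encounters=enc, surveys=surveys, sites=sites,
                 reaches=reaches, species=config.species)
    validate_dataset(ds)
    return SyntheticDataset(dataset=ds, params=params, z=z, psi=psi, p=p,
                            config=config)


def summarize_design(ds: Dataset) -> dict:
    """Design summary: site counts and percentages per ecoregion, surveys per
    gear, detections per species.  Percentages are rounded for display."""
    eco = ds.site_ecoregion() if len(ds.sites) else np.array([], dtype=int)
    n = len(ds.sites)
    n_arb = int((eco == ARBUCKLE).sum())
    n_oz = int((eco == OZARK).sum())
    gear_counts = ds.surveys["gear"].value_counts() if len(ds.surveys) else {}
    out = {
        "n_sites": n,
        "n_reaches": len(ds.reaches),
        "n_surveys": len(ds.surveys),
        "sites_arbuckle": n_arb,
        "sites_ozark": n_oz,
        "pct_arbuckle": int(round(100 * n_arb / n)) if n else 0,
        "pct_ozark": int(round(100 * n_oz / n)) if n else 0,
        "surveys_seining": int(gear_counts.get(0, 0)),
        "surveys_snorkeling": int(gear_counts.get(1, 0)),
    }
    for sp in ds.species:
        col = f"det_{sp}"
        out[f"detections_{sp}"] = int(ds.surveys[col].sum()) if len(ds.surveys) else 0
    return out
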