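"""Post-fit derived quantities: detection-by-gear tables and marginal curves.

All summaries follow the same conditioning convention: the covariate of
interest moves over a grid spanning its observed range (on the natural
scale), every other covariate is held at its mean (standardized 0, so
interaction columns vanish), the year indicator contributes a mean year
effect (0.5 x its coefficient), and the reach random intercept is set to
zero for population-level curves — or integrated over Normal(0, sigma_u) by
Monte Carlo when the wider, reach-to-reach band is wanted.  Probabilities
are computed per posterior draw through the inverse-logit and summarized
afterwards (posterior median, KDE mode, 2.5%/97.5% bounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .field_data import ValidationError
from .inference import PosteriorSamples, hdi, posterior_mode

__all__ = ["EffectCurve", "detection_table", "effect_curve", "interaction_curve"]


@dataclass
class EffectCurve:
    """One species x ecoregion probability curve over a covariate grid."""

    covariate: str
    species: str
    ecoregion: int
    grid: np.ndarray        # natural scale
    median: np.ndarray
    mode: np.ndarray
    lo: np.ndarray          # 2.5% bound
    hi: np.ndarray          # 97.5% bound

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariate,
            "species": self.species,
            "ecoregion": self.ecoregion,
            "x": self.grid,
            "median": self.median,
            "mode": self.mode,
            "lo": self.lo,
            "hi": self.hi,
        })


# ---------------------------------------------------------------------------
# Linear-predictor assembly from posterior draws
# ---------------------------------------------------------------------------

def _coef_draws(ps: PosteriorSamples, prefix: str, species: str,
                columns) -> np.ndarray:
    """(n_draws, n_cols) coefficient draws for one species."""
    return np.column_stack([ps.pooled(f"{prefix}[{species},{c}]")
                            for c in columns])


def _occ_eta(ps: PosteriorSamples, species: str, z_values: dict,
             ecoregion: int, n_grid: int, year: float = 0.5,
             integrate_reach: bool = False, seed: int = 0) -> np.ndarray:
    """Occurrence linear predictor draws (n_draws, n_grid)."""
    design = ps.design
    cols = design.occ_columns
    vals = np.zeros((len(cols), n_grid))
    for ci, col in enumerate(cols):
        if col == "intercept":
            vals[ci] = 1.0
        elif col == "ecoregion":
            vals[ci] = float(ecoregion)
        elif col == "year":
            vals[ci] = year
        elif col.startswith("eco:"):
            vals[ci] = float(ecoregion) * z_values.get(col[4:], 0.0)
        elif ":" in col:
            a, b = col.split(":")
            vals[ci] = np.asarray(z_values.get(a, 0.0)) * np.asarray(z_values.get(b, 0.0))
        else:
            vals[ci] = z_values.get(col, 0.0)
    coefs = _coef_draws(ps, "beta", species, cols)
    eta = coefs @ vals
    if integrate_reach:
        sig = ps.pooled("sigma_u")
        rng = np.random.default_rng(seed)
        eta = eta + (rng.standard_normal(sig.size) * sig)[:, None]
    return eta


def _det_eta(ps: PosteriorSamples, species: str, z_values: dict,
             gear: int, ecoregion: int, n_grid: int) -> np.ndarray:
    """Detection linear predictor draws (n_draws, n_grid)."""
    design = ps.design
    sp_cols = [c for c, sh in zip(design.det_columns, design.det_shared) if not sh]
    sh_cols = [c for c, sh in zip(design.det_columns, design.det_shared) if sh]

    def col_value(col):
        if col == "intercept":
            return np.full(n_grid, 1.0)
        if col == "gear":
            return np.full(n_grid, float(gear))
        if col == "ecoregion":
            return np.full(n_grid, float(ecoregion))
        if col.startswith("gear:"):
            return float(gear) * np.asarray(col_value(col[5:]), dtype=float) * np.ones(n_grid)
        if col.endswith("2") and col[:-1] in design.spec.det_quadratic:
            return np.asarray(z_values.get(col[:-1], 0.0), dtype=float) ** 2 * np.ones(n_grid)
        return np.asarray(z_values.get(col, 0.0), dtype=float) * np.ones(n_grid)

    vals_sp = np.stack([col_value(c) for c in sp_cols])
    eta = _coef_draws(ps, "alpha", species, sp_cols) @ vals_sp
    if sh_cols:
        vals_sh = np.stack([col_value(c) for c in sh_cols])
        gamma = np.column_stack([ps.pooled(f"gamma[{c}]") for c in sh_cols])
        eta = eta + gamma @ vals_sh
    return eta


def _summarize_prob(prob: np.ndarray, covariate, species, ecoregion,
                    grid) -> EffectCurve:
    return EffectCurve(
        covariate=covariate, species=species, ecoregion=ecoregion,
        grid=np.asarray(grid, dtype=float),
        median=np.median(prob, axis=0),
        mode=np.array([posterior_mode(prob[:, g]) for g in range(prob.shape[1])]),
        lo=np.quantile(prob, 0.025, axis=0),
        hi=np.quantile(prob, 0.975, axis=0),
    )


# ---------------------------------------------------------------------------
# Public surfaces
# ---------------------------------------------------------------------------

def detection_table(ps: PosteriorSamples) -> pd.DataFrame:
    """Detection probability per species x gear x ecoregion at mean covariates:
    posterior mode and 95% HDI of the inverse-logit linear predictor."""
    design = ps.design
    if "gear" not in design.det_columns:
        raise ValidationError("model spec has no gear indicator column")
    rows = []
    for sp in design.species:
        for gear in (0, 1):
            for eco in (0, 1):
                eta = _det_eta(ps, sp, {}, gear=gear, ecoregion=eco, n_grid=1)
                prob = expit(eta[:, 0])
                lo, hi = hdi(prob, 0.95)
                rows.append({
                    "species": sp, "gear": gear, "ecoregion": eco,
                    "mode": posterior_mode(prob),
                    "hdi_low": lo, "hdi_high": hi,
                })
    return pd.DataFrame(rows)


def effect_curve(ps: PosteriorSamples, covariate: str, species: str,
                 ecoregion: int = 0, n_grid: int = 100,
                 kind: str = "occurrence", gear: int = 1,
                 integrate_reach: bool = False, seed: int = 0) -> EffectCurve:
    """Marginal probability curve for one covariate, species and ecoregion.

    The grid spans the covariate's observed range on the natural scale; the
    stored standardization record (including any natural-log transform) maps
    it onto the model scale.  Other covariates sit at their means and the
    year effect at its average.
    """
    design = ps.design
    active = (design.spec.occ_covariates if kind == "occurrence"
              else design.spec.det_covariates)
    if covariate not in active:
        raise ValidationError(f"covariate {covariate!r} not in the retained spec")
    rec = design.records[f"{'occ' if kind == 'occurrence' else 'det'}:{covariate}"]
    grid = np.linspace(rec.natural_min, rec.natural_max, n_grid)
    z = rec.forward(grid)
    if kind == "occurrence":
        eta = _occ_eta(ps, species, {covariate: z}, ecoregion, n_grid,
                       integrate_reach=integrate_reach, seed=seed)
    else:
        eta = _det_eta(ps, species, {covariate: z}, gear=gear,
                       ecoregion=ecoregion, n_grid=n_grid)
    return _summarize_prob(expit(eta), covariate, species, ecoregion, grid)


def interaction_curve(ps: PosteriorSamples, covariate: str, moderator: str,
                      species: str, levels=(-1.0, 1.0), ecoregion: int = 0,
                      n_grid: int = 100, integrate_reach: bool = False,
                      seed: int = 0):
    """Occurrence curves for ``covariate`` at low/high ``moderator`` levels
    (default -1 and +1 SD on the standardized scale).  Returns one
    EffectCurve per level."""
    design = ps.design
    pair = f"{covariate}:{moderator}"
    pair_rev = f"{moderator}:{covariate}"
    if pair not in design.occ_columns and pair_rev not in design.occ_columns:
        raise ValidationError(
            f"interaction {covariate} x {moderator} not in the retained spec")
    rec = design.records[f"occ:{covariate}"]
    grid = np.linspace(rec.natural_min, rec.natural_max, n_grid)
    z = rec.forward(grid)
    out = []
    for level in levels:
        eta = _occ_eta(ps, species, {covariate: z, moderator: float(level)},
                       ecoregion, n_grid, integrate_reach=integrate_reach,
                       seed=seed)
        out.append(_summarize_prob(expit(eta), covariate, species,
                                   ecoregion, grid))
    return tuple(out)
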