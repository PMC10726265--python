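"""Covariate transformation and design-matrix assembly.

Occurrence and detection probabilities are modelled by logistic regression on
standardized covariates.  Continuous covariates are centred and scaled (mean 0,
SD 1) on the pooled, both-ecoregion dataset so that species and ecoregion
coefficients are comparable on one scale; drainage area is natural-log
transformed first because it spans two orders of magnitude.  Indicator columns
(gear 0=seining/1=snorkeling, ecoregion 0=Arbuckle/1=Ozark, year 0=2018/1=2019)
are left as 0/1.  Interaction columns are products of standardized mains and
are deliberately not re-centred, so that they vanish when covariates sit at
their means — the conditioning used for marginal-effect curves.

Ecoregion-varying effects are coded as a main column plus an (ecoregion x
main) offset column: the Arbuckle relationship is the main coefficient and the
Ozark relationship is main + offset, mirroring deflection-style reporting of
between-ecoregion differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .field_data import Dataset, ValidationError

__all__ = [
    "StandardizationRecord",
    "ModelSpec",
    "DesignMatrices",
    "standardize",
    "build_design",
    "full_spec",
    "final_spec",
]

DET_COVARIATES_FULL = (
    "wood_pct", "coarse_substrate_pct", "vegetation_pct",
    "velocity", "depth", "clarity", "temperature",
)
OCC_COVARIATES_FULL = (
    "temperature", "drainage_area", "agriculture_pct",
    "fine_substrate_pct", "pool_pct", "rpd", "seepage",
    "vegetation_pct", "wood_pct",
)
OCC_INTERACTIONS_FULL = (
    ("temperature", "rpd"),
    ("vegetation_pct", "rpd"),
    ("vegetation_pct", "pool_pct"),
)
# reach-scale occurrence covariates live in the reach table
_REACH_SCALE = {"temperature", "drainage_area", "agriculture_pct"}

DEFAULT_TRANSFORMS = {"drainage_area": "natural_log"}


@dataclass(frozen=True)
class StandardizationRecord:
    """How one covariate was put on the model scale, kept for back-transforms."""

    name: str
    transform: str          # "identity" | "natural_log"
    mean: float             # post-transform
    sd: float               # post-transform
    natural_min: float = np.nan
    natural_max: float = np.nan

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        t = np.log(x) if self.transform == "natural_log" else x
        return (t - self.mean) / self.sd

    def inverse(self, z):
        z = np.asarray(z, dtype=float)
        t = z * self.sd + self.mean
        return np.exp(t) if self.transform == "natural_log" else t


def standardize(values, transform: str = "identity"):
    """Return (z-scores, StandardizationRecord) for one covariate.

    ``natural_log`` is applied before centring/scaling.  Constant columns are
    rejected because they cannot be scaled to unit SD.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if np.unique(finite).size < 2:
        raise ValidationError("standardize needs at least two distinct finite values")
    if transform == "natural_log":
        if np.any(finite <= 0):
            raise ValidationError("natural_log transform requires positive values")
        t = np.log(x)
    elif transform == "identity":
        t = x
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    mean = float(np.nanmean(t))
    sd = float(np.nanstd(t, ddof=1))
    rec = StandardizationRecord(
        name="", transform=transform, mean=mean, sd=sd,
        natural_min=float(np.nanmin(x)), natural_max=float(np.nanmax(x)),
    )
    return (t - mean) / sd, rec


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which covariates, interactions and varying-effect structures are active.

    This is the object backward selection shrinks.  Detection covariates get a
    species-varying coefficient plus, when ``gear_by_covariate`` is on, a
    community-level gear x covariate column shared among species.
    """

    det_covariates: tuple = DET_COVARIATES_FULL
    det_quadratic: tuple = ("depth",)
    det_gear: bool = True
    det_ecoregion: bool = True
    gear_by_covariate: bool = True
    occ_covariates: tuple = OCC_COVARIATES_FULL
    occ_interactions: tuple = OCC_INTERACTIONS_FULL
    occ_ecoregion: bool = True
    occ_year: bool = True
    vary_by_ecoregion: tuple = OCC_COVARIATES_FULL
    transforms: tuple = tuple(sorted(DEFAULT_TRANSFORMS.items()))

    def __post_init__(self):
        object.__setattr__(self, "det_covariates", tuple(self.det_covariates))
        object.__setattr__(self, "det_quadratic", tuple(self.det_quadratic))
        object.__setattr__(self, "occ_covariates", tuple(self.occ_covariates))
        object.__setattr__(self, "occ_interactions",
                           tuple(tuple(t) for t in self.occ_interactions))
        object.__setattr__(self, "vary_by_ecoregion", tuple(self.vary_by_ecoregion))
        for a, b in self.occ_interactions:
            if a not in self.occ_covariates or b not in self.occ_covariates:
                raise ValidationError(f"interaction ({a}, {b}) lacks a main effect")
        for v in self.vary_by_ecoregion:
            if v not in self.occ_covariates:
                raise ValidationError(f"ecoregion-varying term {v!r} lacks a main effect")
        for q in self.det_quadratic:
            if q not in self.det_covariates:
                raise ValidationError(f"quadratic term {q!r} lacks a main effect")

    # -- selection support ---------------------------------------------------
    def occ_terms(self) -> list:
        """Droppable occurrence terms: interactions, ecoregion offsets, mains."""
        terms = [f"{a}:{b}" for a, b in self.occ_interactions]
        terms += [f"eco:{v}" for v in self.vary_by_ecoregion]
        terms += list(self.occ_covariates)
        return terms

    def is_droppable(self, term: str) -> bool:
        """A main effect is droppable only once nothing above it depends on it."""
        if ":" in term:
            return True
        if any(term in pair for pair in self.occ_interactions):
            return False
        return term not in self.vary_by_ecoregion

    def drop_term(self, term: str) -> "ModelSpec":
        """Return a spec without ``term``; dropping a main removes its dependents."""
        if ":" in term and not term.startswith("eco:"):
            a, b = term.split(":")
            inter = tuple(t for t in self.occ_interactions if t != (a, b))
            if inter == self.occ_interactions:
                raise ValidationError(f"unknown interaction {term!r}")
            return replace(self, occ_interactions=inter)
        if term.startswith("eco:"):
            v = term[4:]
            vary = tuple(t for t in self.vary_by_ecoregion if t != v)
            if vary == self.vary_by_ecoregion:
                raise ValidationError(f"unknown ecoregion offset {term!r}")
            return replace(self, vary_by_ecoregion=vary)
        if term not in self.occ_covariates:
            raise ValidationError(f"unknown occurrence covariate {term!r}")
        return replace(
            self,
            occ_covariates=tuple(c for c in self.occ_covariates if c != term),
            occ_interactions=tuple(t for t in self.occ_interactions if term not in t),
            vary_by_ecoregion=tuple(v for v in self.vary_by_ecoregion if v != term),
        )

    # -- serialization ---------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "det_covariates": list(self.det_covariates),
            "det_quadratic": list(self.det_quadratic),
            "det_gear": self.det_gear,
            "det_ecoregion": self.det_ecoregion,
            "gear_by_covariate": self.gear_by_covariate,
            "occ_covariates": list(self.occ_covariates),
            "occ_interactions": [list(t) for t in self.occ_interactions],
            "occ_ecoregion": self.occ_ecoregion,
            "occ_year": self.occ_year,
            "vary_by_ecoregion": list(self.vary_by_ecoregion),
            "transforms": dict(self.transforms),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["occ_interactions"] = [tuple(t) for t in d.get("occ_interactions", [])]
        d["transforms"] = tuple(sorted(d.get("transforms", {}).items()))
        return cls(**d)


def full_spec() -> ModelSpec:
    """The full model: every detection and occurrence covariate, all three
    hypothesized interactions, ecoregion-varying occurrence mains."""
    return ModelSpec()


def final_spec() -> ModelSpec:
    """The reduced occurrence structure retained after backward selection:
    site-scale percent pool, percent vegetation and RPD plus reach-scale water
    temperature, drainage area and percent agriculture, with the temperature x
    RPD and vegetation x pool interactions."""
    mains = ("temperature", "drainage_area", "agriculture_pct",
             "pool_pct", "rpd", "vegetation_pct")
    return ModelSpec(
        occ_covariates=mains,
        occ_interactions=(("temperature", "rpd"), ("vegetation_pct", "pool_pct")),
        vary_by_ecoregion=("temperature", "drainage_area"),
    )


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Survey-level detection matrix, site-level occurrence matrix, bookkeeping.

    ``X_det`` has one row per conducted survey (``obs_site`` maps rows to site
    indices); ``det_shared`` marks the gear x covariate columns whose
    coefficients are shared among species.  ``X_occ`` has one row per site.
    """

    X_det: np.ndarray
    det_columns: list
    det_shared: np.ndarray          # bool per det column
    X_occ: np.ndarray
    occ_columns: list
    obs_site: np.ndarray            # (n_obs,) site index per survey row
    y_obs: np.ndarray               # (S, n_obs)
    reach_index: np.ndarray         # (n_sites,)
    site_ecoregion: np.ndarray      # (n_sites,)
    n_reaches: int
    species: tuple
    records: dict                   # covariate name -> StandardizationRecord
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return self.X_det.shape[0]

    @property
    def n_sites(self) -> int:
        return self.X_occ.shape[0]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def det_col(self, name: str) -> int:
        return self.det_columns.index(name)

    def occ_col(self, name: str) -> int:
        return self.occ_columns.index(name)


def _occ_values(ds: Dataset, name: str) -> np.ndarray:
    """Site-level vector for an occurrence covariate (reach ones broadcast)."""
    if name in _REACH_SCALE:
        if name not in ds.reaches.columns:
            raise ValidationError(f"unknown occurrence covariate {name!r}")
        per_reach = ds.reaches[name].to_numpy(dtype=float)
        return per_reach[ds.site_reach_index()]
    if name not in ds.sites.columns:
        raise ValidationError(f"unknown occurrence covariate {name!r}")
    return ds.sites[name].to_numpy(dtype=float)


def build_design(ds: Dataset, spec: ModelSpec) -> DesignMatrices:
    """Assemble detection and occurrence design matrices for a model spec.

    Column order is deterministic given the spec: intercept, mains in spec
    order, quadratics, indicators, interactions / ecoregion offsets, and (for
    detection) the shared gear x covariate block last.
    """
    enc = ds.encounters
    transforms = dict(spec.transforms)
    records: dict = {}

    # -- observed-survey bookkeeping -----------------------------------------
    J = enc.n_sites
    obs = [(j, k) for j in range(J) for k in range(enc.mask.shape[1]) if enc.mask[j, k]]
    obs_site = np.array([j for j, _ in obs], dtype=int)
    y_obs = np.stack([[enc.y[i, j, k] for j, k in obs] for i in range(enc.n_species)])
    y_obs = y_obs.astype(np.int8)

    key_to_row = {
        (row["site_id"], int(row["gear"]), int(row["occasion"])): idx
        for idx, row in ds.surveys.iterrows()
    }
    site_ids = enc.site_ids
    obs_rows = []
    for j, k in obs:
        gear, occ = divmod(k, 2)
        key = (site_ids[j], gear, occ + 1)
        if key not in key_to_row:
            raise ValidationError(f"survey row missing for {key!r}")
        obs_rows.append(key_to_row[key])
    sdf = ds.surveys.loc[obs_rows]
    gear_vec = sdf["gear"].to_numpy(dtype=float)

    reach_index = ds.site_reach_index()
    site_eco = ds.site_ecoregion()
    obs_eco = site_eco[obs_site].astype(float)

    # -- detection matrix -----------------------------------------------------
    det_cols, det_mat, det_shared = ["intercept"], [np.ones(len(obs))], [False]
    z_det = {}
    for name in spec.det_covariates:
        if name not in sdf.columns:
            raise ValidationError(f"unknown detection covariate {name!r}")
        z, rec = standardize(sdf[name].to_numpy(dtype=float),
                             transforms.get(name, "identity"))
        rec = replace(rec, name=f"det:{name}")
        records[f"det:{name}"] = rec
        z_det[name] = z
        det_cols.append(name)
        det_mat.append(z)
        det_shared.append(False)
    for name in spec.det_quadratic:
        det_cols.append(f"{name}2")
        det_mat.append(z_det[name] ** 2)  # square of the standardized main
        det_shared.append(False)
    if spec.det_gear:
        det_cols.append("gear")
        det_mat.append(gear_vec)
        det_shared.append(False)
    if spec.det_ecoregion:
        det_cols.append("ecoregion")
        det_mat.append(obs_eco)
        det_shared.append(False)
    if spec.gear_by_covariate:
        for name in spec.det_covariates:
            det_cols.append(f"gear:{name}")
            det_mat.append(gear_vec * z_det[name])
            det_shared.append(True)
        for name in spec.det_quadratic:
            det_cols.append(f"gear:{name}2")
            det_mat.append(gear_vec * z_det[name] ** 2)
            det_shared.append(True)

    # -- occurrence matrix -----------------------------------------------------
    occ_cols, occ_mat = ["intercept"], [np.ones(J)]
    z_occ = {}
    for name in spec.occ_covariates:
        z, rec = standardize(_occ_values(ds, name),
                             transforms.get(name, "identity"))
        rec = replace(rec, name=f"occ:{name}")
        records[f"occ:{name}"] = rec
        z_occ[name] = z
        occ_cols.append(name)
        occ_mat.append(z)
    if spec.occ_ecoregion:
        occ_cols.append("ecoregion")
        occ_mat.append(site_eco.astype(float))
    if spec.occ_year:
        year = ds.reaches["year"].to_numpy(dtype=float)[reach_index]
        occ_cols.append("year")
        occ_mat.append(year)
    for a, b in spec.occ_interactions:
        occ_cols.append(f"{a}:{b}")
        occ_mat.append(z_occ[a] * z_occ[b])
    for name in spec.vary_by_ecoregion:
        occ_cols.append(f"eco:{name}")
        occ_mat.append(site_eco.astype(float) * z_occ[name])

    return DesignMatrices(
        X_det=np.column_stack(det_mat),
        det_columns=det_cols,
        det_shared=np.array(det_shared, dtype=bool),
        X_occ=np.column_stack(occ_mat),
        occ_columns=occ_cols,
        obs_site=obs_site,
        y_obs=y_obs,
        reach_index=reach_index,
        site_ecoregion=site_eco,
        n_reaches=ds.n_reaches,
        species=tuple(ds.species),
        records=records,
        spec=spec,
    )
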