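"""Field-data model: survey tables, derived habitat covariates, encounter histories.

The sampling design is a nested, two-gear, repeat-visit protocol: riffle-run-pool
complexes ("sites") nested in stream reaches, each site surveyed by seining and/or
snorkeling on up to two occasions, giving at most four surveys per site.  Species
detections are 0/1 per survey.  Missing (site, gear, occasion) combinations are a
normal feature of the design — some sites are too shallow to snorkel or too deep
to seine — and are carried as an explicit mask, never as imputed zeros.

Three plain-text CSV tables hold a dataset:

* ``surveys.csv`` — one row per survey: ``site_id, gear, occasion,
  det_<species>..., wood_pct, coarse_substrate_pct, vegetation_pct, velocity,
  depth, clarity, temperature``
* ``sites.csv`` — one row per site: ``site_id, reach_id, fine_substrate_pct,
  pool_pct, vegetation_pct, wood_pct, rpd, seepage, q_up, q_down,
  riffle_crest_depth, max_pool_depth``
* ``reaches.csv`` — one row per reach: ``reach_id, ecoregion, year,
  temperature, drainage_area, agriculture_pct``

Gear is coded 0 = seining, 1 = snorkeling; ecoregion 0 = Arbuckle Uplift,
1 = Ozark Highlands; year 0 = 2018, 1 = 2019.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SPECIES_DEFAULT",
    "SEINING",
    "SNORKELING",
    "ARBUCKLE",
    "OZARK",
    "EncounterArray",
    "Dataset",
    "compute_seepage",
    "compute_rpd",
    "compute_unit_area",
    "build_encounters",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

SEINING, SNORKELING = 0, 1
ARBUCKLE, OZARK = 0, 1
N_OCCASIONS = 2
MAX_SURVEYS = 4  # 2 gears x 2 occasions

SPECIES_DEFAULT = (
    "least_darter",
    "redspot_chub",
    "southern_redbelly_dace",
    "smallmouth_bass_age0",
    "smallmouth_bass_age1",
)

SURVEY_COVARIATES = (
    "wood_pct",
    "coarse_substrate_pct",
    "vegetation_pct",
    "velocity",
    "depth",
    "clarity",
    "temperature",
)
SITE_COVARIATES = (
    "fine_substrate_pct",
    "pool_pct",
    "vegetation_pct",
    "wood_pct",
    "rpd",
    "seepage",
)
REACH_COVARIATES = ("temperature", "drainage_area", "agriculture_pct")

_PERCENT_COLS = {
    "wood_pct",
    "coarse_substrate_pct",
    "vegetation_pct",
    "fine_substrate_pct",
    "pool_pct",
    "agriculture_pct",
}


class ValidationError(ValueError):
    """Raised when a table or derived-covariate input violates its contract."""


# ---------------------------------------------------------------------------
# Derived field covariates
# ---------------------------------------------------------------------------

def compute_seepage(q_down: float, q_up: float) -> float:
    """Seepage run (m³/s): downstream minus upstream discharge, to 0.01 m³/s.

    Positive values indicate a gaining (groundwater-fed) site, negative a
    losing site.  Both discharges must be non-negative.
    """
    q_down = np.asarray(q_down, dtype=float)
    q_up = np.asarray(q_up, dtype=float)
    if np.any(q_down < 0) or np.any(q_up < 0):
        raise ValidationError("discharge measurements must be non-negative")
    out = np.round(q_down - q_up, 2)
    return float(out) if out.ndim == 0 else out


def compute_rpd(riffle_crest_depth: float, max_pool_depth: float) -> float:
    """Residual pool depth (m): pool depth independent of discharge.

    Maximum depth of the pool minus channel depth at the downstream riffle
    crest, clamped at zero for degenerate measurements where the crest is
    recorded deeper than the pool.
    """
    rcd = np.asarray(riffle_crest_depth, dtype=float)
    mpd = np.asarray(max_pool_depth, dtype=float)
    if np.any(rcd < 0) or np.any(mpd < 0):
        raise ValidationError("depths must be non-negative")
    out = np.maximum(0.0, mpd - rcd)
    return float(out) if out.ndim == 0 else out


def compute_unit_area(widths, length: float) -> float:
    """Channel-unit surface area (m²): mean wetted width times unit length.

    Widths are measured at roughly three points along the unit; summing unit
    areas over a site's pools/riffles/runs gives total site area.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0:
        raise ValidationError("at least one wetted width is required")
    if np.any(widths <= 0) or length <= 0:
        raise ValidationError("widths and length must be positive")
    return float(widths.mean() * length)


# ---------------------------------------------------------------------------
# Encounter histories
# ---------------------------------------------------------------------------

@dataclass
class EncounterArray:
    """Binary detections ``y[species, site, survey]`` with a ragged-design mask.

    Survey slot ``k = 2*gear + (occasion-1)`` so k in {0,1} are seining
    occasions 1-2 and k in {2,3} snorkeling occasions 1-2.  ``mask[j, k]`` is
    True where the survey was actually conducted; masked slots carry no
    information in any likelihood.
    """

    y: np.ndarray                 # (S, J, 4) int8
    mask: np.ndarray              # (J, 4) bool
    gear_of_survey: np.ndarray    # (J, 4) int8, -1 where masked
    species: tuple
    site_ids: tuple

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_surveys(self) -> int:
        return int(self.mask.sum())

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.y.shape[1:] != self.mask.shape:
            raise ValidationError("y and mask shapes disagree")


def _slot(gear: int, occasion: int) -> int:
    return 2 * int(gear) + (int(occasion) - 1)


def build_encounters(surveys, species=SPECIES_DEFAULT, site_ids=None) -> EncounterArray:
    """Assemble the detection array y[i, j, k] from per-survey rows.

    ``surveys`` is a DataFrame with columns ``site_id, gear, occasion`` and one
    ``det_<species>`` column per species.  (site, gear, occasion) must be unique.
    The result is invariant to the row order of the input.
    """
    df = pd.DataFrame(surveys)
    keys = list(zip(df["site_id"], df["gear"], df["occasion"]))
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (site_id, gear, occasion) survey rows")
    for sp in species:
        col = f"det_{sp}"
        if col not in df.columns:
            raise ValidationError(f"missing detection column {col!r}")
        vals = df[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"non-binary detections in {col!r}")
    if not df["gear"].isin((SEINING, SNORKELING)).all():
        raise ValidationError("gear must be 0 (seining) or 1 (snorkeling)")
    if not df["occasion"].isin((1, 2)).all():
        raise ValidationError("occasion must be 1 or 2")

    if site_ids is None:
        site_ids = tuple(sorted(df["site_id"].unique()))
    else:
        site_ids = tuple(site_ids)
    site_index = {s: j for j, s in enumerate(site_ids)}

    S, J = len(species), len(site_ids)
    y = np.zeros((S, J, MAX_SURVEYS), dtype=np.int8)
    mask = np.zeros((J, MAX_SURVEYS), dtype=bool)
    gear_of = np.full((J, MAX_SURVEYS), -1, dtype=np.int8)

    for _, row in df.iterrows():
        j = site_index[row["site_id"]]
        k = _slot(row["gear"], row["occasion"])
        mask[j, k] = True
        gear_of[j, k] = int(row["gear"])
        for i, sp in enumerate(species):
            y[i, j, k] = int(row[f"det_{sp}"])

    return EncounterArray(y=y, mask=mask, gear_of_survey=gear_of,
                          species=tuple(species), site_ids=site_ids)


# ---------------------------------------------------------------------------
# Dataset container and CSV round-trip
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A validated survey dataset: encounter array plus the three covariate tables.

    ``surveys`` keeps one row per conducted survey (detection covariates live
    here), ``sites`` one row per site, ``reaches`` one row per reach.
    """

    encounters: EncounterArray
    surveys: pd.DataFrame
    sites: pd.DataFrame
    reaches: pd.DataFrame
    species: tuple = field(default=SPECIES_DEFAULT)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_reaches(self) -> int:
        return len(self.reaches)

    def site_reach_index(self) -> np.ndarray:
        """Integer reach index (row into ``reaches``) for each site row."""
        rmap = {r: i for i, r in enumerate(self.reaches["reach_id"])}
        return np.array([rmap[r] for r in self.sites["reach_id"]], dtype=int)

    def site_ecoregion(self) -> np.ndarray:
        eco = dict(zip(self.reaches["reach_id"], self.reaches["ecoregion"]))
        return np.array([eco[r] for r in self.sites["reach_id"]], dtype=int)


def validate_dataset(ds: Dataset) -> None:
    """Check referential integrity, indicator codings and covariate ranges."""
    reach_ids = set(ds.reaches["reach_id"])
    orphans = set(ds.sites["reach_id"]) - reach_ids
    if orphans:
        raise ValidationError(f"sites reference missing reaches: {sorted(orphans)!r}")
    site_ids = set(ds.sites["site_id"])
    if len(site_ids) != len(ds.sites):
        raise ValidationError("duplicate site_id in sites table")
    orphan_surveys = set(ds.surveys["site_id"]) - site_ids
    if orphan_surveys:
        raise ValidationError(f"surveys reference missing sites: {sorted(orphan_surveys)!r}")
    for col in ("ecoregion", "year"):
        if not ds.reaches[col].isin((0, 1)).all():
            raise ValidationError(f"{col} indicator must be 0/1")
    if (ds.reaches["drainage_area"] <= 0).any():
        raise ValidationError("drainage_area must be positive")
    for df in (ds.surveys, ds.sites, ds.reaches):
        for col in df.columns:
            if col in _PERCENT_COLS:
                vals = df[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise ValidationError(f"percent column {col!r} outside [0, 100]")
    for sp in ds.species:
        col = f"det_{sp}"
        if not ds.surveys[col].isin((0, 1)).all():
            raise ValidationError(f"non-binary detection cell in {col!r}")
    if "rpd" in ds.sites and (ds.sites["rpd"].dropna() < 0).any():
        raise ValidationError("rpd must be non-negative")


def _detect_species(survey_df: pd.DataFrame) -> tuple:
    return tuple(c[len("det_"):] for c in survey_df.columns if c.startswith("det_"))


def read_dataset(survey_csv, site_csv=None, reach_csv=None) -> Dataset:
    """Load and validate a dataset from the three CSV files.

    A single directory argument is accepted in place of the three paths, in
    which case ``surveys.csv``, ``sites.csv`` and ``reaches.csv`` are read
    from it.
    """
    if site_csv is None and os.path.isdir(str(survey_csv)):
        d = str(survey_csv)
        survey_csv = os.path.join(d, "surveys.csv")
        site_csv = os.path.join(d, "sites.csv")
        reach_csv = os.path.join(d, "reaches.csv")
    surveys = pd.read_csv(survey_csv, na_values=["NA"])
    sites = pd.read_csv(site_csv, na_values=["NA"])
    reaches = pd.read_csv(reach_csv, na_values=["NA"])
    species = _detect_species(surveys)
    enc = build_encounters(surveys, species=species,
                           site_ids=tuple(sites["site_id"]))
    ds = Dataset(encounters=enc, surveys=surveys, sites=sites,
                 reaches=reaches, species=species)
    validate_dataset(ds)
    return ds


def write_dataset(ds: Dataset, directory) -> None:
    """Write surveys.csv / sites.csv / reaches.csv (UTF-8, "NA" for missing)."""
    os.makedirs(directory, exist_ok=True)
    ds.surveys.to_csv(os.path.join(directory, "surveys.csv"),
                      index=False, na_rep="NA")
    ds.sites.to_csv(os.path.join(directory, "sites.csv"),
                    index=False, na_rep="NA")
    ds.reaches.to_csv(os.path.join(directory, "reaches.csv"),
                      index=False, na_rep="NA")
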