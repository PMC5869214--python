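"""Synthetic landscapes, historical records and interview surveys.

Every downstream stage of the pipeline is exercised against data generated
here, with the generating parameters stored as ground truth. The generator
emulates the statistical structure the analysis assumes:

- spatially autocorrelated environmental fields (elevation, 12 monthly
  temperatures with a seasonal cycle and an elevation lapse, 12 monthly
  precipitation totals with a wet-season cycle), produced by moving-average
  smoothing of white noise so suitable habitat forms contiguous patches;
- a county partition of the grid (Voronoi regions of random seed cells,
  hence contiguous), grouped into provinces;
- county-level historical presence whose probability rises with percent
  suitable habitat through a logistic link;
- respondent-level interview records with a province random intercept,
  county-level extra-binomial noise (an observation-level effect at the
  county scale), and last-sighting reports rendered in four raw date
  formats.

All outputs are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .raster import RasterGrid

__all__ = [
    "ConfigurationError",
    "LandscapeConfig",
    "SurveyConfig",
    "Landscape",
    "generate_landscape",
    "generate_historical_records",
    "generate_interviews",
]


class ConfigurationError(ValueError):
    """A generator config that cannot produce a valid dataset."""


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Parameters of a synthetic study region.

    ``temperature_params`` is (annual mean degC, spatial SD degC, seasonal
    half-amplitude degC); ``precipitation_params`` is (mean mm/month,
    spatial SD mm/month). ``landcover_classes`` lists (class id, label,
    weight), weights proportional to expected areal share.
    ``autocorrelation_length`` is the moving-average window (cells) applied
    to the white-noise fields. ``lapse_rate_c_per_km`` couples temperature
    to elevation (degC lost per km climbed).
    """

    grid_rows: int = 120
    grid_cols: int = 120
    cell_size: float = 1.0
    n_counties: int = 95
    n_provinces: int = 15
    elevation_range: tuple[float, float] = (0.0, 2500.0)
    temperature_params: tuple[float, float, float] = (12.0, 2.0, 8.0)
    precipitation_params: tuple[float, float] = (90.0, 35.0)
    landcover_classes: tuple[tuple[int, str, float], ...] = (
        (1, "tree cover", 0.30),
        (2, "shrub cover", 0.15),
        (3, "tree cover/natural vegetation mosaic", 0.15),
        (7, "cropland", 0.25),
        (8, "urban/bare", 0.15),
    )
    autocorrelation_length: int = 15
    lapse_rate_c_per_km: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ConfigurationError("grid must be at least 4x4")
        if self.n_provinces > self.n_counties:
            raise ConfigurationError("n_provinces must not exceed n_counties")
        if self.n_counties > self.grid_rows * self.grid_cols:
            raise ConfigurationError("fewer cells than counties")
        if any(w <= 0 for _, _, w in self.landcover_classes):
            raise ConfigurationError("landcover weights must be positive")
        lo, hi = self.elevation_range
        if lo >= hi:
            raise ConfigurationError("elevation_range must be increasing")
        if self.autocorrelation_length < 1:
            raise ConfigurationError("autocorrelation_length must be >= 1")

    @property
    def forest_class_ids(self) -> tuple[int, ...]:
        """Ids of the classes regrouped as forest (the first three by
        convention: tree, shrub, mosaic)."""
        return tuple(cid for cid, _, _ in self.landcover_classes[:3])


@dataclass
class Landscape:
    """A generated study region plus its ground truth."""

    elevation: RasterGrid
    monthly_temperature: list[RasterGrid]
    monthly_precipitation: list[RasterGrid]
    landcover: RasterGrid
    county_labels: RasterGrid
    county_province_map: pd.DataFrame
    truth: dict


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], length: int) -> np.ndarray:
    """Standardised moving-average-smoothed white noise (mean 0, SD 1)."""
    z = rng.standard_normal(shape)
    if length > 1:
        z = ndimage.uniform_filter(z, size=length, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def _seasonal_cycle(amplitude: float) -> np.ndarray:
    """Monthly offsets peaking in July (month index 6)."""
    months = np.arange(12)
    return amplitude * np.cos(2.0 * np.pi * (months - 6) / 12.0)


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate all raster layers and the county/province partition."""
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    grid_kw = dict(origin=(0.0, config.grid_rows * config.cell_size),
                   cell_size=config.cell_size, crs_tag="synthetic")

    def grid(values: np.ndarray) -> RasterGrid:
        return RasterGrid(values, **grid_kw)

    # elevation: smoothed noise rescaled exactly onto the configured range
    lo, hi = config.elevation_range
    z_elev = _smooth_field(rng, shape, config.autocorrelation_length)
    elev = lo + (hi - lo) * (z_elev - z_elev.min()) / (z_elev.max() - z_elev.min())

    # temperature: shared spatial field + seasonal cycle + elevation lapse
    t_mean, t_sd, t_amp = config.temperature_params
    z_temp = _smooth_field(rng, shape, config.autocorrelation_length)
    lapse = config.lapse_rate_c_per_km * (elev - elev.mean()) / 1000.0
    season_t = _seasonal_cycle(t_amp)
    monthly_t = [
        grid(t_mean + t_sd * z_temp - lapse + season_t[m]
             + 0.3 * t_sd * _smooth_field(rng, shape, config.autocorrelation_length))
        for m in range(12)
    ]

    # precipitation: wet-season weighting of a spatial mean field, floored at 0
    p_mean, p_sd = config.precipitation_params
    z_prec = _smooth_field(rng, shape, config.autocorrelation_length)
    season_p = 1.0 + 0.6 * np.cos(2.0 * np.pi * (np.arange(12) - 6) / 12.0)
    monthly_p = [
        grid(np.clip(
            season_p[m] * (p_mean + p_sd * z_prec)
            + 0.2 * p_sd * _smooth_field(rng, shape, config.autocorrelation_length),
            0.0, None))
        for m in range(12)
    ]

    # land cover: quantile slices of a smooth field -> contiguous patches
    weights = np.array([w for _, _, w in config.landcover_classes], dtype=float)
    weights /= weights.sum()
    z_lc = _smooth_field(rng, shape, config.autocorrelation_length)
    edges = np.quantile(z_lc, np.cumsum(weights)[:-1])
    class_index = np.searchsorted(edges, z_lc, side="right")
    ids = np.array([cid for cid, _, _ in config.landcover_classes])
    landcover = grid(ids[class_index].astype(float))

    # counties: Voronoi regions of random distinct seed cells (labels 1..n)
    n_cells = config.grid_rows * config.grid_cols
    seed_cells = rng.choice(n_cells, size=config.n_counties, replace=False)
    seed_rc = np.column_stack(np.unravel_index(seed_cells, shape)).astype(float)
    rr, cc = np.meshgrid(np.arange(config.grid_rows), np.arange(config.grid_cols),
                         indexing="ij")
    cells = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    from scipy.spatial import cKDTree

    county_idx = cKDTree(seed_rc).query(cells)[1]
    county_labels = grid((county_idx + 1).reshape(shape).astype(float))

    # provinces: nearest of n_provinces province seeds, empties filled by
    # stealing the county whose seed lies closest to the empty province seed
    prov_seed_rc = seed_rc[rng.choice(config.n_counties, size=config.n_provinces,
                                      replace=False)]
    prov_of_county = cKDTree(prov_seed_rc).query(seed_rc)[1]
    for p in range(config.n_provinces):
        if not (prov_of_county == p).any():
            d = np.linalg.norm(seed_rc - prov_seed_rc[p], axis=1)
            for j in np.argsort(d):
                if (prov_of_county == prov_of_county[j]).sum() > 1:
                    prov_of_county[j] = p
                    break
    county_province = pd.DataFrame(
        {
            "county_id": np.arange(1, config.n_counties + 1),
            "province": prov_of_county + 1,
        }
    )

    truth = {
        "config": {
            **{k: v for k, v in asdict(config).items()},
        },
        "county_seed_cells": seed_rc.astype(int).tolist(),
    }
    return Landscape(
        elevation=grid(elev),
        monthly_temperature=monthly_t,
        monthly_precipitation=monthly_p,
        landcover=landcover,
        county_labels=county_labels,
        county_province_map=county_province,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# historical presence records
# ---------------------------------------------------------------------------

def generate_historical_records(
    counties: pd.DataFrame,
    intercept: float,
    slope_per_percent: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Draw county-level historical presence from a logistic link.

    presence ~ Bernoulli(expit(intercept + slope_per_percent * percent)),
    where percent is each county's percent suitable habitat in [0, 100].
    Returns the county table with a ``presence`` column plus the ground
    truth used to generate it.
    """
    if "percent_suitable" not in counties.columns:
        raise ValueError("county table lacks a percent_suitable column")
    pct = counties["percent_suitable"].to_numpy(dtype=float)
    if np.isnan(pct).any():
        raise ValueError("percent_suitable contains missing values")
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("percent_suitable must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    p = expit(intercept + slope_per_percent * pct)
    out = counties.copy()
    out["presence"] = rng.random(len(out)) < p
    out["presence"] = out["presence"].astype(int)
    truth = {
        "intercept": intercept,
        "slope_per_percent": slope_per_percent,
        "seed": seed,
        "presence_probabilities": p.tolist(),
    }
    return out, truth


# ---------------------------------------------------------------------------
# interview surveys
# ---------------------------------------------------------------------------

@dataclass
class SurveyConfig:
    """Parameters of a synthetic interview survey.

    ``baseline_report_prob`` is the reporting probability in the
    model-selected arm (selection_method = 0); ``effect_prob`` is the
    difference, on the probability scale, added in the historical arm and
    converted to the logit scale at the baseline. ``province_intercept_sd``
    and ``county_olre_sd`` are logit-scale SDs of the province random
    intercept and the county-level extra-binomial (observation-level)
    effect. ``years_ago_distribution`` is (family, mean) with family
    ``geometric`` (support 0, 1, 2, ...) or ``poisson``.
    ``undated_prob`` is the chance a reporter declines to date the
    sighting (real surveys lose roughly one dated report in eight).
    """

    respondents_per_county: int = 30
    baseline_report_prob: float = 0.45
    effect_prob: float = 0.0
    province_intercept_sd: float = 0.5
    county_olre_sd: float = 0.5
    years_ago_distribution: tuple[str, float] = ("geometric", 20.0)
    undated_prob: float = 0.12
    date_format_mix: dict = field(
        default_factory=lambda: {
            "calendar_year": 0.40,
            "years_ago": 0.30,
            "decade": 0.20,
            "age_at_sighting": 0.10,
        }
    )
    interview_years: tuple[int, ...] = (2013, 2014, 2015, 2016)
    age_mean: float = 47.1
    age_sd: float = 14.6
    age_range: tuple[int, int] = (15, 89)
    prop_male: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_report_prob < 1.0:
            raise ConfigurationError("baseline_report_prob must be in (0,1)")
        if not 0.0 < self.baseline_report_prob + self.effect_prob < 1.0:
            raise ConfigurationError("baseline + effect must stay in (0,1)")
        if self.province_intercept_sd < 0 or self.county_olre_sd < 0:
            raise ConfigurationError("random-effect SDs must be >= 0")
        if self.respondents_per_county < 1:
            raise ConfigurationError("respondents_per_county must be >= 1")
        if not 0.0 <= self.undated_prob < 1.0:
            raise ConfigurationError("undated_prob must be in [0, 1)")
        total = sum(self.date_format_mix.values())
        if abs(total - 1.0) > 1e-8 or any(v < 0 for v in self.date_format_mix.values()):
            raise ConfigurationError("date_format_mix must be nonnegative and sum to 1")

    @property
    def beta0(self) -> float:
        return float(logit(self.baseline_report_prob))

    @property
    def beta1(self) -> float:
        """Historical-arm effect on the logit scale, anchored at baseline."""
        return float(
            logit(self.baseline_report_prob + self.effect_prob) - self.beta0
        )


def _draw_years_ago(rng: np.random.Generator, family: str, mean: float, size: int) -> np.ndarray:
    if family == "geometric":
        # numpy geometric has support 1,2,...; shift to 0-based, mean = 1/p - 1
        return rng.geometric(1.0 / (mean + 1.0), size=size) - 1
    if family == "poisson":
        return rng.poisson(mean, size=size)
    raise ConfigurationError(f"unknown years-ago family {family!r}")


def generate_interviews(
    counties: pd.DataFrame, config: SurveyConfig
) -> tuple[pd.DataFrame, dict]:
    """Simulate one respondent-level interview dataset.

    ``counties`` needs columns ``county_id``, ``province`` and
    ``selection_method`` (0 = model-selected, 1 = historical). Per county a
    reporting probability expit(b0 + b1*method + u_province + e_county) is
    drawn; respondents report independently at that probability. Reporters
    receive a true last-sighting lag from the configured distribution,
    rendered into one of four raw date formats. Respondents assigned the
    decade format have their true lag snapped to the decade midpoint, so
    every raw report normalises back to the stored truth.

    Returns (records, truth); truth carries the logit-scale parameters and
    the realised county probabilities.
    """
    if counties.empty:
        raise ValueError("county table is empty")
    for col in ("county_id", "province", "selection_method"):
        if col not in counties.columns:
            raise ValueError(f"county table lacks required column {col!r}")
    rng = np.random.default_rng(config.seed)
    b0, b1 = config.beta0, config.beta1

    provinces = sorted(counties["province"].unique())
    u = dict(zip(provinces,
                 rng.normal(0.0, config.province_intercept_sd, len(provinces))))
    e = rng.normal(0.0, config.county_olre_sd, len(counties))

    fmt_names = list(config.date_format_mix)
    fmt_probs = np.array([config.date_format_mix[f] for f in fmt_names])
    family, mean_years = config.years_ago_distribution

    rows = []
    county_truth = []
    rid = 0
    for (row, e_c) in zip(counties.itertuples(index=False), e):
        method = int(row.selection_method)
        eta = b0 + b1 * method + u[row.province] + e_c
        p_c = float(expit(eta))
        iy = int(rng.choice(config.interview_years))
        county_truth.append(
            {"county_id": row.county_id, "province": row.province,
             "selection_method": method, "u_province": u[row.province],
             "e_county": e_c, "p_report": p_c, "interview_year": iy}
        )
        n = config.respondents_per_county
        ages = np.clip(
            np.round(rng.normal(config.age_mean, config.age_sd, n)),
            *config.age_range,
        ).astype(int)
        sexes = np.where(rng.random(n) < config.prop_male, "male", "female")
        reported = rng.random(n) < p_c
        years = _draw_years_ago(rng, family, mean_years, n)
        fmts = rng.choice(len(fmt_names), size=n, p=fmt_probs)
        for k in range(n):
            rid += 1
            rec = {
                "respondent_id": rid,
                "county_id": row.county_id,
                "province": row.province,
                "selection_method": method,
                "interview_year": iy,
                "age": int(ages[k]),
                "sex": sexes[k],
                "reported_sighting": bool(reported[k]),
                "identified_correctly": bool(reported[k] or rng.random() < 0.6),
                "raw_format": np.nan,
                "raw_value": np.nan,
                "true_years_ago": np.nan,
            }
            if reported[k] and rng.random() >= config.undated_prob:
                y = int(min(years[k], ages[k] - 5)) if ages[k] > 5 else 0
                y = max(y, 0)
                fmt = fmt_names[fmts[k]]
                if fmt == "decade":
                    # snap to the decade-midpoint convention; fall back to
                    # years_ago when the midpoint would land in the future
                    sight_year = iy - y
                    midpoint = (sight_year // 10) * 10 + 5
                    if midpoint > iy or (iy - midpoint) > max(0, ages[k] - 5):
                        fmt = "years_ago"
                    else:
                        y = iy - midpoint
                if fmt == "calendar_year":
                    raw = iy - y
                elif fmt == "years_ago":
                    raw = y
                elif fmt == "decade":
                    raw = f"{((iy - y) // 10) * 10}s"
                else:  # age_at_sighting
                    raw = int(ages[k] - y)
                rec.update(raw_format=fmt, raw_value=raw, true_years_ago=y)
            rows.append(rec)

    records = pd.DataFrame(rows)
    truth = {
        "config": {
            **{k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(config).items()},
        },
        "beta0": b0,
        "beta1": b1,
        "province_intercepts": {str(k): float(v) for k, v in u.items()},
        "counties": county_truth,
    }
    return records, truth
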