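"""Synthetic monitoring-network study generator.

Emulates the structure of a regional vineyard pest-monitoring database —
weekly scouting visits recording the percentage of 100 inflorescences or
bunches carrying *Lobesia botrana* eggs, farmer management records, coarse
categorical land-cover maps for three reference years, annual NDVI
composites, monthly weather-station series, and farm topography — with
*known* ground-truth effect sizes and variance components, so the whole
downstream pipeline (landscape metrics, response building, mixed-model
fits, subsampling experiments) can be exercised and validated without any
external data.

The generative model for a visit's infested count is

    count ~ BetaBinomial(100, p),  logit(p) = b_g + phenology(doy)
            + beta_vineyard * vineyard_cover
            + beta_grassland * grassland_cover * [generation 1]
            + beta_shrubland * shrubland_cover * [generations 2-3]
            + beta_ndvi * max(0, (NDVI - knee) / span) * [generations 2-3]
            + u_year + u_farm + u_region + u_observer + u_cultivar + e_visit

with per-generation baselines b_1 < b_2 < b_3 (infestation builds over the
season), a within-generation phenology bump peaking mid-generation, random
intercepts drawn once per level, and i.i.d. visit noise.  Beta-binomial
overdispersion makes occasional threshold exceedances possible even at low
mean infestation, as in real scouting data.

Farmer behaviour: a fixed fraction of farms never applies insecticides; the
rest spray once per run of consecutive over-threshold visits, within 7 days,
with a configurable compliance probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import landscape as lsc
from .rasters import Raster, write_raster

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "generate_landcover",
    "generate_farms",
    "generate_weather",
    "generate_ndvi_rasters",
    "simulate_visits",
    "simulate_management",
    "generate_study",
    "write_study",
]

_DEFAULT_CLASS_MIX = {
    "vineyard": 0.30,
    "olive": 0.10,
    "annual_crop": 0.15,
    "forest": 0.10,
    "shrubland": 0.15,
    "grassland": 0.10,
    "water": 0.02,
    "other": 0.08,
}

_DEFAULT_EFFECTS = {
    "vineyard": 1.5,
    "grassland_g1": 0.8,
    "shrubland": -0.8,
    "ndvi_high": -1.0,
}

_DEFAULT_RE_SD = {
    "year": 0.5,
    "farm": 0.7,
    "region": 0.4,
    "observer": 0.2,
    "cultivar": 0.2,
}

#: typical annual-composite NDVI (x 1e4) by land-cover class
_CLASS_NDVI = {
    "vineyard": 2200.0,
    "olive": 2500.0,
    "annual_crop": 2000.0,
    "forest": 3900.0,
    "shrubland": 3100.0,
    "grassland": 1800.0,
    "water": 400.0,
    "other": 1500.0,
}

#: fixed generation windows used as simulation truth (month, day) bounds
GENERATION_WINDOWS = {
    1: ((3, 1), (5, 15)),
    2: ((5, 16), (7, 15)),
    3: ((7, 16), (9, 30)),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the study design
    (about 400 farms monitored for 13 seasons by a 59-technician network
    across 17 regions, 14 cultivars, 79 weather stations)."""

    n_farms: int = 400
    n_years: int = 13
    first_year: int = 2006
    n_regions: int = 17
    n_observers: int = 59
    n_cultivars: int = 14
    n_stations: int = 79
    raster_extent_m: float = 60000.0
    cell_size_m: float = 100.0
    landcover_class_mix: dict = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX)
    )
    landcover_smooth_sigma_cells: float = 8.0
    landcover_change_fraction: float = 0.10
    effect_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    re_sd: dict = field(default_factory=lambda: dict(_DEFAULT_RE_SD))
    visit_noise_sd: float = 0.3
    betabinom_rho: float = 0.10
    generation_baselines: tuple = (-6.0, -5.3, -4.6)
    phenology_amplitude: float = 0.8
    ndvi_knee: float = 2800.0
    ndvi_span: float = 1000.0
    truth_delta: float = 1250.0
    farm_year_participation: float = 0.85
    visit_miss_rate: float = 0.10
    never_sprayer_fraction: float = 0.2
    spray_compliance: float = 0.9
    spray_threshold_pct: float = 8.0
    other_insecticide_rate: float = 0.15
    prophylactic_spray_rate: float = 0.2
    fungicide_rate: float = 3.0
    herbicide_rate: float = 1.5
    tillage_rate: float = 2.0
    irrigated_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_farms",
            "n_years",
            "n_regions",
            "n_observers",
            "n_cultivars",
            "n_stations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.raster_extent_m <= 0 or self.cell_size_m <= 0:
            raise ValueError("raster extent and cell size must be positive")
        mix = self.landcover_class_mix
        if set(mix) - set(lsc.LANDCOVER_CLASSES):
            raise ValueError(f"unknown land-cover classes in mix: {mix}")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class mix must sum to 1 (got {total})")
        if any(v < 0 for v in mix.values()):
            raise ValueError("class mix entries must be non-negative")
        for p in (
            self.never_sprayer_fraction,
            self.spray_compliance,
            self.farm_year_participation,
            self.visit_miss_rate,
            self.irrigated_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(sd < 0 for sd in self.re_sd.values()):
            raise ValueError("random-effect SDs must be >= 0")
        if self.visit_noise_sd < 0 or self.betabinom_rho < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.first_year + self.n_years))


@dataclass
class SyntheticStudy:
    """A complete generated study plus the ground truth that produced it."""

    config: SimulationConfig
    landcover_rasters: dict
    ndvi_rasters: dict
    farms: pd.DataFrame
    weather: pd.DataFrame
    visits: pd.DataFrame
    management: pd.DataFrame
    covariates: pd.DataFrame  # truth-delta covariates used in simulation
    truth: dict


# ---------------------------------------------------------------------------
# land cover and NDVI rasters


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _assign_classes(fields: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    return np.argmax(fields + offsets[:, None, None], axis=0)


def generate_landcover(config: SimulationConfig, seed=None) -> dict[int, Raster]:
    """Categorical land-cover rasters for the three reference map years.

    Classes are spatially autocorrelated (argmax over smoothed Gaussian
    fields with per-class offsets calibrated so empirical frequencies match
    the configured mix).  The 2012 and 2018 maps differ from their
    predecessor on at most ``landcover_change_fraction`` of cells, giving
    the temporal interpolation something to interpolate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.raster_extent_m / config.cell_size_m))
    if n < 1:
        raise ValueError("raster extent smaller than one cell")
    classes = lsc.LANDCOVER_CLASSES
    mix = np.array([config.landcover_class_mix.get(c, 0.0) for c in classes])
    active = mix > 0
    sigma = config.landcover_smooth_sigma_cells

    # semi-natural habitat (forest, shrubland, grassland) clusters at much
    # broader scales than cropland (sierra flanks vs cultivated plains), so
    # its coarse component is stronger: landscapes range from vineyard
    # monocultures to mosaics dominated by semi-natural cover
    coarse_amp = {
        "forest": 1.05, "shrubland": 1.05, "grassland": 1.05
    }

    def _class_fields():
        # two spatial scales: a coarse field drives landscape-scale
        # composition gradients (vineyard-dominated vs mosaic contexts), a
        # fine field interleaves classes so most neighbourhoods are mixed
        return np.stack(
            [
                coarse_amp.get(c, 0.80)
                * _smooth_field(rng, (n, n), 3.0 * sigma)
                + 0.60 * _smooth_field(rng, (n, n), sigma / 3.0)
                for c in classes
            ],
            axis=0,
        )

    fields = _class_fields()
    offsets = np.where(active, np.log(np.maximum(mix, 1e-12)), -np.inf)
    # calibrate offsets on this realisation so marginals match the mix
    for _ in range(60):
        values = _assign_classes(fields, offsets)
        freq = np.bincount(values.ravel(), minlength=len(classes)) / n**2
        err = mix[active] - freq[active]
        if np.max(np.abs(err)) < 0.002:
            break
        adj = np.log(np.maximum(mix[active], 1e-12)) - np.log(
            np.maximum(freq[active], 1e-6)
        )
        offsets[active] += 0.6 * adj
    values = _assign_classes(fields, offsets)

    ref_years = [2006, 2012, 2018]
    rasters = {}
    prev = values
    for i, ry in enumerate(ref_years):
        if i > 0:
            change = _smooth_field(rng, (n, n), sigma / 2)
            thresh = np.quantile(change, 1.0 - config.landcover_change_fraction)
            mask = change > thresh
            new_values = _assign_classes(_class_fields(), offsets)
            prev = prev.copy()
            prev[mask] = new_values[mask]
        rasters[ry] = Raster(
            values=prev.astype(np.uint8),
            x_origin=0.0,
            y_origin=config.raster_extent_m,
            cell_size=config.cell_size_m,
            tags={"year": ry, "kind": "landcover"},
        )
    return rasters


def generate_ndvi_rasters(
    config: SimulationConfig, landcover: dict[int, Raster], seed=None
) -> dict[int, Raster]:
    """Annual NDVI composites (x 1e4): class-typical level + smooth noise
    + a common year anomaly."""
    rng = np.random.default_rng(
        (config.seed + 1) if seed is None else seed
    )
    classes = lsc.LANDCOVER_CLASSES
    class_ndvi = np.array([_CLASS_NDVI[c] for c in classes])
    ref_years = sorted(landcover)
    out = {}
    for year in config.years:
        ry = min(ref_years, key=lambda r: abs(r - year))
        lc = landcover[ry].values
        base = class_ndvi[lc.astype(int)]
        noise = _smooth_field(rng, lc.shape, 8.0) * 250.0
        anomaly = rng.normal(0.0, 120.0)
        vals = np.clip(base + noise + anomaly, 0, 10000)
        out[year] = Raster(
            values=vals.astype(np.float32),
            x_origin=0.0,
            y_origin=config.raster_extent_m,
            cell_size=config.cell_size_m,
            tags={"year": year, "kind": "ndvi"},
        )
    return out


# ---------------------------------------------------------------------------
# farms, regions, weather


def generate_farms(
    config: SimulationConfig,
    landcover: dict[int, Raster] | None = None,
    seed=None,
) -> pd.DataFrame:
    """Farm sites with region, cultivar, topography and irrigation.

    Monitored farms are vineyards, so when a land-cover map is supplied the
    sites are drawn from its vineyard cells (jittered within the cell);
    otherwise placement is uniform.  Farms keep a >= 2 km margin from the
    raster edge so ring metrics are always computable.  Regions are Voronoi
    cells of random centres; observers are assigned to regions round-robin
    (one farm-year is later visited by one observer from its region).
    Slope is strongly correlated with altitude by construction, exercising
    the collinearity screen.
    """
    rng = np.random.default_rng(
        (config.seed + 2) if seed is None else seed
    )
    extent = config.raster_extent_m
    margin = 2000.0 + config.cell_size_m
    if extent <= 2 * margin:
        raise ValueError("raster extent too small to place farms with margin")
    if landcover is not None:
        ref = landcover[min(landcover)]
        code = lsc.LANDCOVER_CLASSES.index("vineyard")
        rows, cols = np.where(ref.values == code)
        cx = ref.x_origin + (cols + 0.5) * ref.cell_size
        cy = ref.y_origin - (rows + 0.5) * ref.cell_size
        ok = (
            (cx >= margin)
            & (cx <= extent - margin)
            & (cy >= margin)
            & (cy <= extent - margin)
        )
        cx, cy = cx[ok], cy[ok]
        if len(cx) < config.n_farms:
            raise ValueError(
                "not enough vineyard cells with edge margin to place farms"
            )
        pick = rng.choice(len(cx), size=config.n_farms, replace=False)
        jitter = rng.uniform(
            -0.4 * ref.cell_size, 0.4 * ref.cell_size, (config.n_farms, 2)
        )
        xy = np.column_stack([cx[pick], cy[pick]]) + jitter
    else:
        xy = rng.uniform(margin, extent - margin, size=(config.n_farms, 2))
    centers = rng.uniform(0, extent, size=(config.n_regions, 2))
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    region = d2.argmin(axis=1)

    alt_grad = 300.0 * xy[:, 1] / extent
    altitude = 150.0 + alt_grad + rng.normal(0, 60.0, config.n_farms)
    slope = 0.04 * altitude + rng.normal(0, 2.0, config.n_farms)
    aspect = rng.uniform(0, 360, config.n_farms)
    cultivar = rng.integers(0, config.n_cultivars, config.n_farms)
    irrigated = rng.random(config.n_farms) < config.irrigated_fraction
    return pd.DataFrame(
        {
            "farm_id": np.arange(config.n_farms),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "region": region,
            "cultivar": cultivar,
            "altitude": altitude,
            "slope": slope,
            "aspect": aspect,
            "irrigated": irrigated.astype(int),
        }
    )


def generate_weather(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Monthly temperature / precipitation series at the weather stations.

    A Mediterranean seasonal cycle plus spatially varying station offsets
    (temperature falls with the same south-north gradient that drives
    altitude) and year-month noise.
    """
    rng = np.random.default_rng(
        (config.seed + 3) if seed is None else seed
    )
    extent = config.raster_extent_m
    xy = rng.uniform(0, extent, size=(config.n_stations, 2))
    months = np.arange(1, 13)
    t_season = 17.0 + 9.0 * np.cos((months - 7.5) * 2 * np.pi / 12.0)
    p_season = 55.0 - 45.0 * np.cos((months - 1.0) * 2 * np.pi / 12.0)
    t_off = -3.0 * xy[:, 1] / extent + rng.normal(0, 1.0, config.n_stations)
    p_off = 15.0 * xy[:, 1] / extent + rng.normal(0, 8.0, config.n_stations)
    rows = []
    for year in config.years:
        t_noise = rng.normal(0, 0.8, (config.n_stations, 12))
        p_noise = rng.normal(0, 10.0, (config.n_stations, 12))
        temp = t_season[None, :] + t_off[:, None] + t_noise
        prec = np.maximum(p_season[None, :] + p_off[:, None] + p_noise, 0.0)
        for s in range(config.n_stations):
            for m in range(12):
                rows.append(
                    (s, xy[s, 0], xy[s, 1], year, m + 1, temp[s, m], prec[s, m])
                )
    return pd.DataFrame(
        rows,
        columns=[
            "station_id",
            "x",
            "y",
            "year",
            "month",
            "temperature_c",
            "precip_mm",
        ],
    )


# ---------------------------------------------------------------------------
# visits


def _generation_of_dates(dates: pd.Series) -> np.ndarray:
    """Generation (1/2/3) of each date by the fixed seasonal windows; 0
    outside March-September."""
    md = dates.dt.month * 100 + dates.dt.day
    gen = np.zeros(len(dates), dtype=int)
    for g, ((m0, d0), (m1, d1)) in GENERATION_WINDOWS.items():
        lo, hi = m0 * 100 + d0, m1 * 100 + d1
        gen[(md >= lo) & (md <= hi)] = g
    return gen


def _phenology_bump(dates: pd.Series, gen: np.ndarray, amplitude: float):
    """Within-generation bump peaking mid-window, zero at the boundaries."""
    out = np.zeros(len(dates))
    year = dates.dt.year
    doy = dates.dt.dayofyear.to_numpy()
    for g, ((m0, d0), (m1, d1)) in GENERATION_WINDOWS.items():
        sel = gen == g
        if not np.any(sel):
            continue
        ystart = pd.to_datetime(
            {"year": year[sel], "month": m0, "day": d0}
        ).dt.dayofyear.to_numpy()
        yend = pd.to_datetime(
            {"year": year[sel], "month": m1, "day": d1}
        ).dt.dayofyear.to_numpy()
        frac = (doy[sel] - ystart) / np.maximum(yend - ystart, 1)
        out[sel] = amplitude * np.sin(np.pi * np.clip(frac, 0, 1))
    return out


def simulate_visits(
    farms: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    seed=None,
) -> pd.DataFrame:
    """Weekly scouting visits with beta-binomially overdispersed counts.

    ``covariates`` must provide vineyard / grassland / shrubland / ndvi for
    every (farm_id, year) the farm is active; missing farm-years raise.  One
    observer (from the farm's region) scouts a farm for a whole season.
    """
    rng = np.random.default_rng(
        (config.seed + 4) if seed is None else seed
    )
    years = config.years
    need = ["vineyard", "grassland", "shrubland", "ndvi"]
    cov = covariates.set_index(["farm_id", "year"])
    missing = [
        (f, y)
        for f in farms["farm_id"]
        for y in years
        if (f, y) not in cov.index
    ]
    if missing:
        raise ValueError(
            f"missing landscape covariates for farm-years: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )

    sd = config.re_sd
    re_year = rng.normal(0, sd.get("year", 0), len(years))
    re_farm = rng.normal(0, sd.get("farm", 0), config.n_farms)
    re_region = rng.normal(0, sd.get("region", 0), config.n_regions)
    re_obs = rng.normal(0, sd.get("observer", 0), config.n_observers)
    re_cult = rng.normal(0, sd.get("cultivar", 0), config.n_cultivars)
    obs_region = np.arange(config.n_observers) % config.n_regions

    frames = []
    farm_ids = farms["farm_id"].to_numpy()
    farm_region = farms["region"].to_numpy()
    farm_cult = farms["cultivar"].to_numpy()
    observers_by_region = {
        r: np.where(obs_region == r)[0] for r in range(config.n_regions)
    }
    eff = config.effect_sizes

    for yi, year in enumerate(years):
        active = rng.random(config.n_farms) < config.farm_year_participation
        if not np.any(active):
            continue
        week_dates = pd.date_range(
            f"{year}-03-01", f"{year}-09-30", freq="7D"
        )
        nvis = len(week_dates)
        af = np.where(active)[0]
        # observer for the farm-year, drawn from the farm's region pool
        obs_ids = np.array(
            [
                rng.choice(observers_by_region[farm_region[i]])
                if len(observers_by_region[farm_region[i]])
                else 0
                for i in af
            ]
        )
        covs = cov.loc[
            [(farm_ids[i], year) for i in af], need
        ].to_numpy()
        vine, grass, shrub, ndvi = covs.T
        ndvi_hi = np.maximum(0.0, (ndvi - config.ndvi_knee) / config.ndvi_span)

        dates = pd.Series(np.tile(week_dates, len(af)))
        gen = _generation_of_dates(dates)
        phen = _phenology_bump(dates, gen, config.phenology_amplitude)
        base = np.array([0.0, *config.generation_baselines])[gen]

        rep = np.repeat(np.arange(len(af)), nvis)
        eta = (
            base
            + phen
            + eff.get("vineyard", 0.0) * vine[rep]
            + eff.get("grassland_g1", 0.0) * grass[rep] * (gen == 1)
            + eff.get("shrubland", 0.0) * shrub[rep] * (gen >= 2)
            + eff.get("ndvi_high", 0.0) * ndvi_hi[rep] * (gen >= 2)
            + re_year[yi]
            + re_farm[af][rep]
            + re_region[farm_region[af][rep]]
            + re_obs[obs_ids[rep]]
            + re_cult[farm_cult[af][rep]]
        )
        if config.visit_noise_sd > 0:
            eta = eta + rng.normal(0, config.visit_noise_sd, len(eta))
        p = 1.0 / (1.0 + np.exp(-eta))
        rho = config.betabinom_rho
        if rho > 0:
            conc = (1.0 - rho) / rho
            a = np.maximum(p * conc, 1e-9)
            b = np.maximum((1.0 - p) * conc, 1e-9)
            p_draw = rng.beta(a, b)
        else:
            p_draw = p
        count = rng.binomial(100, p_draw)

        keep = rng.random(len(eta)) >= config.visit_miss_rate
        frames.append(
            pd.DataFrame(
                {
                    "farm_id": farm_ids[af][rep][keep],
                    "date": dates.to_numpy()[keep],
                    "year": year,
                    "observer": obs_ids[rep][keep],
                    "infested_pct": count[keep].astype(float),
                    "generation_true": gen[keep],
                }
            )
        )
    visits = pd.concat(frames, ignore_index=True)
    visits["date"] = pd.to_datetime(visits["date"])
    return visits


# ---------------------------------------------------------------------------
# management


def simulate_management(
    visits: pd.DataFrame, config: SimulationConfig, seed=None
) -> pd.DataFrame:
    """Farmer responses to scouting plus background field operations.

    Never-sprayer farms (probability ``never_sprayer_fraction``, fixed for
    the whole study) produce no insecticide rows of any kind.  Other farms
    spray once per run of consecutive over-threshold visits, within 1-7
    days, with probability ``spray_compliance``; they also apply
    other-target insecticides at a low background rate.  Fungicide,
    herbicide and tillage events occur on all farms at Poisson rates.
    """
    rng = np.random.default_rng(
        (config.seed + 5) if seed is None else seed
    )
    farm_ids = np.sort(visits["farm_id"].unique())
    never = {
        f: rng.random() < config.never_sprayer_fraction for f in farm_ids
    }
    rows = []
    thr = config.spray_threshold_pct
    v = visits.sort_values(["farm_id", "date"])
    for (farm, year), grp in v.groupby(["farm_id", "year"], sort=True):
        exceed = (grp["infested_pct"] > thr).to_numpy()
        dates = grp["date"].to_numpy()
        if not never[farm]:
            # one spray opportunity per run of consecutive exceedances
            run_start = exceed & ~np.concatenate(([False], exceed[:-1]))
            for d in dates[run_start]:
                if rng.random() < config.spray_compliance:
                    delay = int(rng.integers(1, 8))
                    rows.append(
                        (
                            farm,
                            year,
                            pd.Timestamp(d) + pd.Timedelta(days=delay),
                            "insecticide",
                            "lobesia_botrana",
                        )
                    )
            for _ in range(rng.poisson(config.other_insecticide_rate)):
                rows.append(
                    (
                        farm,
                        year,
                        pd.Timestamp(f"{year}-06-01")
                        + pd.Timedelta(days=int(rng.integers(0, 90))),
                        "insecticide",
                        "other",
                    )
                )
            # occasional prophylactic sprays not triggered by scouting,
            # as observed on farms that do not strictly follow IPM timing
            for _ in range(rng.poisson(config.prophylactic_spray_rate)):
                rows.append(
                    (
                        farm,
                        year,
                        pd.Timestamp(f"{year}-05-15")
                        + pd.Timedelta(days=int(rng.integers(0, 100))),
                        "insecticide",
                        "lobesia_botrana",
                    )
                )
        for etype, rate in (
            ("fungicide", config.fungicide_rate),
            ("herbicide", config.herbicide_rate),
            ("tillage", config.tillage_rate),
        ):
            for _ in range(rng.poisson(rate)):
                rows.append(
                    (
                        farm,
                        year,
                        pd.Timestamp(f"{year}-04-01")
                        + pd.Timedelta(days=int(rng.integers(0, 150))),
                        etype,
                        "",
                    )
                )
    return pd.DataFrame(
        rows, columns=["farm_id", "year", "date", "event_type", "target_pest"]
    )


# ---------------------------------------------------------------------------
# full study


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete, internally consistent synthetic study."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(6) % (2**31)]
    landcover = generate_landcover(config, seeds[0])
    ndvi = generate_ndvi_rasters(config, landcover, seeds[1])
    farms = generate_farms(config, landcover, seeds[2])
    weather = generate_weather(config, seeds[3])
    covariates = lsc.compute_landscape_covariates(
        landcover,
        ndvi,
        farms,
        deltas=(config.truth_delta,),
        years=config.years,
    )
    sim_cov = covariates[covariates["delta"] == config.truth_delta]
    visits = simulate_visits(farms, sim_cov, config, seeds[4])
    management = simulate_management(visits, config, seeds[5])
    truth = {
        "effect_sizes": dict(config.effect_sizes),
        "re_sd": dict(config.re_sd),
        "generation_baselines": list(config.generation_baselines),
        "truth_delta": config.truth_delta,
        "seed": config.seed,
    }
    return SyntheticStudy(
        config=config,
        landcover_rasters=landcover,
        ndvi_rasters=ndvi,
        farms=farms,
        weather=weather,
        visits=visits,
        management=management,
        covariates=covariates,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write all study artefacts (CSV tables, TIFF rasters, truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.farms.to_csv(outdir / "farms.csv", index=False)
    v = study.visits.copy()
    v["date"] = v["date"].dt.strftime("%Y-%m-%d")
    v.to_csv(outdir / "visits.csv", index=False)
    m = study.management.copy()
    m["date"] = pd.to_datetime(m["date"]).dt.strftime("%Y-%m-%d")
    m.to_csv(outdir / "management.csv", index=False)
    study.weather.to_csv(outdir / "weather.csv", index=False)
    study.covariates.to_csv(outdir / "landscape_covariates.csv", index=False)
    for year, raster in study.landcover_rasters.items():
        write_raster(outdir / f"landcover_{year}.tif", raster)
    for year, raster in study.ndvi_rasters.items():
        write_raster(outdir / f"ndvi_{year}.tif", raster)
    with open(outdir / "truth.json", "w") as fh:
        cfg = asdict(study.config)
        json.dump({"truth": study.truth, "config": cfg}, fh, indent=2)
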