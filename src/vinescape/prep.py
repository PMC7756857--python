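"""From raw visit and management records to model-ready response tables.

The modelling works on farm-year aggregates.  Visits are first assigned to
one of the pest's three within-season generations — boundaries estimated
from a seasonal smooth of infestation (troughs between the three flight
peaks), with a fixed fallback — then aggregated per farm-year-generation
(visit count, mean infestation, number of visits exceeding the 8% economic
injury threshold) and per farm-year season (visit count, targeted
insecticide applications).  Sparse farm-years are filtered (fewer than 4
visits in a generation, fewer than 10 in the season).  Regional climate is
summarised by two principal components each for station-level monthly
temperature and precipitation, inherited from the nearest station; a
collinearity screen with preference ordering drops redundant covariates
(|r| > 0.5, e.g. slope in favour of altitude).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import build_spline_basis

__all__ = [
    "GenerationWindow",
    "ClimatePCA",
    "FALLBACK_WINDOWS",
    "estimate_generation_windows",
    "assign_generations",
    "build_responses",
    "apply_filters",
    "climate_pca",
    "collinearity_screen",
    "flag_never_sprayers",
    "attach_covariates",
]


@dataclass(frozen=True)
class GenerationWindow:
    """One generation's day-of-year window (inclusive, leap-free doy)."""

    generation: int
    start_day: int
    end_day: int


def _doy(month: int, day: int) -> int:
    """Day-of-year on the fixed non-leap calendar."""
    return int(pd.Timestamp(2001, month, day).dayofyear)


#: fixed fallback: March 1 - May 15, May 16 - July 15, July 16 - September 30
FALLBACK_WINDOWS = (
    GenerationWindow(1, _doy(3, 1), _doy(5, 15)),
    GenerationWindow(2, _doy(5, 16), _doy(7, 15)),
    GenerationWindow(3, _doy(7, 16), _doy(9, 30)),
)

_SEASON_START = _doy(3, 1)
_SEASON_END = _doy(9, 30)


def _nonleap_doy(dates: pd.Series) -> np.ndarray:
    """Map dates to the non-leap day-of-year so windows are year-stable."""
    return np.array(
        [_doy(m, min(d, 28) if (m == 2 and d == 29) else d)
         for m, d in zip(dates.dt.month, dates.dt.day)]
    )


def estimate_generation_windows(
    visits: pd.DataFrame, basis_dim: int = 10
) -> list[GenerationWindow]:
    """Generation boundaries from the seasonal infestation curve.

    Fits a cubic regression spline (basis dimension ``basis_dim``) of visit
    infestation on day-of-year, pooling all farms and years, and places the
    two generation boundaries at the interior local minima of the fitted
    curve.  If the curve does not show at least two interior minima (e.g. a
    monotone season), the fixed fallback windows are used with a warning.
    When more than two minima appear, the two with the lowest fitted values
    are taken.
    """
    doy = _nonleap_doy(visits["date"])
    in_season = (doy >= _SEASON_START) & (doy <= _SEASON_END)
    if not np.any(in_season):
        raise ValueError("no visits in the March-September season")
    x = doy[in_season].astype(float)
    y = visits.loc[in_season, "infested_pct"].to_numpy(dtype=float)

    basis = build_spline_basis(x, k=basis_dim)
    X = np.column_stack([np.ones(len(x)), basis.X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    grid = np.arange(_SEASON_START, _SEASON_END + 1, dtype=float)
    G = np.column_stack([np.ones(len(grid)), basis.matrix(grid)])
    fit = G @ beta

    interior = np.where(
        (fit[1:-1] < fit[:-2]) & (fit[1:-1] <= fit[2:])
    )[0] + 1
    if len(interior) < 2:
        warnings.warn(
            "seasonal curve shows fewer than two interior minima; "
            "falling back to fixed generation windows",
            stacklevel=2,
        )
        return list(FALLBACK_WINDOWS)
    if len(interior) > 2:
        interior = interior[np.argsort(fit[interior])[:2]]
    b1, b2 = np.sort(grid[interior].astype(int))
    return [
        GenerationWindow(1, _SEASON_START, b1),
        GenerationWindow(2, b1 + 1, b2),
        GenerationWindow(3, b2 + 1, _SEASON_END),
    ]


def assign_generations(
    visits: pd.DataFrame, windows: list[GenerationWindow]
) -> pd.DataFrame:
    """Return a copy of ``visits`` with a ``generation`` column (0 = outside
    all windows)."""
    doy = _nonleap_doy(visits["date"])
    gen = np.zeros(len(visits), dtype=int)
    for w in windows:
        gen[(doy >= w.start_day) & (doy <= w.end_day)] = w.generation
    out = visits.copy()
    out["generation"] = gen
    return out


def build_responses(
    visits: pd.DataFrame,
    management: pd.DataFrame,
    windows: list[GenerationWindow],
    threshold: float = 8.0,
    target_pest: str = "lobesia_botrana",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate visits and sprays into the modelling response tables.

    Returns ``(per_generation, per_season)``:

    * per farm-year-generation: ``n_visits``, ``mean_infestation``
      (arithmetic mean of visit percentages), ``n_exceed`` (visits with
      infestation strictly above ``threshold``);
    * per farm-year: season visit totals, ``spray_count`` (insecticide rows
      whose target is the focal pest), exceedance fraction and an
      ``ever_exceeded`` flag.

    Farm-year-generations with no visits yield no row.  Management rows for
    farms absent from the visit table raise.
    """
    known = set(visits["farm_id"].unique())
    unknown = set(management["farm_id"].unique()) - known
    if unknown:
        raise ValueError(
            f"management rows reference unknown farms: {sorted(unknown)[:10]}"
        )

    v = assign_generations(visits, windows)
    v = v[v["generation"] > 0].copy()
    v["exceed"] = (v["infested_pct"] > threshold).astype(int)

    aggs = {
        "n_visits": ("infested_pct", "size"),
        "mean_infestation": ("infested_pct", "mean"),
        "n_exceed": ("exceed", "sum"),
    }
    if "observer" in v.columns:  # one observer scouts a farm-year
        aggs["observer"] = ("observer", "first")

    gen = (
        v.groupby(["farm_id", "year", "generation"]).agg(**aggs).reset_index()
    )
    season = v.groupby(["farm_id", "year"]).agg(**aggs).reset_index()
    sprays = (
        management[
            (management["event_type"] == "insecticide")
            & (management["target_pest"] == target_pest)
        ]
        .groupby(["farm_id", "year"])
        .size()
        .rename("spray_count")
        .reset_index()
    )
    season = season.merge(sprays, on=["farm_id", "year"], how="left")
    season["spray_count"] = season["spray_count"].fillna(0).astype(int)
    season["fraction_exceeded"] = season["n_exceed"] / season["n_visits"]
    season["ever_exceeded"] = (season["n_exceed"] > 0).astype(int)
    return gen, season


def apply_filters(
    gen_responses: pd.DataFrame,
    season_responses: pd.DataFrame,
    min_visits_gen: int = 4,
    min_visits_season: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop under-visited rows; keep an itemised account of what was lost.

    Generation rows need at least ``min_visits_gen`` visits; season rows at
    least ``min_visits_season``.  Both bounds are inclusive ("fewer than"
    is dropped).
    """
    keep_g = gen_responses["n_visits"] >= min_visits_gen
    keep_s = season_responses["n_visits"] >= min_visits_season
    report = {
        "generation_rows_in": int(len(gen_responses)),
        "generation_rows_dropped": int((~keep_g).sum()),
        "season_rows_in": int(len(season_responses)),
        "season_rows_dropped": int((~keep_s).sum()),
        "min_visits_gen": min_visits_gen,
        "min_visits_season": min_visits_season,
    }
    return (
        gen_responses[keep_g].reset_index(drop=True),
        season_responses[keep_s].reset_index(drop=True),
        report,
    )


@dataclass
class ClimatePCA:
    """Station-level PCA of monthly climate normals (one per variable)."""

    variable: str
    months: list
    loadings: np.ndarray  # (n_months, n_axes)
    scores: pd.DataFrame  # station_id -> axis scores
    variance_explained: np.ndarray


def _station_pca(matrix: pd.DataFrame, variable: str, n_axes: int = 2):
    X = matrix.to_numpy(dtype=float)
    keep = X.std(axis=0) > 1e-12
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance monthly columns "
            f"from the {variable} PCA",
            stacklevel=3,
        )
        X = X[:, keep]
    if X.shape[1] < 2 or np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        raise ValueError(f"{variable} PCA needs >= 2 effective dimensions")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (s**2).sum()
    scores = U[:, :n_axes] * s[:n_axes]
    return ClimatePCA(
        variable=variable,
        months=list(np.array(matrix.columns)[keep]),
        loadings=Vt[:n_axes].T,
        scores=pd.DataFrame(
            scores,
            index=matrix.index,
            columns=[f"{variable}_pc{i + 1}" for i in range(n_axes)],
        ),
        variance_explained=var,
    )


def climate_pca(
    weather: pd.DataFrame, farms: pd.DataFrame
) -> tuple[ClimatePCA, ClimatePCA, pd.DataFrame]:
    """Two station-level PCAs (temperature, precipitation) + farm scores.

    Stations are summarised by their mean monthly values across years (12
    columns each); each PCA is on centred station-level data and the first
    two axes are retained.  Every farm inherits the scores of its nearest
    station (planar Euclidean distance, ties to the lowest station id).
    """
    if weather["station_id"].nunique() < 3:
        raise ValueError("need at least 3 weather stations")
    temp = weather.pivot_table(
        index="station_id", columns="month", values="temperature_c"
    )
    prec = weather.pivot_table(
        index="station_id", columns="month", values="precip_mm"
    )
    pca_t = _station_pca(temp, "temp")
    pca_p = _station_pca(prec, "precip")

    st = (
        weather[["station_id", "x", "y"]]
        .drop_duplicates("station_id")
        .sort_values("station_id")
        .reset_index(drop=True)
    )
    d2 = (farms["x"].to_numpy()[:, None] - st["x"].to_numpy()[None, :]) ** 2 + (
        farms["y"].to_numpy()[:, None] - st["y"].to_numpy()[None, :]
    ) ** 2
    # argmin returns the first (lowest-id) station on ties
    nearest = st["station_id"].to_numpy()[np.argmin(d2, axis=1)]
    scores = pd.concat([pca_t.scores, pca_p.scores], axis=1)
    farm_scores = scores.loc[nearest].reset_index()
    farm_scores.insert(0, "farm_id", farms["farm_id"].to_numpy())
    return pca_t, pca_p, farm_scores


def collinearity_screen(
    covariates: pd.DataFrame,
    r_max: float = 0.5,
    preferences: tuple = ("altitude", "vineyard"),
) -> tuple[list, dict]:
    """Greedy pairwise collinearity filter.

    Repeatedly finds the pair with the largest |Pearson r| above ``r_max``
    and drops its less-preferred member.  ``preferences`` ranks covariates
    to keep (earlier = higher priority, e.g. altitude over slope, vineyard
    over annual-crop cover); unranked covariates lose to ranked ones and
    among themselves the later column loses.  Constant covariates are
    dropped up front with a warning.  Returns (retained columns, report).
    """
    cols = list(covariates.columns)
    dropped = []
    for c in cols[:]:
        if covariates[c].std() <= 1e-12 or covariates[c].isna().all():
            warnings.warn(f"dropping constant covariate {c!r}", stacklevel=2)
            cols.remove(c)
            dropped.append({"covariate": c, "reason": "constant"})

    def rank(c):
        if c in preferences:
            return preferences.index(c)
        return len(preferences) + list(covariates.columns).index(c)

    corr = covariates[cols].corr()
    while True:
        sub = covariates[cols].corr().abs()
        np.fill_diagonal(sub.values, 0.0)
        if sub.values.max() <= r_max or len(cols) < 2:
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = sub.index[i], sub.columns[j]
        loser = b if rank(a) <= rank(b) else a
        winner = a if loser == b else b
        cols.remove(loser)
        dropped.append(
            {
                "covariate": loser,
                "reason": f"|r|={sub.loc[a, b]:.3f} with {winner}",
            }
        )
    report = {
        "pairwise_r": corr,
        "dropped": dropped,
        "retained": list(cols),
        "r_max": r_max,
    }
    return cols, report


def flag_never_sprayers(
    management: pd.DataFrame, farms=None
) -> set:
    """Farms with zero insecticide rows of *any* target across all years.

    ``farms`` optionally widens the universe to farms with no management
    rows at all; by default the universe is the farms present in the table.
    """
    universe = (
        set(farms)
        if farms is not None
        else set(management["farm_id"].unique())
    )
    sprayers = set(
        management.loc[
            management["event_type"] == "insecticide", "farm_id"
        ].unique()
    )
    return universe - sprayers


def attach_covariates(
    responses: pd.DataFrame,
    landscape_cov: pd.DataFrame,
    farms: pd.DataFrame,
    farm_climate: pd.DataFrame,
    management: pd.DataFrame | None = None,
    delta: float = 1250.0,
) -> pd.DataFrame:
    """Join landscape, topography, climate (and optionally management
    counts) onto a response table keyed by (farm_id, year).

    Landscape rows flagged ``excluded`` are dropped (water / colocation /
    edge screens); the number removed is recorded in ``attrs['n_excluded']``.
    """
    cov = landscape_cov[landscape_cov["delta"] == delta]
    n0 = len(responses)
    keep_cols = [
        "farm_id",
        "year",
        "vineyard",
        "olive",
        "annual_crop",
        "forest",
        "shrubland",
        "grassland",
        "ndvi",
        "excluded",
    ]
    out = responses.merge(
        cov[[c for c in keep_cols if c in cov.columns]],
        on=["farm_id", "year"],
        how="inner",
    )
    out = out[~out["excluded"].astype(bool)].drop(columns=["excluded"])
    out = out.merge(
        farms[
            ["farm_id", "region", "cultivar", "altitude", "slope", "aspect",
             "irrigated"]
        ],
        on="farm_id",
        how="left",
    )
    out = out.merge(farm_climate.drop(columns=["station_id"], errors="ignore"),
                    on="farm_id", how="left")
    if management is not None:
        counts = (
            management.groupby(["farm_id", "year", "event_type"])
            .size()
            .unstack(fill_value=0)
            .reset_index()
        )
        counts.columns.name = None
        rename = {
            "insecticide": "n_insecticide",
            "herbicide": "n_herbicide",
            "fungicide": "n_fungicide",
            "tillage": "n_tillage",
        }
        counts = counts.rename(columns=rename)
        out = out.merge(counts, on=["farm_id", "year"], how="left")
        for c in rename.values():
            if c in out.columns:
                out[c] = out[c].fillna(0).astype(int)
            else:
                out[c] = 0
    out.attrs["n_excluded"] = n0 - len(out)
    return out
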