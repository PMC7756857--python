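"""Subsampling detectability experiment.

How often would a conventional landscape pest-control study — a couple of
dozen sites followed for two seasons — have detected the vineyard-cover
effect that the full multi-year monitoring network reveals?  The experiment
repeatedly (500 times by default) reduces the response table to 25 farms
and two sequential years, drawing five farms from each quintile of
farm-level vineyard cover so the subsample still spans the landscape
gradient, refits a simplified model, and records the p-value of the
vineyard term.  The fraction of significant iterations estimates the
detectability of the effect at that study size.

The simplified per-iteration model drops the other landscape covariates,
treats climate and topography as linear terms, includes study year as a
fixed effect, and has no random effects; the vineyard effect stays a
penuriously small spline (basis dimension 3).  Fits are ordinary GLMs
(binomial for exceedance responses, Poisson for spray counts) and the
vineyard p-value is a 2-df likelihood-ratio test of its two basis columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import build_spline_basis

__all__ = [
    "PowerSimConfig",
    "PowerSimResult",
    "stratified_subsample",
    "fit_reduced_model",
    "run_power_simulation",
]

_LINEAR_CANDIDATES = (
    "altitude",
    "aspect",
    "temp_pc1",
    "temp_pc2",
    "precip_pc1",
    "precip_pc2",
)


@dataclass
class PowerSimConfig:
    """Design of the subsampling experiment."""

    n_iterations: int = 500
    n_farms: int = 25
    n_strata: int = 5
    farms_per_stratum: int = 5
    n_years: int = 2
    response: str = "exceedance_gen3"  # or exceedance_gen2 / sprays
    alpha: float = 0.05
    include_year_fixed_effect: bool = True
    seed: int = 0
    subsample: bool = True  #: False fits the full table each iteration

    def __post_init__(self) -> None:
        if self.subsample and self.n_strata * self.farms_per_stratum != self.n_farms:
            raise ValueError(
                "n_strata * farms_per_stratum must equal n_farms"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PowerSimResult:
    p_values: np.ndarray
    converged: np.ndarray
    alpha: float
    config: PowerSimConfig = field(repr=False)

    @property
    def n_iterations(self) -> int:
        return len(self.p_values)

    @property
    def convergence_rate(self) -> float:
        return float(np.mean(self.converged))

    @property
    def fraction_significant(self) -> float:
        ok = self.converged
        return float(np.mean(self.p_values[ok] < self.alpha))

    @property
    def mc_standard_error(self) -> float:
        f = self.fraction_significant
        n = int(self.converged.sum())
        return float(np.sqrt(f * (1.0 - f) / n))

    def to_dict(self) -> dict:
        return {
            "response": self.config.response,
            "n_iterations": self.n_iterations,
            "convergence_rate": self.convergence_rate,
            "fraction_significant": self.fraction_significant,
            "mc_standard_error": self.mc_standard_error,
            "alpha": self.alpha,
        }


def _farm_strata(responses: pd.DataFrame, n_strata: int) -> pd.Series:
    """Quintile stratum per farm from its time-averaged vineyard cover."""
    mean_cover = responses.groupby("farm_id")["vineyard"].mean()
    ranks = mean_cover.rank(method="first")
    return pd.Series(
        np.minimum(
            (n_strata * (ranks - 1) / len(ranks)).astype(int), n_strata - 1
        ),
        index=mean_cover.index,
        name="stratum",
    )


def stratified_subsample(
    responses: pd.DataFrame, config: PowerSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Reduce to ``n_farms`` farms spanning the vineyard-cover gradient and
    two consecutive study years.

    Strata are quantile bins of each farm's time-averaged vineyard cover;
    ``farms_per_stratum`` farms are drawn without replacement per stratum,
    and a consecutive year pair is drawn uniformly.  All response rows of
    the selected farm-years are returned.
    """
    strata = _farm_strata(responses, config.n_strata)
    chosen = []
    for s in range(config.n_strata):
        pool = strata.index[strata == s].to_numpy()
        if len(pool) < config.farms_per_stratum:
            raise ValueError(
                f"stratum {s} has only {len(pool)} farms; "
                f"needs {config.farms_per_stratum}"
            )
        chosen.append(
            rng.choice(pool, size=config.farms_per_stratum, replace=False)
        )
    farms = np.concatenate(chosen)
    years = np.sort(responses["year"].unique())
    pairs = [
        (y, y + config.n_years - 1)
        for y in years
        if all(y + k in years for k in range(config.n_years))
    ]
    if not pairs:
        raise ValueError("no run of consecutive study years available")
    y0, y1 = pairs[rng.integers(len(pairs))]
    out = responses[
        responses["farm_id"].isin(farms)
        & responses["year"].between(y0, y1)
    ]
    return out.reset_index(drop=True)


def _response_family(response: str):
    if response.startswith("exceedance"):
        return "binomial"
    if response == "sprays":
        return "poisson"
    raise ValueError(f"unknown powersim response {response!r}")


def fit_reduced_model(
    reduced: pd.DataFrame, config: PowerSimConfig
) -> tuple[float, bool]:
    """Vineyard-term p-value from the simplified no-random-effect GLM.

    Returns ``(p_value, converged)``.  The p-value is a likelihood-ratio
    test of the two vineyard spline columns; design or fitting failures
    mark the iteration non-converged rather than raising.
    """
    if len(reduced) == 0:
        raise ValueError("empty reduced dataset")
    family_name = _response_family(config.response)
    try:
        basis = build_spline_basis(reduced["vineyard"].to_numpy(), k=3)
    except ValueError:
        return np.nan, False
    cols = [np.ones(len(reduced)), basis.X]
    for name in _LINEAR_CANDIDATES:
        if name in reduced.columns and reduced[name].std() > 1e-12:
            cols.append(reduced[name].to_numpy(dtype=float)[:, None])
    if config.include_year_fixed_effect:
        dummies = pd.get_dummies(reduced["year"], drop_first=True)
        if dummies.shape[1]:
            cols.append(dummies.to_numpy(dtype=float))
    X = np.column_stack(
        [c if c.ndim == 2 else c[:, None] for c in cols]
    )
    X0 = np.delete(X, [1, 2], axis=1)  # drop the vineyard basis columns

    if family_name == "binomial":
        succ = reduced["n_exceed"].to_numpy(dtype=float)
        trials = reduced["n_visits"].to_numpy(dtype=float)
        y = np.column_stack([succ, trials - succ])
        fam = sm.families.Binomial()
        kwargs = {}
        if succ.sum() == 0:
            return 1.0, True  # no events: the test carries no information
    else:
        y = reduced["spray_count"].to_numpy(dtype=float)
        fam = sm.families.Poisson()
        kwargs = {
            "freq_weights": reduced["n_visits"].to_numpy(dtype=float)
        } if "n_visits" in reduced.columns else {}
        if y.sum() == 0:
            return 1.0, True
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            full = sm.GLM(y, X, family=fam, **kwargs).fit(maxiter=100)
            null = sm.GLM(y, X0, family=fam, **kwargs).fit(maxiter=100)
    except Exception:
        return np.nan, False
    if not np.all(np.isfinite(full.params)):
        return np.nan, False
    from scipy import stats

    lr = max(null.deviance - full.deviance, 0.0)
    p = float(stats.chi2.sf(lr, 2))
    return p, True


def run_power_simulation(
    responses: pd.DataFrame, config: PowerSimConfig
) -> PowerSimResult:
    """The full subsample-and-refit experiment.

    ``responses`` is the per-generation table (for exceedance responses;
    filtered to the relevant generation if a ``generation`` column is
    present) or the per-season table (for spray counts), with landscape,
    climate and topography covariates attached.  Results are a pure
    function of (data, config, seed).
    """
    if config.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    data = responses
    if "generation" in data.columns and config.response.startswith(
        "exceedance_gen"
    ):
        g = int(config.response[-1])
        data = data[data["generation"] == g].reset_index(drop=True)
    rng = np.random.default_rng(config.seed)
    pvals = np.empty(config.n_iterations)
    conv = np.zeros(config.n_iterations, dtype=bool)
    for i in range(config.n_iterations):
        sub = (
            stratified_subsample(data, config, rng)
            if config.subsample
            else data
        )
        pvals[i], conv[i] = fit_reduced_model(sub, config)
    if np.mean(conv) < 0.8:
        raise RuntimeError(
            f"only {np.mean(conv):.0%} of iterations converged; "
            "the reduced model is unstable on this data"
        )
    return PowerSimResult(
        p_values=pvals, converged=conv, alpha=config.alpha, config=config
    )
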