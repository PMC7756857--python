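"""End-to-end orchestration: simulate -> metrics -> prep -> fits -> powersim.

`run_all` sequences the whole analysis on either a synthetic study or
user-supplied tables, producing a :class:`RunReport` with per-stage row
accounting (no silent row loss), the decay-rate AIC table, model summaries,
prediction curves, deviance partitions and subsampling-power fractions.
`read_deposited_tables` adapts externally deposited CSVs to the internal
schema through an editable column mapping.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gamm, landscape, powersim, prep, synthdata

__all__ = ["PipelineConfig", "RunReport", "run_all", "read_deposited_tables"]

log = logging.getLogger("vinescape")

LANDSCAPE_SMOOTHS = ["vineyard", "forest", "shrubland", "grassland", "ndvi"]
LINEAR_TERMS = [
    "altitude",
    "aspect",
    "temp_pc1",
    "temp_pc2",
    "precip_pc1",
    "precip_pc2",
]
RANDOM_EFFECTS = ["year", "farm_id", "region", "observer", "cultivar"]
MANAGEMENT_TERMS = ["n_insecticide", "n_herbicide", "n_fungicide", "n_tillage",
                    "irrigated"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and model options for a full run."""

    output_dir: str = "vinescape_output"
    input_dir: str | None = None  #: None => simulate
    deltas: tuple = (250.0, 750.0, 1250.0)
    primary_delta: float = 1250.0
    threshold_pct: float = 8.0
    min_visits_gen: int = 4
    min_visits_season: int = 10
    single_predictor: bool = False
    with_management: bool = False
    powersim_iterations: int = 200
    powersim_responses: tuple = ("exceedance_gen2", "exceedance_gen3", "sprays")
    run_powersim: bool = True
    fit_all_generations: bool = True
    fit_infestation: bool = True
    seed: int = 0
    simulation: dict = field(default_factory=dict)  #: SimulationConfig overrides

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_pct < 100.0:
            raise ValueError("threshold must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    """Everything a run produced, JSON-serialisable."""

    seed: int
    stages: dict = field(default_factory=dict)
    row_accounting: dict = field(default_factory=dict)
    aic_table: dict = field(default_factory=dict)
    model_summaries: dict = field(default_factory=dict)
    deviance_partition: dict = field(default_factory=dict)
    morans: dict = field(default_factory=dict)
    powersim: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        text = json.dumps(self.__dict__, indent=2, default=default,
                          sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _timed(stages: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            stages[name] = {
                "seconds": round(time.perf_counter() - self.t0, 2),
                "ok": exc_type is None,
            }
            if exc_type is not None:
                stages[name]["error"] = f"{exc_type.__name__}: {exc}"
            log.info("stage %s done (%.1fs)", name, stages[name]["seconds"])

    return _Timer()


def build_model_tables(study, config: PipelineConfig):
    """Shared prep: covariates at all deltas, responses, filters, PCA.

    Returns (gen_tables, season_tables) keyed by delta, plus the prep
    report; covariate-attached, filtered, ready for fitting.
    """
    cov_all = landscape.compute_landscape_covariates(
        study.landcover_rasters,
        study.ndvi_rasters,
        study.farms,
        deltas=config.deltas,
        years=study.config.years,
    )
    windows = prep.estimate_generation_windows(study.visits)
    gen_resp, season_resp = prep.build_responses(
        study.visits, study.management, windows,
        threshold=config.threshold_pct,
    )
    gen_resp, season_resp, filter_report = prep.apply_filters(
        gen_resp, season_resp,
        min_visits_gen=config.min_visits_gen,
        min_visits_season=config.min_visits_season,
    )
    _, _, farm_scores = prep.climate_pca(study.weather, study.farms)

    gen_tables, season_tables = {}, {}
    for d in config.deltas:
        gen_tables[d] = prep.attach_covariates(
            gen_resp, cov_all, study.farms, farm_scores,
            management=study.management, delta=d,
        )
        season_tables[d] = prep.attach_covariates(
            season_resp, cov_all, study.farms, farm_scores,
            management=study.management, delta=d,
        )
    report = {
        "windows": [
            {"generation": w.generation, "start_day": w.start_day,
             "end_day": w.end_day}
            for w in windows
        ],
        "filters": filter_report,
        "landscape_rows": int(len(cov_all)),
        "landscape_excluded_farms": int(
            cov_all.loc[cov_all["excluded"], "farm_id"].nunique()
        ),
    }
    return gen_tables, season_tables, report


def _exceedance_spec(config: PipelineConfig, smooths=None) -> gamm.GAMMSpec:
    return gamm.GAMMSpec(
        family="binomial",
        response=("n_exceed", "n_visits"),
        smooth_terms=smooths or list(LANDSCAPE_SMOOTHS),
        linear_terms=list(LINEAR_TERMS)
        + (MANAGEMENT_TERMS if config.with_management else []),
        random_effects=list(RANDOM_EFFECTS),
    )


def _spray_spec(config: PipelineConfig, smooths=None) -> gamm.GAMMSpec:
    return gamm.GAMMSpec(
        family="poisson",
        response="spray_count",
        smooth_terms=smooths or list(LANDSCAPE_SMOOTHS),
        linear_terms=list(LINEAR_TERMS),
        random_effects=list(RANDOM_EFFECTS),
        weights="n_visits",
    )


def _infestation_spec(config: PipelineConfig) -> gamm.GAMMSpec:
    return gamm.GAMMSpec(
        family="negative_binomial",
        response="infestation_count",
        smooth_terms=list(LANDSCAPE_SMOOTHS),
        linear_terms=list(LINEAR_TERMS),
        random_effects=list(RANDOM_EFFECTS),
        weights="n_visits",
    )


def run_all(config: PipelineConfig) -> RunReport:
    """Execute every stage and return the run report.

    Any stage failure aborts with the stage name recorded in the report's
    ``stages`` block before the exception propagates.
    """
    report = RunReport(seed=config.seed)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _timed(report.stages, "simulate"):
        if config.input_dir is None:
            sim_cfg = synthdata.SimulationConfig(
                seed=config.seed, **config.simulation
            )
            study = synthdata.generate_study(sim_cfg)
        else:
            study = _load_study(config)
        report.row_accounting["visits"] = int(len(study.visits))
        report.row_accounting["management"] = int(len(study.management))
        report.row_accounting["farms"] = int(len(study.farms))

    with _timed(report.stages, "prep"):
        gen_tables, season_tables, prep_report = build_model_tables(
            study, config
        )
        report.row_accounting["prep"] = prep_report
        d0 = config.primary_delta
        gen_main, season_main = gen_tables[d0], season_tables[d0]
        for g in (1, 2, 3):
            report.row_accounting[f"gen{g}_rows"] = int(
                (gen_main["generation"] == g).sum()
            )
        report.row_accounting["season_rows"] = int(len(season_main))

    with _timed(report.stages, "fit"):
        fits = {}
        exc_spec = _exceedance_spec(config)
        gens = (1, 2, 3) if config.fit_all_generations else (3,)
        for g in gens:
            sub = gen_main[gen_main["generation"] == g]
            fit = gamm.fit_gamm(exc_spec, sub)
            fit_no_re = gamm.fit_gamm(gamm.strip_random_effects(exc_spec), sub)
            fits[f"exceedance_gen{g}"] = fit
            report.model_summaries[f"exceedance_gen{g}"] = fit.summary()
            de_w, de_wo = gamm.deviance_explained(fit, fit_no_re)
            report.deviance_partition[f"exceedance_gen{g}"] = {
                "with_re": de_w, "without_re": de_wo,
            }
            _morans_for(report, study, sub, fit, f"exceedance_gen{g}")
            report.curves[f"exceedance_gen{g}_vineyard"] = (
                gamm.predict_curve(fit, "vineyard").to_dict("list")
            )
        if config.fit_infestation:
            for g in gens:
                sub = gen_main[gen_main["generation"] == g].copy()
                sub["infestation_count"] = np.rint(
                    sub["mean_infestation"]
                ).astype(int)
                fit = gamm.fit_gamm(_infestation_spec(config), sub)
                fits[f"infestation_gen{g}"] = fit
                report.model_summaries[f"infestation_gen{g}"] = fit.summary()

        spray_fit = gamm.fit_gamm(_spray_spec(config), season_main)
        spray_no_re = gamm.fit_gamm(
            gamm.strip_random_effects(_spray_spec(config)), season_main
        )
        fits["sprays"] = spray_fit
        report.model_summaries["sprays"] = spray_fit.summary()
        de_w, de_wo = gamm.deviance_explained(spray_fit, spray_no_re)
        report.deviance_partition["sprays"] = {
            "with_re": de_w, "without_re": de_wo,
        }
        report.curves["sprays_vineyard"] = gamm.predict_curve(
            spray_fit, "vineyard"
        ).to_dict("list")

        if config.single_predictor:
            # sensitivity fits with one landscape predictor at a time, to
            # check that collinear covers do not drive spurious trends
            for smooth in LANDSCAPE_SMOOTHS:
                spec1 = _exceedance_spec(config, smooths=[smooth])
                spec1.single_predictor_mode = True
                sub = gen_main[gen_main["generation"] == 3]
                fit1 = gamm.fit_gamm(spec1, sub)
                report.model_summaries[
                    f"exceedance_gen3_single_{smooth}"
                ] = fit1.summary()

        never = prep.flag_never_sprayers(
            study.management, farms=study.farms["farm_id"]
        )
        thr_fits = gamm.threshold_response_models(season_main, never)
        for name, f in thr_fits.items():
            report.model_summaries[f"threshold_{name}"] = f.summary()

    with _timed(report.stages, "decay_comparison"):
        by_delta = {}
        for d in config.deltas:
            sub = gen_tables[d][gen_tables[d]["generation"] == 3]
            by_delta[d] = gamm.fit_gamm(exc_spec, sub)
        sizes = {d: f.n for d, f in by_delta.items()}
        if len(set(sizes.values())) == 1:
            table = gamm.compare_decay_rates(by_delta)
            report.aic_table = {
                "rows": table.to_dict("records"),
                "winner": table.attrs["winner"],
            }
        else:  # differing exclusions across deltas: compare on common rows
            report.aic_table = {"rows": [], "winner": None,
                                "note": f"unequal sizes {sizes}"}

    if config.run_powersim:
        with _timed(report.stages, "powersim"):
            for resp in config.powersim_responses:
                table = (
                    season_main if resp == "sprays" else gen_main
                )
                ps_cfg = powersim.PowerSimConfig(
                    n_iterations=config.powersim_iterations,
                    response=resp,
                    seed=config.seed,
                )
                result = powersim.run_power_simulation(table, ps_cfg)
                report.powersim[resp] = result.to_dict()

    report.to_json(outdir / "run_report.json")
    return report


def _morans_for(report, study, sub, fit, name):
    """Moran's I on farm-averaged deviance residuals."""
    resid = sub[["farm_id"]].copy()
    resid["r"] = fit.deviance_residuals
    by_farm = resid.groupby("farm_id")["r"].mean()
    coords = study.farms.set_index("farm_id").loc[
        by_farm.index, ["x", "y"]
    ].to_numpy()
    try:
        m = gamm.morans_i(by_farm.to_numpy(), coords)
        report.morans[name] = {"I": m.I, "p_value": m.p_value}
    except ValueError as err:
        report.morans[name] = {"error": str(err)}


# ---------------------------------------------------------------------------
# deposited-data reader

MANDATORY = {
    "visits": ["farm_id", "date", "infested_pct"],
    "management": ["farm_id", "date", "event_type", "target_pest"],
    "farms": ["farm_id", "x", "y"],
}


def read_deposited_tables(path, mapping: dict | None = None) -> dict:
    """Load visits / management / farms CSVs with a column-mapping layer.

    ``mapping`` maps internal names to deposit headers, e.g.
    ``{"visits": {"infested_pct": "PercentInfested"}}``.  Unmapped extra
    columns are kept and reported, never silently dropped; a missing
    mandatory column raises with the mapping key to edit.
    """
    path = Path(path)
    mapping = mapping or {}
    out, extras = {}, {}
    for table, mandatory in MANDATORY.items():
        fp = path / f"{table}.csv"
        if not fp.exists():
            raise FileNotFoundError(fp)
        df = pd.read_csv(fp)
        tmap = mapping.get(table, {})
        df = df.rename(columns={v: k for k, v in tmap.items()})
        missing = [c for c in mandatory if c not in df.columns]
        if missing:
            raise ValueError(
                f"{table}.csv is missing mandatory column(s) {missing}; "
                f"add entries under mapping[{table!r}] to translate the "
                "deposit's headers"
            )
        extras[table] = [
            c for c in df.columns if c not in mandatory
        ]
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"])
            if "year" not in df.columns:
                df["year"] = df["date"].dt.year
        out[table] = df
    out["unmapped_columns"] = extras
    for table, cols in extras.items():
        if cols:
            log.info("%s.csv: extra columns kept: %s", table, cols)
    return out


def _load_study(config: PipelineConfig):
    """Assemble a SyntheticStudy-shaped bundle from deposited tables plus
    rasters written by this package."""
    from .rasters import read_raster

    tables = read_deposited_tables(config.input_dir)
    indir = Path(config.input_dir)
    landcover = {}
    ndvi = {}
    for fp in sorted(indir.glob("landcover_*.tif")):
        landcover[int(fp.stem.split("_")[1])] = read_raster(fp)
    for fp in sorted(indir.glob("ndvi_*.tif")):
        ndvi[int(fp.stem.split("_")[1])] = read_raster(fp)
    if not landcover or not ndvi:
        raise FileNotFoundError(
            f"no landcover_*.tif / ndvi_*.tif rasters under {indir}"
        )
    weather = pd.read_csv(indir / "weather.csv")
    years = sorted(tables["visits"]["year"].unique())
    sim_cfg = synthdata.SimulationConfig(
        n_farms=len(tables["farms"]),
        n_years=len(years),
        first_year=int(years[0]),
        seed=config.seed,
    )
    return synthdata.SyntheticStudy(
        config=sim_cfg,
        landcover_rasters=landcover,
        ndvi_rasters=ndvi,
        farms=tables["farms"],
        weather=weather,
        visits=tables["visits"],
        management=tables["management"],
        covariates=pd.DataFrame(),
        truth={},
    )
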