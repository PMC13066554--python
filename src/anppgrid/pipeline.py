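"""End-to-end pipeline driver: simulate -> features -> compare -> tune ->
train -> predict (historical + scenarios) -> validate, with a machine-readable
manifest.

Each stage draws its randomness from a stream derived from the single run
seed, so a rerun with the same config writes byte-identical products.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import xarray as xr

from . import __version__, cv as cvs, features as feat, harness, projection, spatial, temporal, world as worldmod
from .config import derive_seed, load_config
from .grids import GridMeta, annual_cube
from .io import ProductName, format_name, write_raster

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "compare", "tune", "train", "predict", "validate")


@dataclass
class RunState:
    """In-memory products handed from stage to stage."""

    cfg: dict
    outdir: Path
    world: worldmod.SyntheticWorld | None = None
    sites: pd.DataFrame | None = None
    annual: dict[str, xr.DataArray] = field(default_factory=dict)
    normals: dict[str, np.ndarray] = field(default_factory=dict)
    table: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None
    selected: tuple[int, int] | None = None
    population: harness.ModelPopulation | None = None
    predicted: xr.DataArray | None = None
    manifest: dict = field(default_factory=dict)


def _predictors(state: RunState) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = feat.predictor_columns(state.table)
    return state.table[cols].values, state.table["anpp_g_m2"].values, cols


def _strat_features(state: RunState) -> np.ndarray:
    cols = ["mean_anpp"] + [c for c in state.table.columns if c.startswith("baseline_")]
    return state.table[cols].values


def stage_simulate(state: RunState) -> None:
    cfg = state.cfg
    spec = worldmod.WorldSpec(seed=derive_seed(cfg["seed"], "world"), **cfg["world"])
    state.world = worldmod.generate_world(spec)
    s = cfg["sites"]
    state.sites = worldmod.sample_sites(
        state.world,
        n_sites=s["n_sites"],
        obs_per_site=s["obs_per_site"],
        obs_noise_sd=s["obs_noise_sd"],
        seed=derive_seed(cfg["seed"], "sites"),
    )
    state.sites.to_csv(state.outdir / "sites.csv", index=False)
    meta = state.world.meta
    write_raster(state.outdir / "mean_anpp.tif", state.world.mean_anpp, meta)
    write_raster(state.outdir / "mask.tif", state.world.mask.astype(float), meta)
    tdir = state.outdir / "truth"
    tdir.mkdir(exist_ok=True)
    for i, y in enumerate(state.world.years):
        write_raster(tdir / format_name(ProductName("historical", int(y))), state.world.anpp.values[i], meta)


def stage_features(state: RunState) -> None:
    w = state.world
    annual = {
        name: feat.aggregate_annual(w.monthly[name], name)
        for name in ("temperature", "precipitation", "radiation", "pet")
    }
    annual["aridity"] = feat.annual_aridity(annual["precipitation"], annual["pet"])
    window = w.spec.baseline_window
    state.annual = annual
    state.normals = {name: compute for name, compute in
                     ((n, feat.compute_normals(c, window)) for n, c in annual.items())}
    state.table = feat.build_feature_table(
        state.sites, state.normals, annual, w.mean_anpp, w.meta
    )
    state.table.to_csv(state.outdir / "features.csv", index=False)


def stage_compare(state: RunState) -> None:
    cfg = state.cfg
    X, y, _ = _predictors(state)
    learners = {
        name: harness.LearnerSpec(name, {"ntree": 200, "mtry": 4} if name == "random_forest" else {})
        for name in cfg["compare"]["learners"]
    }
    state.comparison = harness.compare_models(
        learners,
        cfg["compare"]["strategies"],
        X,
        y,
        coords=(state.table["lon"].values, state.table["lat"].values),
        strat_features=_strat_features(state),
        k=cfg["cv"]["k"],
        repeats=cfg["compare"]["repeats"],
        base_seed=derive_seed(cfg["seed"], "compare"),
    )
    state.comparison.to_csv(state.outdir / "comparison.csv", index=False)
    if len(learners) >= 2 and cfg["compare"]["repeats"] >= 2:
        sub = state.comparison[state.comparison["strategy"] == "env_stratified"]
        if not sub.empty:
            rep = harness.compare_stats(sub, factor="learner", metric="r2")
            rep.tukey.to_csv(state.outdir / "compare_tukey.csv", index=False)
            pd.DataFrame(
                [{"factor": rep.factor, "metric": rep.metric, "anova_f": rep.anova_f, "anova_p": rep.anova_p}]
            ).to_csv(state.outdir / "compare_anova.csv", index=False)


def stage_tune(state: RunState) -> None:
    cfg = state.cfg
    X, y, _ = _predictors(state)
    table, selected = harness.grid_search(
        X,
        y,
        _strat_features(state),
        grid={"ntree": cfg["tune"]["ntree"], "mtry": cfg["tune"]["mtry"]},
        repeats=cfg["tune"]["repeats"],
        k=cfg["cv"]["k"],
        base_seed=derive_seed(cfg["seed"], "tune"),
        n_classes=cfg["cv"]["n_classes"],
    )
    table.to_csv(state.outdir / "tuning.csv", index=False)
    state.selected = selected


def stage_train(state: RunState) -> None:
    cfg = state.cfg
    X, y, names = _predictors(state)
    ntree, mtry = state.selected
    state.population = harness.train_population(
        X,
        y,
        names,
        harness.LearnerSpec("random_forest", {"ntree": ntree, "mtry": mtry}),
        _strat_features(state),
        n_models=cfg["train"]["n_models"],
        k=cfg["cv"]["k"],
        base_seed=derive_seed(cfg["seed"], "train"),
        n_classes=cfg["cv"]["n_classes"],
    )
    state.population.summary().to_csv(state.outdir / "population.csv", index=False)
    best = state.population.best
    joblib.dump(
        {
            "format_version": 1,
            "package_version": __version__,
            "model": best,
            "feature_names": list(best.feature_names),
            "hyperparameters": {"ntree": ntree, "mtry": mtry},
            "seed": best.spec.seed,
        },
        state.outdir / "model.joblib",
    )


def stage_predict(state: RunState) -> None:
    w = state.world
    best = state.population.best
    meta = w.meta
    hdir = state.outdir / "maps" / "historical"
    hdir.mkdir(parents=True, exist_ok=True)
    maps = []
    for i, y in enumerate(w.years):
        annual_vals = {name: cube.values[i] for name, cube in state.annual.items()}
        m = projection.predict_map(best, state.normals, annual_vals, w.mean_anpp, w.mask)
        maps.append(m)
        write_raster(hdir / format_name(ProductName("historical", int(y))), m, meta)
    state.predicted = annual_cube(np.stack(maps), w.years, meta)
    _stage_scenarios(state)


def _coarse_meta(meta: GridMeta, factor: int) -> GridMeta:
    return GridMeta(
        rows=max(meta.rows // factor, 2),
        cols=max(meta.cols // factor, 2),
        cell_size=meta.cell_size * factor,
        lon0=meta.lon0,
        lat0=meta.lat0,
        crs=meta.crs,
    )


def _stage_scenarios(state: RunState) -> None:
    """Scenario era: biased synthetic climate models, QDM correction to the
    observed baseline, bilinear coarsening, per-year prediction, and ensemble
    statistic layers."""
    cfg = state.cfg
    w = state.world
    sc = cfg["scenario"]
    if not sc.get("models"):
        return
    fdir = state.outdir / "maps" / "future"
    fdir.mkdir(parents=True, exist_ok=True)
    meta = w.meta
    cmeta = _coarse_meta(meta, int(sc.get("coarsen", 1)))
    cal = w.spec.baseline_window

    # coarse-grid static layers shared by all members
    mean_c = projection.bilinear_regrid(w.mean_anpp, meta, cmeta)
    mask_c = projection.bilinear_regrid(w.mask.astype(float), meta, cmeta) >= 0.5
    normals_c = {n: projection.bilinear_regrid(v, meta, cmeta) for n, v in state.normals.items()}
    best = state.population.best

    years = np.arange(sc["future_start"], sc["future_end"] + 1)
    per_scenario: dict[str, dict[int, list[np.ndarray]]] = {
        s: {int(y): [] for y in years} for s in sc["scenarios"]
    }
    for scenario in sc["scenarios"]:
        harder = 1.0 if scenario.endswith("585") else 0.4
        for model_id in sc["models"]:
            mseed = derive_seed(cfg["seed"], f"scenario/{model_id}/{scenario}")
            rng = np.random.default_rng(mseed)
            add = {"temperature": float(rng.normal(1.5, 0.5))}
            mul = {"precipitation": float(rng.uniform(0.8, 1.25)),
                   "pet": float(rng.uniform(0.9, 1.1)),
                   "radiation": float(rng.uniform(0.95, 1.05))}
            xtr = {"temperature": 0.02 * harder, "pet": 1.0 * harder,
                   "precipitation": float(rng.normal(0.0, 0.3))}
            sim = worldmod.simulate_climate_model(
                w, model_id, scenario, future_end=sc["future_end"],
                additive_bias=add, multiplicative_bias=mul, extra_trend=xtr, seed=mseed,
            )
            corrected = {
                name: projection.qdm_correct_cube(
                    w.monthly[name], cube, projection.QdmSpec(name, calibration=cal)
                )
                for name, cube in sim.items()
            }
            annual = {
                name: feat.aggregate_annual(corrected[name], name)
                for name in ("temperature", "precipitation", "radiation", "pet")
            }
            annual["aridity"] = feat.annual_aridity(annual["precipitation"], annual["pet"])
            model_years = np.asarray(annual["temperature"]["year"].values)
            for y in years:
                i = int(np.searchsorted(model_years, y))
                vals_c = {
                    name: projection.bilinear_regrid(cube.values[i], meta, cmeta)
                    for name, cube in annual.items()
                }
                m = projection.predict_map(best, normals_c, vals_c, mean_c, mask_c)
                per_scenario[scenario][int(y)].append(m)
                name = format_name(ProductName("future", int(y), model=model_id, scenario=scenario))
                write_raster(fdir / name, m, cmeta)
        for y in years:
            members = per_scenario[scenario][int(y)]
            if len(members) >= 2:
                for stat, layer in projection.ensemble_layers(members).items():
                    name = format_name(ProductName("future", int(y), scenario=scenario, statistic=stat))
                    write_raster(fdir / name, layer, cmeta)


def stage_validate(state: RunState) -> None:
    cfg = state.cfg
    w = state.world
    vdir = state.outdir / "validation"
    vdir.mkdir(exist_ok=True)
    window = w.spec.baseline_window
    in_win = (w.years >= window[0]) & (w.years <= window[1])
    pred_mean = state.predicted.values[in_win].mean(axis=0)
    truth_mean = np.where(w.mask, w.mean_anpp, np.nan)
    pred_mean = np.where(w.mask, pred_mean, np.nan)

    conc = spatial.spatial_concordance(truth_mean, pred_mean)
    pd.DataFrame(
        [{
            "kappa": conc.kappa,
            "taylor_r": conc.taylor.r,
            "taylor_sd_ref": conc.taylor.sd_ref,
            "taylor_sd_test": conc.taylor.sd_test,
            "taylor_crmsd": conc.taylor.crmsd,
            "morans_i_truth": conc.morans_i_ref,
            "morans_i_predicted": conc.morans_i_test,
        }]
    ).to_csv(vdir / "spatial_concordance.csv", index=False)
    _, lisa = spatial.local_morans_lisa(
        pred_mean, n_perm=cfg["validate"]["n_perm"], seed=derive_seed(cfg["seed"], "lisa")
    )
    write_raster(vdir / "lisa_predicted.tif", lisa, w.meta)

    # residual diagnostics on pooled out-of-fold predictions of the best model
    X, y, _ = _predictors(state)
    best = state.population.best
    folds = cvs.env_stratified_cv(
        _strat_features(state), cfg["cv"]["n_classes"], cfg["cv"]["k"], best.spec.seed
    )
    _, oof = harness.cross_validate(best.spec, X, y, folds, return_predictions=True)
    diag = temporal.residual_diagnostics(y, oof, state.table["year"].values)
    diag.bins.to_csv(vdir / "residual_bins.csv", index=False)
    pd.DataFrame(
        [{"slope": diag.slope, "intercept": diag.intercept, "r2": diag.r2, "p": diag.p_value}]
    ).to_csv(vdir / "residual_fit.csv", index=False)

    members = {
        f"ref{i:02d}": worldmod.make_reference_npp(
            w,
            anpp_fraction=0.5,
            extra_noise_sd=cfg["validate"]["reference_noise_sd"],
            seed=derive_seed(cfg["seed"], f"reference/{i}"),
        )
        for i in range(cfg["validate"]["reference_members"])
    }
    summary = temporal.fraction_positive_summary(state.predicted, members)
    summary.to_csv(vdir / "temporal_fraction_positive.csv", index=False)
    tc = temporal.gridwise_correlation(state.predicted, members["ref00"])
    write_raster(vdir / "correlation_ref00.tif", tc.r_map, w.meta)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict | None = None, outdir: str | Path = "run", seed: int | None = None,
                 stages=STAGES) -> Path:
    """Run the pipeline stages in order, writing products and a manifest.

    Any stage failure leaves a FAILED marker naming the stage and re-raises.
    Because every stage reseeds from the run seed, running a prefix of the
    stage list is always consistent with a full run.
    """
    cfg = load_config(overrides=cfg)
    if seed is not None:
        cfg = dict(cfg, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = RunState(cfg=cfg, outdir=outdir)
    funcs = {
        "simulate": stage_simulate,
        "features": stage_features,
        "compare": stage_compare,
        "tune": stage_tune,
        "train": stage_train,
        "predict": stage_predict,
        "validate": stage_validate,
    }
    # stages depend on their predecessors; always execute the prefix ending at
    # the last requested stage
    last = max(STAGES.index(s) for s in stages)
    for name in STAGES[: last + 1]:
        logger.info("stage %s", name)
        try:
            funcs[name](state)
        except Exception as e:
            (outdir / "FAILED").write_text(f"stage {name}: {e}\n")
            raise RuntimeError(f"stage {name} failed: {e}") from e

    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "selected_hyperparameters": (
            {"ntree": state.selected[0], "mtry": state.selected[1]} if state.selected else None
        ),
        "best_model_cv_r2": (
            state.population.best.score.r2 if state.population else None
        ),
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir
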