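"""End-to-end seasonal analysis driven by one YAML configuration.

The full chain: simulate (or load) occurrence records and monthly
environmental rasters → QC and split the records → derive seasonal predictor
stacks (climatologies, slope, distance to the 200 m shelf break, distance to
shore, plankton occurrence) → correlation-screen the predictors → build the
bias-matched background → fit and cross-validate a maxent model per
(target, season) → write mean-probability rasters, MTP habitat maps and
evaluation reports → the multi-guild biodiversity index and strandings
summaries.

All outputs are deterministic functions of (config, seed): reports carry no
timestamps, floats are written with fixed precision, and every random draw
flows from the configured seed, so re-running a config reproduces every
report byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background as bg
from . import env_layers, evaluation, maxent, records, summaries, synthetic_world
from .errors import ConfigurationError
from .grids import GridSpec, RasterLayer, write_ascii_grid

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "simulate", "run_analysis",
           "run_hotspots", "run_strandings", "run_all"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "results/run",
    "seasons": ["spring", "summer", "autumn", "winter"],
    "grid": {"n_rows": 45, "n_cols": 60, "cell_size": 4.0},
    "index_grid": {"cell_factor": 5},  # coarse cell = factor x analysis cell
    "simulate": {
        "enabled": True,
        "max_depth": 400.0,
        "bias_center_frac": [0.3, 0.35],  # fraction of grid extent (x, y up)
        "bias_spread_frac": 0.2,
        "n_plankton": 300,
        "degrade_rate": 0.06,
        "strandings": {"n": 240},
        "targets": [
            {
                "name": "shelf_cetacean",
                "guild": "cetaceans",
                "species": "Phocoena phocoena",
                "coefficients": {"dist_200m": -4.0},
                "n_per_season": {"spring": 150, "summer": 150,
                                 "autumn": 150, "winter": 150},
            },
            {
                "name": "coastal_seabird",
                "guild": "pelagic seabirds",
                "species": "Morus bassanus",
                "coefficients": {"chlorophyll": 2.5, "slope": 1.0},
                "n_per_season": {"spring": 150, "summer": 150,
                                 "autumn": 150, "winter": 150},
            },
            {
                "name": "summer_turtle",
                "guild": "marine turtles",
                "species": "Dermochelys coriacea",
                "coefficients": {"sst": 3.0},
                "n_per_season": {"spring": 1, "summer": 60,
                                 "autumn": 23, "winter": 2},
            },
            {
                "name": "coastal_pinniped",
                "guild": "pinnipeds",
                "species": "Halichoerus grypus",
                "coefficients": {"dist_shore": -3.0},
                "n_per_season": {"spring": 12, "summer": 12,
                                 "autumn": 12, "winter": 12},
            },
            {
                "name": "shelf_shark",
                "guild": "large pelagic fishes",
                "species": "Cetorhinus maximus",
                "coefficients": {"chlorophyll": 2.0, "sst": 1.0},
                "n_per_season": {"spring": 30, "summer": 30,
                                 "autumn": 12, "winter": 4},
            },
        ],
    },
    "background": {"n": 10_000, "levels": [25, 50, 75, 99, 100],
                   "bandwidth": "scott"},
    "maxent": {
        "k_folds": 25,
        "min_presence": 5,
        "reg_multiplier": 1.0,
        "n_knots": 10,
        "max_sweeps": 500,
        "jackknife": True,
        "jackknife_k": 0,
    },
    "correlation_threshold": 0.7,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config (and optional dict overrides) over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if not isinstance(cfg.get("seed"), int):
        raise ConfigurationError("config needs an integer seed")
    g = cfg["grid"]
    if g["n_rows"] < 10 or g["n_cols"] < 10 or g["cell_size"] <= 0:
        raise ConfigurationError("invalid analysis grid")
    for t in cfg["simulate"]["targets"]:
        if not t.get("species"):
            raise ConfigurationError(f"target {t.get('name')} has no species")
    if cfg["maxent"]["k_folds"] < 2:
        raise ConfigurationError("k_folds must be >= 2")


def _config_hash(cfg: dict) -> str:
    # paths are excluded: the hash identifies the scientific run, not where
    # its outputs happen to land
    scientific = {k: v for k, v in cfg.items() if k != "output_dir"}
    blob = json.dumps(scientific, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _minmax_scale(layer: RasterLayer) -> RasterLayer:
    v = layer.values
    lo, hi = np.nanmin(v), np.nanmax(v)
    scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return layer.with_values(scaled)


class Workspace:
    """In-memory products of a run, handed between pipeline stages."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.out = Path(cfg["output_dir"])
        self.monthly: dict[tuple[str, int], RasterLayer] = {}
        self.bathymetry: RasterLayer | None = None
        self.land: RasterLayer | None = None
        self.sightings: pd.DataFrame | None = None
        self.strandings: pd.DataFrame | None = None
        self.stacks: dict[str, env_layers.PredictorStack] = {}
        self.kept_vars: dict[str, list[str]] = {}
        self.backgrounds: dict[str, bg.BackgroundSet] = {}
        self.zones: list[tuple[str, object]] = []


def simulate(cfg: dict, ws: Workspace | None = None) -> Workspace:
    """Generate the synthetic world, sightings, and strandings per config."""
    ws = ws or Workspace(cfg)
    sim = cfg["simulate"]
    g = cfg["grid"]
    wc = synthetic_world.WorldConfig(
        n_rows=g["n_rows"], n_cols=g["n_cols"], cell_size=g["cell_size"],
        max_depth=sim["max_depth"],
    )
    seed = cfg["seed"]
    ws.monthly, ws.bathymetry, ws.land = synthetic_world.make_world(wc, seed)
    spec = ws.bathymetry.spec

    # predictor stacks must exist before the truth surfaces can be built
    _derive_stacks(cfg, ws)

    cx = spec.origin_x + sim["bias_center_frac"][0] * (spec.x_max - spec.origin_x)
    cy = spec.y_min + sim["bias_center_frac"][1] * (spec.origin_y - spec.y_min)
    spread = sim["bias_spread_frac"] * (spec.x_max - spec.origin_x)

    frames = []
    for ti, tgt in enumerate(sim["targets"]):
        truth = synthetic_world.TruthModel(
            coefficients=tgt["coefficients"], bias_center=(cx, cy),
            bias_spread=spread, seed=seed,
        )
        for si, season in enumerate(cfg["seasons"]):
            n = int(tgt["n_per_season"].get(season, 0))
            if n < 1:
                continue
            stack = ws.stacks[season]
            scaled = {v: _minmax_scale(stack.layers[v]) for v in tgt["coefficients"]}
            surface = synthetic_world.make_truth_surface(truth, scaled)
            bias = synthetic_world.make_bias_field(truth, spec)
            df = synthetic_world.sample_sightings(
                surface, bias, n, tgt["guild"], season,
                seed=seed * 1000 + ti * 10 + si,
            )
            df["species"] = tgt["species"]
            frames.append(df)
    raw = pd.concat(frames, ignore_index=True)
    raw = synthetic_world.degrade_records(raw, sim["degrade_rate"], seed + 7)

    bounds = records.StudyBounds(spec.origin_x, spec.x_max, spec.y_min, spec.origin_y)
    kept, rejected = records.qc_filter(raw, bounds)
    ws.sightings, _ = records.split_databases(kept)
    ws.rejected = rejected

    sp = synthetic_world.StrandingParams(**sim.get("strandings", {}))
    ws.strandings = synthetic_world.sample_strandings(sp, ws.land, seed + 13)
    ws.zones = _band_zones(spec, list(sp.zone_weights))
    ws.sightings = records.assign_zone(ws.sightings, ws.zones)
    ws.strandings["season"] = ws.strandings["date"].map(records.assign_season)
    return ws


def _band_zones(spec: GridSpec, labels: list[str]):
    """Vertical-band zone polygons partitioning the study area."""
    from shapely.geometry import box

    width = (spec.x_max - spec.origin_x) / len(labels)
    zones = []
    for i, label in enumerate(labels):
        zones.append(
            (label, box(spec.origin_x + i * width, spec.y_min,
                        spec.origin_x + (i + 1) * width, spec.origin_y))
        )
    return zones


def _derive_stacks(cfg: dict, ws: Workspace) -> None:
    """Seasonal climatologies plus static terrain and plankton predictors."""
    sea = ws.land.values == 0
    slope = env_layers.slope_degrees(ws.bathymetry)
    dist200 = env_layers.distance_to_level(ws.bathymetry, 200.0)
    dshore = env_layers.distance_to_shore(ws.land)
    variables = sorted({v for v, _ in ws.monthly})
    rng = np.random.default_rng(cfg["seed"] + 99)
    for season in cfg["seasons"]:
        months = records.SEASON_MONTHS[season]
        stack = env_layers.PredictorStack(season=season)
        for var in variables:
            monthly = [ws.monthly[(var, m)] for m in months if (var, m) in ws.monthly]
            stack.add(env_layers.seasonal_mean(monthly, season))
        for static in (slope, dist200, dshore):
            lay = static.with_values(np.where(sea, static.values, np.nan))
            lay.name = static.name
            lay.season = season
            stack.add(lay)
        n_pl = cfg["simulate"].get("n_plankton", 0)
        if n_pl:
            chl = stack.layers.get("chlorophyll")
            if chl is not None:
                pts = _plankton_points(chl, n_pl, rng)
                surf = env_layers.occurrence_surface(
                    pts, chl.spec, bandwidth=3 * chl.spec.cell_size,
                    sea=sea, name="copepod",
                )
                surf.season = season
                stack.add(surf)
        ws.stacks[season] = stack


def _plankton_points(chl: RasterLayer, n: int, rng) -> np.ndarray:
    """Presence-only plankton records drawn from a chlorophyll-tied intensity."""
    spec = chl.spec
    v = np.where(chl.mask, chl.values, np.nan)
    z = (v - np.nanmin(v)) / max(np.nanmax(v) - np.nanmin(v), 1e-12)
    p = np.where(np.isnan(z), 0.0, np.exp(2.0 * z)).ravel()
    p /= p.sum()
    cells = rng.choice(p.size, size=n, p=p)
    r, c = np.unravel_index(cells, spec.shape)
    xs = spec.origin_x + (c + 0.5) * spec.cell_size
    ys = spec.origin_y - (r + 0.5) * spec.cell_size
    return np.column_stack([xs, ys])


def _screen(cfg: dict, ws: Workspace, season: str) -> env_layers.PredictorStack:
    """Correlation-screen one season's stack against the background table."""
    stack = ws.stacks[season]
    table = stack.table()
    kept, dropped, corr = env_layers.correlation_screen(
        table, cfg["correlation_threshold"]
    )
    ws.kept_vars[season] = kept
    out = ws.out / "layers"
    out.mkdir(parents=True, exist_ok=True)
    corr.round(6).to_csv(out / f"correlation_{season}.csv")
    if dropped:
        logger.info("%s: correlation screen dropped %s", season, dropped)
    return stack.subset(kept)


def _season_background(cfg: dict, ws: Workspace, season: str,
                       stack: env_layers.PredictorStack) -> bg.BackgroundSet:
    sights = ws.sightings[ws.sightings["season"] == season]
    pts = sights[["x", "y"]].to_numpy(dtype=float)
    sea = stack.sea_mask()
    density = bg.kde_density(pts, stack.spec, cfg["background"]["bandwidth"], sea=sea)
    contours = bg.volume_contour_masks(
        density, tuple(cfg["background"]["levels"])
    )
    return bg.sample_background(
        contours, cfg["background"]["n"], seed=cfg["seed"] + 17, env=stack
    )


def run_analysis(cfg: dict, ws: Workspace | None = None) -> dict:
    """Fit, evaluate, and map every (target, season); return the manifest."""
    if ws is None:
        ws = simulate(cfg) if cfg["simulate"]["enabled"] else Workspace(cfg)
    out = ws.out
    (out / "models").mkdir(parents=True, exist_ok=True)
    mx = cfg["maxent"]
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "models": [],
    }
    for season in cfg["seasons"]:
        stack = _screen(cfg, ws, season)
        bset = _season_background(cfg, ws, season, stack)
        ws.backgrounds[season] = bset
        bframe = bset.as_frame()
        bframe.to_csv(out / "models" / f"background_{season}.csv", index=False,
                      float_format="%.10g")
        bg_features = bset.features
        for tgt in cfg["simulate"]["targets"]:
            name = tgt["name"]
            entry = {"target": name, "season": season}
            pres = ws.sightings[
                (ws.sightings["species"] == tgt["species"])
                & (ws.sightings["season"] == season)
            ]
            if len(pres) < mx["min_presence"]:
                entry.update(status="skipped", reason="insufficient sample",
                             n_presence=int(len(pres)))
                manifest["models"].append(entry)
                logger.info("%s/%s skipped: %d presences", name, season, len(pres))
                continue
            rows, cols = zip(*(
                stack.spec.cell_of(x, y) for x, y in zip(pres["x"], pres["y"])
            ))
            ptable = stack.values_at(np.array(rows), np.array(cols))
            ok = ptable.notna().all(axis=1).to_numpy()
            ptable = ptable[ok].reset_index(drop=True)
            k = min(mx["k_folds"], len(ptable))
            cv = maxent.cross_validate(
                ptable, bg_features, stack, k, cfg["seed"] + 23,
                n_knots=mx["n_knots"], reg_multiplier=mx["reg_multiplier"],
                max_sweeps=mx["max_sweeps"],
            )
            # full-data fit supplies the gain trace for percent contribution
            f_bg = cv.builder.transform(bg_features)
            f_pres = cv.builder.transform(ptable)
            full = maxent.fit(
                f_pres, f_bg, builder=cv.builder,
                reg_multiplier=mx["reg_multiplier"], max_sweeps=mx["max_sweeps"],
            )
            jk = None
            if mx["jackknife"]:
                jk = evaluation.jackknife_importance(
                    ptable, bg_features, stack.names, k=mx["jackknife_k"],
                    seed=cfg["seed"] + 29,
                    classes=maxent.default_feature_classes(len(ptable)),
                    reg_multiplier=mx["reg_multiplier"],
                    max_sweeps=mx["max_sweeps"],
                )
            report = evaluation.evaluate_cv(cv, full, jackknife=jk)
            base = out / "models" / f"{name}_{season}"
            report.to_json(f"{base}_report.json")
            full.to_json(f"{base}_model.json")
            write_ascii_grid(cv.mean_raster, f"{base}_probability.asc")
            habitat = evaluation.binarize(cv.mean_raster, report.mtp)
            write_ascii_grid(habitat, f"{base}_habitat.asc")
            pd.DataFrame(
                {
                    "fold": range(len(cv.folds)),
                    "train_auc": [f.train_auc for f in cv.folds],
                    "test_auc": [f.test_auc for f in cv.folds],
                    "train_gain": [f.train_gain for f in cv.folds],
                    "mtp": [f.mtp for f in cv.folds],
                }
            ).to_csv(f"{base}_folds.csv", index=False, float_format="%.10g")
            entry.update(
                status="ok",
                n_presence=int(len(ptable)),
                k_folds=k,
                mean_auc=round(report.mean_auc, 10),
                mtp_threshold=round(report.mtp, 10),
                discrimination_class=report.discrimination,
                top_contribution=max(
                    report.percent_contribution,
                    key=report.percent_contribution.get,
                ),
                outputs={
                    "report": f"{base.name}_report.json",
                    "probability": f"{base.name}_probability.asc",
                    "habitat": f"{base.name}_habitat.asc",
                },
            )
            manifest["models"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_hotspots(cfg: dict, ws: Workspace) -> dict:
    """Guild presence rasters, the 0-5 biodiversity index, per-zone means."""
    if ws.sightings is None:
        raise ConfigurationError("no sightings database in workspace")
    spec = ws.land.spec
    factor = cfg["index_grid"]["cell_factor"]
    coarse = GridSpec(
        n_rows=max(spec.n_rows // factor, 3),
        n_cols=max(spec.n_cols // factor, 3),
        cell_size=spec.cell_size * factor,
        origin_x=spec.origin_x,
        origin_y=spec.origin_y,
    )
    out = ws.out / "hotspots"
    out.mkdir(parents=True, exist_ok=True)
    guild_rasters = {}
    for guild in records.GUILDS:
        r = summaries.guild_presence_raster(ws.sightings, guild, coarse)
        if r.values.sum() == 0:
            logger.warning("guild %r absent from the sightings database", guild)
        guild_rasters[guild] = r
        write_ascii_grid(r, out / f"guild_{guild.replace(' ', '_')}.asc")
    index = summaries.biodiversity_index(guild_rasters)
    write_ascii_grid(index, out / "biodiversity_index.asc")

    rows = []
    if ws.zones:
        xs, ys = coarse.cell_centers()
        from shapely.geometry import Point

        for label, poly in ws.zones:
            sel = np.array(
                [poly.covers(Point(x, y)) for x, y in zip(xs.ravel(), ys.ravel())]
            ).reshape(coarse.shape)
            if sel.any():
                rows.append({"zone": label,
                             "mean_index": float(index.values[sel].mean()),
                             "n_cells": int(sel.sum())})
    table = pd.DataFrame(rows)
    table.to_csv(out / "zone_mean_index.csv", index=False, float_format="%.10g")
    return {"index": index, "guilds": guild_rasters, "zone_table": table}


def run_strandings(cfg: dict, ws: Workspace) -> summaries.StrandingSummary:
    """Write the strandings composition and trend tables."""
    if ws.strandings is None:
        raise ConfigurationError("no strandings database in workspace")
    summ = summaries.strandings_summary(ws.strandings)
    out = ws.out / "strandings"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"category": k, "count": v, "proportion": round(v / summ.n_total, 10)}
         for k, v in sorted(summ.cause_counts.items())]
    ).to_csv(out / "cause_composition.csv", index=False)
    summ.yearly.to_csv(out / "yearly_trend.csv", float_format="%.10g")
    summ.family_season_zone.to_csv(out / "family_season_zone.csv", index=False)
    return summ


def run_all(cfg: dict) -> dict:
    """Simulate, analyse, index, summarize — the whole pipeline."""
    ws = simulate(cfg)
    ws.out.mkdir(parents=True, exist_ok=True)
    records.write_records_csv(ws.sightings, ws.out / "sightings.csv")
    records.write_records_csv(ws.strandings, ws.out / "strandings.csv")
    manifest = run_analysis(cfg, ws)
    run_hotspots(cfg, ws)
    run_strandings(cfg, ws)
    return manifest
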