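"""End-to-end pipeline: simulate -> extract -> fit -> map -> evaluate -> connect.

The run is a pure function of (inputs, configuration, seeds): every stage
derives its RNG stream from the master seed, logs its parameters and writes
plain-text artifacts (ASCII rasters, CSVs, JSON) to the output directory,
so re-running a configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuits, evaluate, io, niche, synthetic
from .layers import EnvStack, VariableTable, extract_table

logger = logging.getLogger("ecominima")


def setup_logging(level: int = logging.INFO, logfile=None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and cause."""


@dataclass
class RunConfig:
    """Full configuration for a pipeline run.

    Defaults describe the demo study conditions: a 64x64 synthetic
    landscape with 10 environmental variables, 2 planted minimum
    directions, 4 populations totalling 500 leks, 99 historic locations
    and 500 background points.
    """

    out_dir: str = "ecominima_run"
    seed: int = 0
    # synthetic landscape
    simulate: bool = True
    n_rows: int = 64
    n_cols: int = 64
    cell_km: float = 1.0
    p: int = 10
    m: int = 2
    corr_length: float = 3.0
    sigma_min: float = 0.1
    sigma_free: float = 1.0
    presence_quantile: float = 0.25
    n_pops: int = 4
    n_leks: int = 500
    n_historic: int = 99
    # optional external inputs (used when simulate is False)
    stack_dir: str | None = None
    occurrences_csv: str | None = None
    historic_csv: str | None = None
    # model
    n_boot: int = 1000
    pop_cap: int = 25
    k: int | None = None            # None -> smallest k with eigenvalue <= 1
    d2_mode: str = "tail-sum"
    # evaluation
    calibration_fraction: float = 0.70
    n_background: int = 500
    n_bins: int = 20
    coverage: float = 0.90
    # connectivity
    run_connectivity: bool = True
    neighborhood: int = 8
    r_max: float = 100_000.0
    hsi_floor: float = 1e-5
    resistance_rule: str = "reciprocal"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _point_spec(stack: EnvStack) -> dict[str, tuple[str, str, float]]:
    """Point-sampling extraction spec covering every stack layer."""
    return {name: (name, "point", 0.0) for name in stack.names}


@dataclass
class RunResult:
    """In-memory handles to everything the pipeline computed."""

    config: RunConfig
    stack: EnvStack
    model: niche.PartitionModel
    hsi_grid: np.ndarray
    occurrences: pd.DataFrame
    calibration: pd.DataFrame
    evaluation: pd.DataFrame
    historic: pd.DataFrame
    background: pd.DataFrame
    diagnostics: niche.PartitionDiagnostics
    scores: dict[str, np.ndarray]
    threshold: float
    importance: pd.DataFrame
    summary: pd.DataFrame
    current: circuits.CurrentMap | None


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full analysis; see module docstring for the stage order."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "run_config.yaml")
    rng_seed = int(config.seed)

    # --- simulate or load -------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            lc = synthetic.LandscapeConfig(
                n_rows=config.n_rows, n_cols=config.n_cols, cell_km=config.cell_km,
                p=config.p, corr_length=config.corr_length, seed=rng_seed)
            pniche = synthetic.random_niche(
                config.p, config.m, seed=rng_seed + 1, sigma_min=config.sigma_min,
                sigma_free=config.sigma_free,
                presence_quantile=config.presence_quantile)
            layout = synthetic.default_layout(lc, n_pops=config.n_pops,
                                              leks_per_pop=config.n_leks,
                                              seed=rng_seed + 2)
            stack = synthetic.gen_env_stack(lc, pniche, layout)
            occ = synthetic.gen_occurrences(stack, pniche, layout, seed=rng_seed + 3)
            historic = synthetic.gen_historic(stack, pniche, config.n_historic,
                                              seed=rng_seed + 4)
        else:
            if not (config.stack_dir and config.occurrences_csv):
                raise PipelineError("simulate=false requires stack_dir and "
                                    "occurrences_csv")
            stack = io.read_stack(config.stack_dir)
            occ = io.read_occurrences(config.occurrences_csv)
            historic = (io.read_occurrences(config.historic_csv)
                        if config.historic_csv else occ.iloc[0:0])
        stage = "extract"
        spec = _point_spec(stack)
        cal_occ, evl_occ = evaluate.split(
            occ, calibration_fraction=config.calibration_fraction,
            seed=rng_seed + 5)
        background = evaluate.sample_background(stack.nodata_mask,
                                                config.n_background,
                                                seed=rng_seed + 6,
                                                cell_km=stack.cell_km)
        tab_cal = extract_table(stack, cal_occ, spec)
        tab_evl = extract_table(stack, evl_occ, spec)
        tab_his = extract_table(stack, historic, spec) if len(historic) else None
        tab_bg = extract_table(stack, background, spec)

        stage = "fit"
        pops = cal_occ.loc[tab_cal.data.index, "population"].to_numpy()
        model = niche.bootstrap_fit(tab_cal, pops, n_boot=config.n_boot,
                                    pop_cap=config.pop_cap, seed=rng_seed + 7)
        model.mode = config.d2_mode
        k = config.k if config.k is not None else niche.select_k(model)
        model.k_selected = int(k)
        logger.info("fit: selected boundary partition k=%d (df=%d)", k, model.df)

        stage = "diagnostics"
        diag = niche.diagnostics(
            model, tab_cal.values, tab_evl.values,
            tab_his.values if tab_his is not None and len(tab_his.data) else
            tab_bg.values, tab_bg.values)

        stage = "map"
        hsi_grid = niche.map_hsi(stack, spec, model)

        stage = "evaluate"
        scores = {
            "calibration": niche.score_hsi(tab_cal.values, model),
            "evaluation": niche.score_hsi(tab_evl.values, model),
            "background": niche.score_hsi(tab_bg.values, model),
        }
        if tab_his is not None and len(tab_his.data):
            scores["historic"] = niche.score_hsi(tab_his.values, model)
        lek_scores = np.concatenate([scores["calibration"], scores["evaluation"]])
        threshold = evaluate.hsi_threshold(lek_scores, coverage=config.coverage)
        importance = evaluate.variable_importance(
            model, scores["calibration"], tab_cal.values)
        groups = {"active": pd.concat([tab_cal.data, tab_evl.data]),
                  "study_area": tab_bg.data}
        if tab_his is not None and len(tab_his.data):
            groups["historic"] = tab_his.data
        summary = evaluate.group_summary(groups)
        curves = {}
        for var in model.var_names:
            grids = {var: stack.layer(var).copy()}
            g = grids[var]
            g[stack.nodata_mask] = np.nan
            lek_vals = pd.concat([tab_cal.data, tab_evl.data])[var].to_numpy()
            try:
                curves[var] = evaluate.dose_response(
                    g, hsi_grid, lek_vals, n_bins=config.n_bins, variable=var)
            except evaluate.EvalError:
                logger.warning("dose_response skipped for %s (degenerate)", var)

        stage = "connectivity"
        current = None
        if config.run_connectivity:
            resistance = circuits.resistance_from_hsi(
                hsi_grid, range_mask=None, r_max=config.r_max,
                hsi_floor=config.hsi_floor, rule=config.resistance_rule)
            graph = circuits.build_graph(resistance,
                                         neighborhood=config.neighborhood)
            lek_cells = occ[["row", "col"]].to_numpy()
            amplitudes = occ["count"].to_numpy(dtype=float)
            current = circuits.solve_all_to_one(graph, lek_cells, amplitudes)

        stage = "write"
        if write:
            io.write_stack(stack, out / "stack")
            io.write_occurrences(occ, out / "occurrences.csv")
            io.write_occurrences(historic, out / "historic.csv")
            io.write_occurrences(background, out / "background.csv")
            model.to_json(out / "model.json")
            diag.to_csv(out / "diagnostics.csv")
            io.write_raster(hsi_grid, out / "hsi.asc", cell_km=stack.cell_km)
            importance.to_csv(out / "importance.csv", index=False)
            summary.to_csv(out / "group_summary.csv", index=False)
            pd.DataFrame({
                "set": list(scores),
                "median_hsi": [float(np.median(s)) for s in scores.values()],
            }).to_csv(out / "median_hsi.csv", index=False)
            with open(out / "threshold.json", "w") as fh:
                json.dump({"coverage": config.coverage,
                           "hsi_threshold": threshold}, fh, indent=1)
            for var, curve in curves.items():
                curve.to_frame().to_csv(out / f"dose_response_{var}.csv",
                                        index=False)
            if current is not None:
                io.write_raster(resistance, out / "resistance.asc",
                                cell_km=stack.cell_km)
                io.write_raster(current.cumulative, out / "current.asc",
                                cell_km=stack.cell_km)
                current.per_source.to_csv(out / "current_sources.csv",
                                          index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return RunResult(config=config, stack=stack, model=model, hsi_grid=hsi_grid,
                     occurrences=occ, calibration=cal_occ, evaluation=evl_occ,
                     historic=historic, background=background, diagnostics=diag,
                     scores=scores, threshold=threshold, importance=importance,
                     summary=summary, current=current)
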