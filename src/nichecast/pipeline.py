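"""Orchestration of the three modelling experiments from one configuration.

The pipeline mirrors a complete uncertainty study for an invasive pest:

* ``run_prevalence_experiment`` — one GAM per assumed prevalence level
  (default 10–90%), projected to current and scenario climates, with
  median consensus, between-prevalence variance, and range-change maps.
* ``run_family_experiment`` — all eight model families at 50% prevalence,
  repeated-split evaluation, retention at AUC >= 0.9, and consensus /
  variance over the retained members (variance over all members is also
  written for contrast).
* ``run_clade_analysis`` — per-clade GAMs (reusing the species-level
  variable selection), per-clade range-change maps, and the OMI
  niche-overlap analysis between the two clades.

Inputs are either simulated virtual-species fixtures (the default; see
:mod:`nichecast.synthetic_data`) or raster stacks + occurrence CSVs named
in the config. Every randomized stage derives its own seed from the run
seed, so a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

import contextlib
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ensemble_uncertainty import MapStack, binarize, consensus, range_change, variance_map
from .evaluation import EvalReport, cv_evaluate, mst_threshold, retain_models
from .geo_io import (
    EnvGrid, PresenceSet, grid_occurrences, load_env_stack, read_occurrences,
    sample_background, write_ascii_grid, write_occurrences, OccurrencePoints,
)
from .niche_omi import OMIResult, run_omi
from .sdm_engines import FAMILY_FITTERS, predict_map
from .synthetic_data import (
    VirtualSpeciesConfig, make_env_layers, make_future_layers, make_two_clades,
)
from .weighting_selection import build_training_table, forward_select

logger = logging.getLogger("nichecast")

__all__ = [
    "RunConfig", "run_simulate", "run_select", "run_prevalence_experiment",
    "run_family_experiment", "run_clade_analysis", "run_all",
]

ALL_FAMILIES = tuple(FAMILY_FITTERS)


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run (YAML-serializable)."""

    outdir: str = "runs/fixture"
    seed: int = 0

    # synthetic environment (used unless env_current is given)
    n_rows: int = 100
    n_cols: int = 100
    n_env_vars: int = 4
    decoy_r: float = 0.9
    smooth_sigma: float = 6.0
    sea_fraction: float = 0.05

    # virtual species
    species: dict = field(default_factory=dict)  # VirtualSpeciesConfig overrides

    # real-data inputs (optional; override simulation)
    env_current: list[str] = field(default_factory=list)
    env_scenarios: dict[str, list[str]] = field(default_factory=dict)
    env_variables: list[str] = field(default_factory=list)
    occurrences: str = ""

    # modelling design
    prevalence_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    families: tuple[str, ...] = ALL_FAMILIES
    n_background: int = 5000
    r_max: float = 0.8
    alpha: float = 0.05
    auc_min: float = 0.9
    n_repeats: int = 10
    train_frac: float = 0.8
    n_boot: int = 1000
    scenarios: tuple[str, ...] = ("mild", "strong")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("prevalence_grid", "families", "scenarios"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("prevalence_grid", "families", "scenarios"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def species_config(self) -> VirtualSpeciesConfig:
        return VirtualSpeciesConfig(
            **{"decoy_r": self.decoy_r, "seed": self.seed, **self.species}
        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------

@dataclass
class PipelineContext:
    """Loaded/simulated inputs shared by the experiment stages."""

    grid: EnvGrid
    scenario_grids: dict[str, EnvGrid]
    species: PresenceSet
    clade1: PresenceSet
    clade2: PresenceSet
    background: frozenset
    candidates: list[str]


def prepare_context(cfg: RunConfig) -> PipelineContext:
    if cfg.env_current:
        grid = load_env_stack(cfg.env_current, cfg.env_variables or None)
        scenario_grids = {
            name: load_env_stack(paths, cfg.env_variables or None)
            for name, paths in cfg.env_scenarios.items()
        }
        points = read_occurrences(cfg.occurrences)
        clade1 = grid_occurrences(points, grid, clade_filter=1)
        clade2 = grid_occurrences(points, grid, clade_filter=2)
        species = grid_occurrences(points, grid)
    else:
        sp_cfg = cfg.species_config()
        grid = make_env_layers(
            cfg.n_rows, cfg.n_cols, cfg.n_env_vars, cfg.decoy_r, seed=cfg.seed,
            smooth_sigma=cfg.smooth_sigma, sea_fraction=cfg.sea_fraction,
        )
        scenario_grids = {s: make_future_layers(grid, s) for s in cfg.scenarios}
        clade1, clade2 = make_two_clades(grid, sp_cfg)
        species = PresenceSet(clade1.cells | clade2.cells, taxon="species")
    background = sample_background(grid, cfg.n_background, seed=cfg.seed + 1)
    return PipelineContext(
        grid=grid, scenario_grids=scenario_grids, species=species,
        clade1=clade1, clade2=clade2, background=background,
        candidates=list(grid.variable_names),
    )


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def _stage(fn):
    """Run a pipeline stage under the no-partial-outputs guarantee."""
    import functools

    @functools.wraps(fn)
    def wrapper(cfg: RunConfig, ctx: "PipelineContext | None" = None):
        with _cleanup_on_failure(Path(cfg.outdir)):
            return fn(cfg, ctx)

    return wrapper


@contextlib.contextmanager
def _cleanup_on_failure(outdir: Path):
    """Remove files a failing stage leaves behind (no partial outputs)."""
    outdir.mkdir(parents=True, exist_ok=True)
    before = set(outdir.rglob("*"))
    try:
        yield
    except Exception:
        for p in sorted(set(outdir.rglob("*")) - before, reverse=True):
            with contextlib.suppress(OSError):
                p.unlink() if p.is_file() else p.rmdir()
        raise


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, cfg: RunConfig, stage: str,
                    files: Sequence[Path], extra: Mapping | None = None) -> Path:
    manifest = {
        "stage": stage,
        "config_hash": cfg.digest(),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(files)},
    }
    if extra:
        manifest.update(extra)
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def _write_map(outdir: Path, name: str, array: np.ndarray, grid: EnvGrid) -> Path:
    path = outdir / f"{name}.asc"
    write_ascii_grid(path, array, origin=grid.origin, cell_size_deg=grid.cell_size_deg)
    return path


def _consensus_threshold(consensus_map: np.ndarray, presences: PresenceSet,
                         background, grid: EnvGrid) -> float:
    """MST threshold of a consensus map against the training presences plus
    a background sample (the binarization rule for range-change maps)."""
    cells = presences.sorted_cells() + sorted(background)
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    scores = consensus_map[rows, cols]
    labels = np.array([1] * len(presences) + [0] * len(background))
    ok = np.isfinite(scores)
    t, _, _ = mst_threshold(scores[ok], labels[ok])
    return t


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@_stage
def run_simulate(cfg: RunConfig, ctx: PipelineContext | None = None) -> dict:
    """Write the simulated fixture (rasters + occurrence CSV) to disk."""
    ctx = ctx or prepare_context(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for name, grid in [("current", ctx.grid)] + list(ctx.scenario_grids.items()):
        env_dir = outdir / "env" / name
        env_dir.mkdir(parents=True, exist_ok=True)
        for var in grid.variable_names:
            p = env_dir / f"{var}.asc"
            write_ascii_grid(p, grid.layers[var], origin=grid.origin,
                             cell_size_deg=grid.cell_size_deg)
            files.append(p)
    rows = []
    for pset, label in [(ctx.clade1, 1), (ctx.clade2, 2)]:
        for cell in pset.sorted_cells():
            lon, lat = ctx.grid.cell_centroid(cell)
            rows.append({"lon": lon, "lat": lat, "clade": label})
    occ_path = outdir / "occurrences.csv"
    write_occurrences(OccurrencePoints(pd.DataFrame(rows)), occ_path)
    files.append(occ_path)
    manifest = _write_manifest(outdir, cfg, "simulate", files)
    return {"files": files, "manifest": manifest}


def run_select(cfg: RunConfig, ctx: PipelineContext | None = None):
    """Species-level forward variable selection (run once, reused for clades)."""
    ctx = ctx or prepare_context(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = build_training_table(ctx.grid, ctx.species, ctx.background, phi=0.5)
    result = forward_select(table, ctx.candidates, r_max=cfg.r_max, alpha=cfg.alpha)
    trace_path = outdir / "selection_trace.csv"
    result.to_csv(trace_path)
    sel_path = outdir / "selected_variables.json"
    sel_path.write_text(json.dumps({"selected": result.selected}, indent=2))
    _write_manifest(outdir, cfg, "select", [trace_path, sel_path],
                    {"selected": result.selected})
    logger.info("selected variables: %s", result.selected)
    return result


def _selected_variables(cfg: RunConfig, ctx: PipelineContext) -> list[str]:
    sel_path = Path(cfg.outdir) / "selected_variables.json"
    if sel_path.exists():
        return json.loads(sel_path.read_text())["selected"]
    return run_select(cfg, ctx).selected


def _project_and_summarize(
    cfg: RunConfig, ctx: PipelineContext, members: dict[str, dict[str, np.ndarray]],
    stage: str, outdir: Path,
) -> tuple[list[Path], dict]:
    """Consensus / variance / range-change maps for a member dict of
    ``{member_id: {"current": map, scenario: map, ...}}``."""
    files = []
    meta: dict = {"members": sorted(members)}
    for member, maps in members.items():
        for name, arr in maps.items():
            files.append(_write_map(outdir, f"map_{stage}_{member}_{name}", arr, ctx.grid))

    regions = ["current"] + list(cfg.scenarios)
    stacks = {
        region: MapStack.from_dict(
            {m: members[m][region] for m in sorted(members)}, ctx.grid.mask
        )
        for region in regions
    }
    cons = {region: consensus(stacks[region], "median") for region in regions}
    for region in regions:
        files.append(_write_map(outdir, f"consensus_{stage}_{region}", cons[region], ctx.grid))
        files.append(_write_map(outdir, f"variance_{stage}_{region}",
                                variance_map(stacks[region]), ctx.grid))

    threshold = _consensus_threshold(cons["current"], ctx.species, ctx.background, ctx.grid)
    meta["binarization_threshold"] = threshold
    cur_bin = binarize(cons["current"], threshold)
    counts_rows = []
    for scen in cfg.scenarios:
        rc = range_change(cur_bin, binarize(cons[scen], threshold))
        out = np.where(rc.classes < 0, np.nan, rc.classes).astype(float)
        files.append(_write_map(outdir, f"rangechange_{stage}_{scen}", out, ctx.grid))
        counts_rows.append({"scenario": scen, **rc.counts()})
    counts_path = outdir / f"rangechange_counts_{stage}.csv"
    pd.DataFrame(counts_rows).to_csv(counts_path, index=False)
    files.append(counts_path)
    return files, meta


@_stage
def run_prevalence_experiment(cfg: RunConfig, ctx: PipelineContext | None = None) -> dict:
    """GAMs across the prevalence grid; consensus, variance, range change."""
    ctx = ctx or prepare_context(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = _selected_variables(cfg, ctx)
    fit = FAMILY_FITTERS["GAM"]

    members, reports = {}, {}
    for i, phi in enumerate(cfg.prevalence_grid):
        member = f"phi{int(round(phi * 100))}"
        table = build_training_table(ctx.grid, ctx.species, ctx.background,
                                     phi=phi, variables=selected)
        model = fit(table)
        members[member] = {"current": predict_map(model, ctx.grid)}
        for scen, sgrid in ctx.scenario_grids.items():
            members[member][scen] = predict_map(model, sgrid)
        reports[member] = cv_evaluate(
            fit, ctx.species, ctx.grid, phi=phi, n_repeats=cfg.n_repeats,
            train_frac=cfg.train_frac, seed=cfg.seed + 10 + i, family="GAM",
            variables=selected,
        )

    files, meta = _project_and_summarize(cfg, ctx, members, "prevalence", outdir)
    eval_path = outdir / "evaluation_prevalence.csv"
    pd.DataFrame([r.summary() for r in reports.values()]).to_csv(eval_path, index=False)
    files.append(eval_path)
    manifest = _write_manifest(outdir, cfg, "prevalence", files, meta)
    return {"members": members, "reports": reports, "manifest": manifest, "meta": meta}


@_stage
def run_family_experiment(cfg: RunConfig, ctx: PipelineContext | None = None) -> dict:
    """All families at 50% prevalence; retention, consensus, variance."""
    ctx = ctx or prepare_context(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = _selected_variables(cfg, ctx)

    table = build_training_table(ctx.grid, ctx.species, ctx.background,
                                 phi=0.5, variables=selected)
    members, reports = {}, {}
    for i, family in enumerate(cfg.families):
        fit = FAMILY_FITTERS[family]
        model = fit(table)
        members[family] = {"current": predict_map(model, ctx.grid)}
        for scen, sgrid in ctx.scenario_grids.items():
            members[family][scen] = predict_map(model, sgrid)
        reports[family] = cv_evaluate(
            fit, ctx.species, ctx.grid, phi=0.5, n_repeats=cfg.n_repeats,
            train_frac=cfg.train_frac, seed=cfg.seed + 100 + i, family=family,
            variables=selected,
        )

    retained = retain_models(reports, auc_min=cfg.auc_min)
    if not retained:
        best = max(reports, key=lambda f: reports[f].mean_auc) if reports else None
        retained = [best] if best else []
    meta_extra = {"retained": retained, "auc_min": cfg.auc_min}

    files = []
    if len(retained) >= 2:
        retained_members = {f: members[f] for f in retained}
        files, meta = _project_and_summarize(cfg, ctx, retained_members,
                                             "families", outdir)
        meta.update(meta_extra)
    else:
        meta = meta_extra
        logger.warning("fewer than 2 retained families; no consensus computed")
    # all-members variance for contrast with the retained-only maps
    if len(members) >= 2:
        stack_all = MapStack.from_dict(
            {m: members[m]["current"] for m in sorted(members)}, ctx.grid.mask
        )
        files.append(_write_map(outdir, "variance_families_all_current",
                                variance_map(stack_all), ctx.grid))

    eval_path = outdir / "evaluation_families.csv"
    pd.DataFrame([r.summary() for r in reports.values()]).to_csv(eval_path, index=False)
    files.append(eval_path)
    table2_path = outdir / "table_families.csv"
    pd.DataFrame([r.summary_row() for r in reports.values()]).to_csv(table2_path, index=False)
    files.append(table2_path)
    manifest = _write_manifest(outdir, cfg, "families", files, meta)
    return {"members": members, "reports": reports, "retained": retained,
            "manifest": manifest, "meta": meta}


@_stage
def run_clade_analysis(cfg: RunConfig, ctx: PipelineContext | None = None) -> dict:
    """Per-clade GAM projections plus the OMI niche-overlap analysis."""
    ctx = ctx or prepare_context(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = _selected_variables(cfg, ctx)
    fit = FAMILY_FITTERS["GAM"]

    files: list[Path] = []
    areas = {}
    counts_rows = []
    for pset in (ctx.clade1, ctx.clade2):
        table = build_training_table(ctx.grid, pset, ctx.background,
                                     phi=0.5, variables=selected)
        model = fit(table)
        cur = predict_map(model, ctx.grid)
        threshold = _consensus_threshold(cur, pset, ctx.background, ctx.grid)
        cur_bin = binarize(cur, threshold)
        areas[pset.taxon] = int(np.nansum(cur_bin))
        files.append(_write_map(outdir, f"map_clade_{pset.taxon}_current", cur, ctx.grid))
        for scen, sgrid in ctx.scenario_grids.items():
            fut = predict_map(model, sgrid)
            rc = range_change(cur_bin, binarize(fut, threshold))
            out = np.where(rc.classes < 0, np.nan, rc.classes).astype(float)
            files.append(_write_map(outdir, f"rangechange_{pset.taxon}_{scen}", out, ctx.grid))
            counts_rows.append({"taxon": pset.taxon, "scenario": scen, **rc.counts()})
    counts_path = outdir / "rangechange_counts_clades.csv"
    pd.DataFrame(counts_rows).to_csv(counts_path, index=False)
    files.append(counts_path)

    omi = run_omi(
        ctx.grid, [ctx.clade1, ctx.clade2], reference_cells=ctx.background,
        variables=selected or None, n_boot=cfg.n_boot, seed=cfg.seed + 200,
    )
    files.extend(omi.to_csvs(outdir))
    manifest = _write_manifest(
        outdir, cfg, "clades", files,
        {"range_area_cells": areas,
         "axis1_pct_variance": float(omi.pct_variance[0]) if len(omi.pct_variance) else None},
    )
    return {"omi": omi, "areas": areas, "manifest": manifest}


def run_all(cfg: RunConfig) -> dict:
    """Simulate (fixture mode), select, then all three experiments."""
    ctx = prepare_context(cfg)
    out = {}
    if not cfg.env_current:
        out["simulate"] = run_simulate(cfg, ctx)
    out["select"] = run_select(cfg, ctx)
    out["prevalence"] = run_prevalence_experiment(cfg, ctx)
    out["families"] = run_family_experiment(cfg, ctx)
    out["clades"] = run_clade_analysis(cfg, ctx)
    return out
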