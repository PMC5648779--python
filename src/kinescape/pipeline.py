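"""End-to-end analysis pipeline.

``run_pipeline`` drives the full chain

    generate/ingest → featurize → cluster → estimate → validate
    → propagate → project → dissipate

from a single validated configuration, writing every artifact as a plain
text file plus a reproducibility manifest (config, seeds, package version,
content hashes). Stages whose configuration and upstream hashes are
unchanged are skipped on re-runs (cache hits are recorded in the
manifest), so individual stages are independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .errors import ConfigError, EstimationError, KinescapeError, StageError
from .geometry import (
    DistanceFeature,
    FeatureMatrix,
    MolecularFrameSet,
    RmsdFeature,
    SasaFeature,
    Selection,
    featurize,
    read_structure,
    write_structure,
)
from .io import save_count_matrix, save_dtraj, save_model
from .landscape import (
    default_initial_distribution,
    equilibrium_surface,
    project_surface,
    propagate,
    sample_state_representatives,
)
from .msm import build_msm, count_transitions, kcenters_cluster
from .synthetic import (
    LangevinParams,
    PotentialSpec,
    embed_pseudo_atoms,
    pseudo_atom_features,
    simulate,
)
from .validation import ck_test, implied_timescales
from .dissipation import biased_propagate, dissipation_surface

logger = logging.getLogger("kinescape.pipeline")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "featurize",
    "cluster",
    "msm",
    "validate",
    "propagate",
    "project",
    "dissipate",
)


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration; with the seed it fully determines
    every output."""

    output_dir: str
    seed: int = 2024
    # input: either synthetic generation or multi-model PDB paths
    source: str = "synthetic"  # synthetic | pdb
    pdb_paths: tuple[str, ...] = ()
    frame_interval_ns: float | None = None
    potential: PotentialSpec = field(default_factory=PotentialSpec)
    langevin: dict = field(default_factory=dict)  # overrides for LangevinParams
    write_structures: bool = False
    # order parameters: None → pseudo-atom defaults (synthetic source)
    order_parameters: tuple[dict, ...] | None = None
    # clustering / estimation
    cluster_radius: float = 2.0
    cluster_metric: str = "euclidean_feature"
    lag_ns: float = 5.0
    counting_mode: str = "sliding"
    lag_scan_ns: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 15.0)
    # validation
    basin: tuple[int, ...] | str = "initial"  # explicit states or "initial"
    ck_probe_multiples: tuple[int, ...] = (0, 1, 2, 4, 8, 16)
    # landscape / dissipation
    n_per_state: int = 10
    op_pair: tuple[str, str] | None = None
    grid_bins: int = 50
    surface_times_ns: tuple[float, ...] = (5.0, 30.0, 100.0, 300.0)
    lambdas: tuple[float, ...] = (1.0, 2.0)
    probe_times_ns: tuple[float, ...] = (30.0, 100.0)


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_LANGEVIN_KEYS = {f.name for f in dataclasses.fields(LangevinParams)}
_POTENTIAL_KEYS = {f.name for f in dataclasses.fields(PotentialSpec)}


def _err(path: str, message: str) -> ConfigError:
    return ConfigError(f"{path}: {message}")


def validate_config(raw: dict[str, Any]) -> RunConfig:
    """Schema-check a raw config mapping and inject defaults.

    Unknown keys are rejected with the offending path; cross-field
    constraints (e.g. the lag being a multiple of the frame interval) are
    enforced before any stage runs.
    """
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise _err(sorted(unknown)[0], "unknown configuration key")
    if "output_dir" not in raw:
        raise _err("output_dir", "required key missing")
    cooked = dict(raw)
    if "potential" in cooked and isinstance(cooked["potential"], dict):
        bad = set(cooked["potential"]) - _POTENTIAL_KEYS
        if bad:
            raise _err(f"potential.{sorted(bad)[0]}", "unknown key")
        pot = {
            k: tuple(tuple(p) for p in v) if k == "well_centers" else (tuple(v) if isinstance(v, list) else v)
            for k, v in cooked["potential"].items()
        }
        cooked["potential"] = PotentialSpec(**pot)
    if "langevin" in cooked:
        bad = set(cooked["langevin"]) - _LANGEVIN_KEYS
        if bad:
            raise _err(f"langevin.{sorted(bad)[0]}", "unknown key")
    for key in ("pdb_paths", "lag_scan_ns", "ck_probe_multiples", "surface_times_ns", "lambdas", "probe_times_ns"):
        if key in cooked and isinstance(cooked[key], list):
            cooked[key] = tuple(cooked[key])
    if "order_parameters" in cooked and isinstance(cooked["order_parameters"], list):
        cooked["order_parameters"] = tuple(cooked["order_parameters"])
    if "basin" in cooked and isinstance(cooked["basin"], list):
        cooked["basin"] = tuple(int(b) for b in cooked["basin"])
    if "op_pair" in cooked and isinstance(cooked["op_pair"], list):
        cooked["op_pair"] = tuple(cooked["op_pair"])
    try:
        cfg = RunConfig(**cooked)
    except (TypeError, KinescapeError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    # cross-field checks
    if cfg.source not in ("synthetic", "pdb"):
        raise _err("source", f"must be 'synthetic' or 'pdb', got {cfg.source!r}")
    if cfg.source == "pdb" and not cfg.pdb_paths:
        raise _err("pdb_paths", "required when source is 'pdb'")
    if cfg.source == "pdb" and cfg.frame_interval_ns is None:
        raise _err("frame_interval_ns", "required when source is 'pdb'")
    if cfg.cluster_radius <= 0:
        raise _err("cluster_radius", f"must be positive, got {cfg.cluster_radius}")
    if cfg.n_per_state < 1:
        raise _err("n_per_state", "must be >= 1")
    if cfg.grid_bins < 2:
        raise _err("grid_bins", "must be >= 2")
    interval = _frame_interval(cfg)
    for name, lags in (("lag_ns", (cfg.lag_ns,)), ("lag_scan_ns", cfg.lag_scan_ns)):
        for lag in lags:
            steps = lag / interval
            if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
                raise _err(name, f"lag {lag} ns is not a positive multiple of the frame interval {interval} ns")
    if any(lam <= 0 for lam in cfg.lambdas):
        raise _err("lambdas", "bias strengths must be positive")
    return cfg


def _frame_interval(cfg: RunConfig) -> float:
    if cfg.source == "pdb":
        return float(cfg.frame_interval_ns)
    return _langevin_params(cfg).frame_interval_ns


def _langevin_params(cfg: RunConfig) -> LangevinParams:
    kw = dict(cfg.langevin)
    kw.setdefault("seed", cfg.seed)
    return LangevinParams(**kw)


def _parse_selection(d: dict) -> Selection:
    return Selection(
        residue_number=d.get("residue_number"),
        residue_name=d.get("residue_name"),
        atom_names=tuple(d["atom_names"]) if d.get("atom_names") else None,
        part=d.get("part", "any"),
    )


def _parse_order_parameters(cfg: RunConfig):
    if cfg.order_parameters is None:
        if cfg.source != "synthetic":
            raise ConfigError("order_parameters: required for PDB input")
        return pseudo_atom_features()
    defs = []
    for i, raw in enumerate(cfg.order_parameters):
        kind = raw.get("type")
        name = raw.get("name")
        if not name:
            raise _err(f"order_parameters[{i}].name", "required")
        if kind == "distance":
            defs.append(
                DistanceFeature(
                    name=name,
                    group_a=_parse_selection(raw["group_a"]),
                    group_b=_parse_selection(raw["group_b"]),
                    mode=raw.get("mode", "centroid"),
                )
            )
        elif kind == "rmsd":
            defs.append(
                RmsdFeature(
                    name=name,
                    selection=_parse_selection(raw.get("selection", {"part": "backbone"})),
                    reference_frame=raw.get("reference_frame", 0),
                )
            )
        elif kind == "sasa":
            defs.append(
                SasaFeature(
                    name=name,
                    target=_parse_selection(raw["target"]),
                    probe_radius=raw.get("probe_radius", 1.4),
                    n_points=raw.get("n_points", 960),
                )
            )
        else:
            raise _err(f"order_parameters[{i}].type", f"unknown type {kind!r}")
    return defs


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path, config_dict: dict):
        self.path = path
        if path.exists():
            self.data = json.loads(path.read_text())
        else:
            self.data = {"stages": {}, "files": {}}
        self.data["package_version"] = _pkg_version
        self.data["config"] = config_dict
        self.cache_hits: list[str] = []

    def stage_fresh(self, stage: str, input_hash: str, outdir: Path) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec or rec.get("input_hash") != input_hash or rec.get("status") != "ok":
            return False
        return all((outdir / f).exists() for f in rec.get("outputs", []))

    def record(self, stage: str, input_hash: str, outputs: Sequence[Path], outdir: Path, elapsed: float, status: str = "ok"):
        self.data["stages"][stage] = {
            "input_hash": input_hash,
            "outputs": [str(p.relative_to(outdir)) for p in outputs],
            "elapsed_s": round(elapsed, 3),
            "status": status,
        }
        for p in outputs:
            self.data["files"][str(p.relative_to(outdir))] = _hash_file(p)
        self.write()

    def write(self):
        self.data["cache_hits"] = self.cache_hits
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(config: RunConfig | dict, through_stage: str | None = None, force: bool = False) -> dict:
    """Execute the pipeline (optionally only up to ``through_stage``).

    Returns the manifest dict. Unchanged stages are skipped using the
    manifest's input hashes; any stage error aborts with the stage name and
    leaves a FAILED marker in the manifest.
    """
    if isinstance(config, dict):
        config = validate_config(config)
    if through_stage is not None and through_stage not in STAGES:
        raise ConfigError(f"unknown stage {through_stage!r}; stages are {STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    manifest = _Manifest(outdir / "manifest.json", cfg_dict)
    state: dict[str, Any] = {}
    last = STAGES.index(through_stage) if through_stage else len(STAGES) - 1
    upstream_hash = _hash_obj({"seed": config.seed, "version": _pkg_version})
    for stage in STAGES[: last + 1]:
        input_hash = _hash_obj([upstream_hash, _stage_config(config, stage)])
        upstream_hash = input_hash
        fresh = not force and manifest.stage_fresh(stage, input_hash, outdir)
        t0 = time.perf_counter()
        try:
            outputs = _run_stage(stage, config, state, outdir, load_only=fresh)
        except KinescapeError as exc:
            manifest.record(stage, input_hash, [], outdir, time.perf_counter() - t0, status="FAILED")
            raise StageError(stage, str(exc)) from exc
        if fresh:
            manifest.cache_hits.append(stage)
            manifest.write()
            logger.info("stage %s: cache hit", stage)
        else:
            manifest.record(stage, input_hash, outputs, outdir, time.perf_counter() - t0)
            logger.info("stage %s: done in %.2fs (%d files)", stage, time.perf_counter() - t0, len(outputs))
    return manifest.data


def _stage_config(cfg: RunConfig, stage: str) -> dict:
    d = dataclasses.asdict(cfg)
    keys = {
        "simulate": ["source", "pdb_paths", "frame_interval_ns", "potential", "langevin", "seed", "write_structures"],
        "featurize": ["order_parameters"],
        "cluster": ["cluster_radius", "cluster_metric"],
        "msm": ["lag_ns", "counting_mode"],
        "validate": ["lag_scan_ns", "basin", "ck_probe_multiples"],
        "propagate": ["surface_times_ns"],
        "project": ["n_per_state", "op_pair", "grid_bins", "seed"],
        "dissipate": ["lambdas", "probe_times_ns"],
    }[stage]
    return {k: d[k] for k in keys}


def _run_stage(stage: str, cfg: RunConfig, state: dict, outdir: Path, load_only: bool) -> list[Path]:
    # NB: even on cache hits the stage recomputes in memory when a later
    # stage needs its objects; load_only stages with loadable artifacts
    # reload instead where cheap. For simplicity every stage rebuilds its
    # in-memory state; load_only only suppresses file writes.
    fn = {
        "simulate": _stage_simulate,
        "featurize": _stage_featurize,
        "cluster": _stage_cluster,
        "msm": _stage_msm,
        "validate": _stage_validate,
        "propagate": _stage_propagate,
        "project": _stage_project,
        "dissipate": _stage_dissipate,
    }[stage]
    return fn(cfg, state, outdir, load_only)


def _stage_simulate(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    outputs: list[Path] = []
    if cfg.source == "pdb":
        parts = []
        for i, path in enumerate(cfg.pdb_paths):
            fs = read_structure(path, frame_interval_ns=cfg.frame_interval_ns)
            fs.trajectory_ids[:] = i
            parts.append(fs)
        state["frames"] = MolecularFrameSet.concatenate(parts)
        return outputs
    params = _langevin_params(cfg)
    ens = simulate(cfg.potential, params)
    state["ensemble"] = ens
    state["frames"] = embed_pseudo_atoms(ens)
    if not load_only:
        p = outdir / "trajectories.csv"
        ens.to_csv(p)
        outputs.append(p)
        m = outdir / "generator.json"
        m.write_text(
            json.dumps(
                {"potential": dataclasses.asdict(cfg.potential), "langevin": dataclasses.asdict(params)},
                indent=2,
            )
        )
        outputs.append(m)
        if cfg.write_structures:
            sp_ = outdir / "pseudo_structures.pdb"
            write_structure(state["frames"], sp_)
            outputs.append(sp_)
    return outputs


def _stage_featurize(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    defs = _parse_order_parameters(cfg)
    fm = featurize(state["frames"], defs)
    state["features"] = fm
    if load_only:
        return []
    p = outdir / "features.csv"
    fm.to_csv(p)
    return [p]


def _stage_cluster(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    data = state["features"] if cfg.cluster_metric == "euclidean_feature" else state["frames"]
    dtraj, centers = kcenters_cluster(data, radius=cfg.cluster_radius, metric=cfg.cluster_metric)
    state["dtraj"], state["centers"] = dtraj, centers
    if load_only:
        return []
    p = outdir / "dtraj.csv"
    save_dtraj(dtraj, p)
    c = outdir / "centers.csv"
    np.savetxt(c, centers, fmt="%d", header="center_frame_index", comments="")
    return [p, c]


def _stage_msm(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    dtraj = state["dtraj"]
    lag_steps = int(round(cfg.lag_ns / dtraj.frame_interval_ns))
    counts = count_transitions(dtraj, lag_steps, mode=cfg.counting_mode)
    model, mapping, relabeled = build_msm(dtraj, lag_steps, mode=cfg.counting_mode)
    state.update(model=model, index_map=mapping, dtraj_trimmed=relabeled)
    if load_only:
        return []
    outputs = save_count_matrix(counts, outdir / "counts")
    outputs += save_model(model, outdir / "transition_matrix")
    p = outdir / "index_map.csv"
    np.savetxt(p, np.column_stack([np.arange(mapping.size), mapping]), fmt="%d", header="old_state,new_state", comments="", delimiter=",")
    outputs.append(p)
    return outputs


def _resolve_basin(cfg: RunConfig, state) -> np.ndarray:
    if isinstance(cfg.basin, tuple):
        return np.asarray(cfg.basin, int)
    if cfg.basin == "initial":
        p0 = default_initial_distribution(state["dtraj_trimmed"], state["model"].n_states)
        return np.flatnonzero(p0 > 0)
    raise ConfigError(f"basin: unknown specifier {cfg.basin!r}")


def _stage_validate(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    dtraj = state["dtraj"]
    interval = dtraj.frame_interval_ns
    lags = [int(round(l / interval)) for l in cfg.lag_scan_ns]
    scan = implied_timescales(dtraj, lags, n_timescales=3, mode=cfg.counting_mode)
    basin = _resolve_basin(cfg, state)
    ck = ck_test(state["model"], state["dtraj_trimmed"], basin, cfg.ck_probe_multiples)
    state.update(timescale_scan=scan, ck=ck, basin=basin)
    if load_only:
        return []
    p1 = outdir / "timescales.csv"
    scan.to_csv(p1)
    p2 = outdir / "ck.csv"
    ck.to_csv(p2)
    return [p1, p2]


def _propagation_steps(cfg: RunConfig) -> int:
    return int(np.ceil(max(cfg.surface_times_ns + cfg.probe_times_ns) / cfg.lag_ns))


def _stage_propagate(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    model = state["model"]
    p0 = default_initial_distribution(state["dtraj_trimmed"], model.n_states)
    evo = propagate(model, p0, _propagation_steps(cfg))
    state.update(p0=p0, evolution=evo)
    if load_only:
        return []
    import pandas as pd

    n_t, n_s = evo.distributions.shape
    df = pd.DataFrame(
        {
            "time_ns": np.repeat(evo.times_ns, n_s),
            "state": np.tile(np.arange(n_s), n_t),
            "probability": evo.distributions.ravel(),
        }
    )
    p = outdir / "evolution.csv"
    df.to_csv(p, index=False)
    return [p]


def _op_pair(cfg: RunConfig, features: FeatureMatrix) -> tuple[str, str]:
    if cfg.op_pair is not None:
        return cfg.op_pair
    if len(features.feature_names) < 2:
        raise ConfigError("op_pair: need at least two order parameters to project")
    return (features.feature_names[0], features.feature_names[1])


def _stage_project(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    model, evo, fm = state["model"], state["evolution"], state["features"]
    reps = sample_state_representatives(model, cfg.n_per_state, seed=cfg.seed)
    state["representatives"] = reps
    pair = _op_pair(cfg, fm)
    idx = sorted({min(int(round(t / cfg.lag_ns)), evo.n_times - 1) for t in cfg.surface_times_ns})
    surf = project_surface(evo, reps, fm, pair, bins=cfg.grid_bins, time_indices=idx)
    eq = equilibrium_surface(model, reps, fm, pair, bins=cfg.grid_bins)
    state.update(surface=surf, equilibrium=eq)
    if load_only:
        return []
    p1 = outdir / "surface.csv"
    surf.to_csv(p1)
    p2 = outdir / "equilibrium_surface.csv"
    eq.to_csv(p2)
    return [p1, p2]


def _stage_dissipate(cfg: RunConfig, state, outdir: Path, load_only: bool) -> list[Path]:
    model, fm = state["model"], state["features"]
    reps = state["representatives"]
    pair = _op_pair(cfg, fm)
    p0 = state["p0"]
    n_steps = _propagation_steps(cfg)
    probe_idx = sorted({min(int(round(t / cfg.lag_ns)), n_steps) for t in cfg.probe_times_ns})
    outputs: list[Path] = []
    state["tilted"] = {}
    for lam in cfg.lambdas:
        res = biased_propagate(model, lam, p0, n_steps)
        state["tilted"][lam] = res
        surf = dissipation_surface(res, reps, fm, pair, bins=cfg.grid_bins, time_indices=probe_idx)
        state.setdefault("dissipation_surfaces", {})[lam] = surf
        if not load_only:
            p = outdir / f"delta_f_lambda{lam:g}.csv"
            res.to_dataframe().to_csv(p, index=False)
            outputs.append(p)
            ps = outdir / f"dissipation_surface_lambda{lam:g}.csv"
            df = surf.to_dataframe()
            df["lambda"] = lam
            df.to_csv(ps, index=False)
            outputs.append(ps)
    return outputs
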