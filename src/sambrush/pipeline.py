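"""Pipeline orchestration: build -> simulate -> analyze -> report.

Each run writes a JSON manifest (config hash, seed, stage outputs) so every
output file is traceable; the same config and seed reproduce the same
manifest (timestamps aside).  Replica seeds are handled by running the
morphology comparison per seed and reporting mean +/- sd across replicas.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import builder, dynamics, profiles, surface
from .contacts import SwitchParams, s_function_series
from .errors import AnalysisError
from .io import Moiety, Trajectory, select, write_coordinates

__all__ = [
    "RunConfig",
    "run",
    "report",
    "tensile_shift",
    "morphology_metrics",
    "compare_morphologies",
]


@dataclass
class RunConfig:
    preset: str = "NS@P-CLP"          # or "custom"
    stages: tuple[str, ...] = ("build", "simulate", "analyze")
    output_dir: str = "sambrush_run"
    seed: int = 0
    force: bool = False
    synthetic: dict = field(default_factory=dict)   # SyntheticParams overrides
    analysis: dict = field(default_factory=dict)    # thresholds / cutoffs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _synthetic_params(cfg: RunConfig) -> dynamics.SyntheticParams:
    return dynamics.SyntheticParams(seed=cfg.seed, **cfg.synthetic)


def tensile_shift(
    params: dynamics.SyntheticParams,
    pull_acceleration: float = 0.01,
    window_frac: float = 0.25,
    reference: Trajectory | None = None,
) -> float:
    """Z shift of the peptide-moiety density centroid under constant pull.

    Runs the same seed with and without the pull and differences the
    density-weighted mean Z over the final ``window_frac`` of each run.
    Negative values mean displacement toward the gold surface.  An already
    computed pull-free run with the same parameters may be passed as
    ``reference`` to avoid recomputing it.
    """
    free = reference or dynamics.simulate(replace(params, pull_acceleration=0.0))
    pulled = dynamics.simulate(replace(params, pull_acceleration=pull_acceleration))
    t_end = free.frames[-1].time
    t0 = t_end * (1 - window_frac)
    sel = select(free.topology, moiety=Moiety.PEPTIDE)
    p_free = profiles.density_profile(free, sel, window=(t0, t_end), label="peptide")
    p_pull = profiles.density_profile(pulled, sel, window=(t0, t_end), label="peptide")
    return profiles.density_centroid_shift(p_free, p_pull)


def morphology_metrics(
    traj: Trajectory,
    params: dynamics.SyntheticParams,
    window_frac: float = 0.25,
    sasa_stride: int = 5,
) -> dict[str, float]:
    """Summary metrics of one synthetic monolayer run.

    Normalized S function, mean per-chain SASA at both probes, maximum
    pocket depth of the final frame, and the monolayer threshold distance.
    """
    t_end = traj.frames[-1].time
    t0 = t_end * (1 - window_frac)
    window = (t0, t_end)
    s = s_function_series(traj, SwitchParams(), normalize=True, window=window, stride=sasa_stride)
    pep = select(traj.topology, moiety=Moiety.PEPTIDE)
    out = {"s_normalized": float(s.mean())}
    for probe, key in ((0.15, "sasa_water"), (1.5, "sasa_probe")):
        df = surface.sasa_timeseries(traj, pep, probe, window=window, stride=sasa_stride)
        out[key] = float(df.mean(axis=1).mean())
    all_beads = select(traj.topology, moiety=[Moiety.LINKER, Moiety.PEPTIDE])
    hm = surface.mean_height_map(traj, all_beads, window=window, stride=sasa_stride)
    out["max_pocket_depth"] = hm.max_pocket_depth()
    prof = profiles.density_profile(traj, pep, window=window, label="peptide")
    td = profiles.threshold_distance(prof, threshold=200.0, key="peptide")
    out["threshold_distance"] = float("nan") if td is None else td
    if params.pull_acceleration == 0:
        out["tensile_shift"] = tensile_shift(params, window_frac=window_frac, reference=traj)
    return out


def compare_morphologies(
    base: dynamics.SyntheticParams,
    seeds: list[int],
    eps_clustered: float = 1.5,
    eps_grid: float = 0.0,
) -> pd.DataFrame:
    """Clustered-vs-grid metric table, one row per (seed, morphology)."""
    rows = []
    for seed in seeds:
        for label, eps in (("clustered", eps_clustered), ("grid", eps_grid)):
            p = replace(base, seed=seed, interchain_attraction=eps)
            traj = dynamics.simulate(p)
            m = morphology_metrics(traj, p)
            m.update(seed=seed, morphology=label)
            rows.append(m)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# staged runner


def run(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {
        "config_hash": config.content_hash(),
        "preset": config.preset,
        "seed": config.seed,
        "stages": {},
    }
    params = _synthetic_params(config)
    build_path = out / "system.gro"
    traj_path = out / "trajectory.gro"
    if "build" in config.stages:
        if build_path.exists() and not config.force:
            manifest["stages"]["build"] = {"output": str(build_path), "skipped": True}
        else:
            if config.preset.upper().startswith("NS@"):
                system = builder.build_system(config.preset, seed=config.seed)
            else:
                raise ValueError(f"build stage requires an NS@ preset, got {config.preset!r}")
            write_coordinates(system, build_path)
            manifest["stages"]["build"] = {
                "output": str(build_path),
                "n_atoms": len(system.topology),
                "n_peptides": int(np.sum(np.unique(system.topology.peptide_indices) >= 0)),
            }
    if "simulate" in config.stages:
        if traj_path.exists() and not config.force:
            manifest["stages"]["simulate"] = {"output": str(traj_path), "skipped": True}
        else:
            traj = dynamics.simulate(params)
            write_coordinates(traj, traj_path)
            manifest["stages"]["simulate"] = {
                "output": str(traj_path),
                "n_frames": len(traj.frames),
                "params": dataclasses.asdict(params),
            }
    if "analyze" in config.stages:
        traj = dynamics.simulate(params)
        metrics = morphology_metrics(traj, params)
        metrics_path = out / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2))
        prof = profiles.moiety_density_profiles(traj)
        prof_path = out / "density_profile.csv"
        prof.to_frame().to_csv(prof_path, index=False)
        manifest["stages"]["analyze"] = {
            "metrics": str(metrics_path),
            "density_profile": str(prof_path),
            **metrics,
        }
    manifest["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


_REPORT_COLS = [
    "s_normalized", "sasa_water", "sasa_probe", "max_pocket_depth",
    "threshold_distance", "tensile_shift",
]


def report(manifests: list[dict]) -> pd.DataFrame:
    """Side-by-side comparison table of analyzed systems."""
    if not manifests:
        raise AnalysisError("report needs at least one manifest")
    rows = []
    for m in manifests:
        st = m.get("stages", {}).get("analyze")
        if st is None:
            raise AnalysisError("manifest lacks an analyze stage")
        row = {"preset": m.get("preset"), "seed": m.get("seed")}
        row.update({k: st.get(k) for k in _REPORT_COLS})
        rows.append(row)
    return pd.DataFrame(rows)
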