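"""Experiment orchestration: configs, presets, replicate sweeps, pipelines.

A condition is a full ``ModelParams`` plus a replicate count and base seed;
replicate ``i`` runs with seed ``base_seed + i`` so any run can be
reproduced bit-for-bit from its manifest.  The figure presets bundle the
published parameter combinations: the no-feedback motility-mode survey
(weak vs strong adhesion, low vs high formation rate), the
feedback-enabled low-adhesion regime, and the two cluster-morphology
conditions (many small clusters vs few large clusters).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tracks as T
from .engine import SimulationResult, run_simulation
from .msdmodels import fit_msd
from .params import ModelParams

__all__ = [
    "ExperimentConfig",
    "SweepSpec",
    "PRESETS",
    "preset_params",
    "simulate_condition",
    "analyze_condition",
    "run_experiment",
    "run_sweep",
    "run_preset",
    "cluster_morphology_analysis",
]


# -- presets ----------------------------------------------------------------

_TAB2_BASE = dict(p_e=0.0055, p_d=0.0008)  # no-feedback conditions
_FB_BASE = dict(p_e=0.0055, p_d=0.001, enabled=True, b=0.5, s=0.1)
_FIG8_BASE = dict(p_d=0.0004, lambda_adh=60.0, enabled=True, b=0.5, s=0.12)

#: name -> keyword overrides on the Table-3 default ModelParams
PRESETS: dict[str, dict] = {
    "act-only": dict(),
    "table2-weak": dict(lambda_adh=20.0, p_s=0.004, **_TAB2_BASE),
    "table2-weak-high-ps": dict(lambda_adh=20.0, p_s=0.02, **_TAB2_BASE),
    "table2-strong-low-ps": dict(lambda_adh=100.0, p_s=0.004, **_TAB2_BASE),
    "table2-pivoting": dict(lambda_adh=100.0, p_s=0.02, **_TAB2_BASE),
    "fig6-floating": dict(lambda_adh=100.0, p_s=0.001, **_FB_BASE),
    "fig6-stick-slip": dict(lambda_adh=100.0, p_s=0.0025, **_FB_BASE),
    "fig6-threshold": dict(lambda_adh=100.0, p_s=0.004, **_FB_BASE),
    "fig8-blue": dict(p_s=0.003, p_e=0.0015, **_FIG8_BASE),
    "fig8-orange": dict(p_s=0.001, p_e=0.004, **_FIG8_BASE),
}

#: composite presets: list of condition names run together
PRESET_GROUPS: dict[str, list[str]] = {
    "fig2": ["table2-weak", "table2-strong-low-ps", "table2-weak-high-ps", "table2-pivoting"],
    "fig3-grid": ["table2-weak", "table2-strong-low-ps", "table2-weak-high-ps", "table2-pivoting"],
    "fig4-msd": ["table2-weak", "table2-strong-low-ps", "table2-weak-high-ps", "table2-pivoting"],
    "fig6": ["fig6-floating", "fig6-stick-slip", "fig6-threshold"],
    "fig7-grid": ["fig6-floating", "fig6-stick-slip", "fig6-threshold"],
    "fig8-clusters": ["fig8-blue", "fig8-orange"],
}


def preset_params(name: str, base: ModelParams | None = None) -> ModelParams:
    """Expand a named condition preset into a full ModelParams."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    base = base if base is not None else ModelParams()
    return base.replace(**PRESETS[name])


# -- configuration ----------------------------------------------------------


@dataclass
class ExperimentConfig:
    """One simulation campaign: parameters, replicates, seeds, sampling."""

    params: ModelParams = field(default_factory=ModelParams)
    n_replicates: int = 30
    base_seed: int = 0
    record_interval: int = T.DEFAULT_SAMPLING
    snapshot_interval: int = 0
    speed_window: int = T.DEFAULT_SPEED_WINDOW
    output_dir: str = "output"
    preset: str | None = None

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        self.params.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        params = d.pop("params", {})
        cfg = cls(params=ModelParams.from_dict(params), **d)
        if cfg.preset:
            cfg.params = preset_params(cfg.preset, cfg.params)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        import tomllib

        return cls.from_dict(tomllib.loads(text))


@dataclass
class SweepSpec:
    """Parameter grid layered over a base configuration."""

    grid: list[tuple[str, list]] = field(default_factory=list)

    def validate(self, params: ModelParams) -> None:
        valid = set(params.to_dict()) | {"enabled", "b", "s"}
        for name, values in self.grid:
            if name not in valid:
                raise ValueError(f"unknown parameter {name!r} in sweep grid")
            if not values:
                raise ValueError(f"empty value list for {name!r}")

    def points(self) -> list[dict]:
        pts = [dict()]
        for name, values in self.grid:
            pts = [dict(p, **{name: v}) for p in pts for v in values]
        return pts

    @classmethod
    def from_file(cls, path) -> "SweepSpec":
        path = Path(path)
        if path.suffix == ".json":
            data = json.loads(path.read_text())
        else:
            import tomllib

            data = tomllib.loads(path.read_text())
        return cls(grid=[(k, list(v)) for k, v in data.items()])


# -- pipelines --------------------------------------------------------------


def simulate_condition(
    params: ModelParams,
    n_replicates: int,
    base_seed: int,
    record_interval: int = T.DEFAULT_SAMPLING,
    snapshot_interval: int = 0,
    speed_window: int = T.DEFAULT_SPEED_WINDOW,
    log=None,
) -> list[SimulationResult]:
    """Run ``n_replicates`` independent replicates (seed = base_seed + i)."""
    results = []
    t0 = time.time()
    for i in range(n_replicates):
        res = run_simulation(
            params,
            seed=base_seed + i,
            record_interval=record_interval,
            snapshot_interval=snapshot_interval,
        )
        results.append(res)
        if log is not None:
            log(f"  replicate {i + 1}/{n_replicates} (seed {base_seed + i}) "
                f"done in {time.time() - t0:.1f}s total")
    return results


def analyze_condition(
    results: list[SimulationResult],
    burn_in: int | None = None,
    speed_window: int = T.DEFAULT_SPEED_WINDOW,
    fit_models: tuple = (),
    diffusion_window: tuple = (11500, 24000),
) -> dict:
    """Ensemble statistics for one condition: speed, adhesion area, MSD,
    diffusivity and (optionally) MSD model fits."""
    params = results[0].params
    if burn_in is None:
        burn_in = params.burn_in_mcs
    trajs = [T.trajectory_from_result(r, speed_window, replicate_id=i)
             for i, r in enumerate(results)]
    post = [tr.mcs >= burn_in for tr in trajs]
    speeds = np.concatenate([tr.speed[m & ~np.isnan(tr.speed)]
                             for tr, m in zip(trajs, post)])
    adh = np.concatenate([tr.adhesion_fraction[m] for tr, m in zip(trajs, post)])
    msd = T.ensemble_msd(trajs, burn_in=burn_in)
    out = {
        "n_replicates": len(results),
        "mean_speed": float(speeds.mean()),
        "mean_adh_fraction": float(adh.mean()),
        "msd": msd,
        "trajectories": trajs,
    }
    lo, hi = diffusion_window
    if msd.lag.max() >= hi:
        out["diffusion_coefficient"] = T.diffusion_coefficient(msd, diffusion_window)
    fits = {}
    for model in fit_models:
        fits[model] = fit_msd(msd, model)
    out["fits"] = fits
    return out


def run_experiment(config: ExperimentConfig, log=print) -> Path:
    """Run a campaign and write tracks, snapshots and a manifest.

    Produces one track CSV per replicate, one adhesion-snapshot npz per
    replicate (when snapshots are enabled) and ``manifest.json`` echoing
    the full configuration; identical config and seed reproduce identical
    bytes.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dims = (config.params.width, config.params.height)
    manifest = {
        "config": config.to_dict(),
        "replicate_seeds": [config.base_seed + i for i in range(config.n_replicates)],
        "format": {"track": "tracks/replicate_<i>.csv", "snapshots": "snapshots/replicate_<i>.npz"},
    }
    (outdir / "tracks").mkdir(exist_ok=True)
    if config.snapshot_interval > 0:
        (outdir / "snapshots").mkdir(exist_ok=True)
    for i in range(config.n_replicates):
        res = run_simulation(
            config.params,
            seed=config.base_seed + i,
            record_interval=config.record_interval,
            snapshot_interval=config.snapshot_interval,
        )
        tr = T.trajectory_from_result(res, config.speed_window, replicate_id=i)
        T.write_track_csv(outdir / "tracks" / f"replicate_{i}.csv", [tr], dims)
        if config.snapshot_interval > 0:
            snaps = res.snapshots
            np.savez_compressed(
                outdir / "snapshots" / f"replicate_{i}.npz",
                mcs=np.array([m for m, _ in snaps]),
                sites=np.array([np.pad(s, (0, max(0, 4000 - s.size)))[:4000] for m, s in snaps]),
                counts=np.array([s.size for _, s in snaps]),
                dims=np.array(dims),
            )
        log(f"replicate {i + 1}/{config.n_replicates} written (seed {config.base_seed + i})")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def run_sweep(config: ExperimentConfig, spec: SweepSpec, log=print) -> Path:
    """Run the grid of parameter combinations under a base config."""
    spec.validate(config.params)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, overrides in enumerate(spec.points()):
        params = config.params.replace(**overrides)
        sub = dataclasses.replace(
            config, params=params, output_dir=str(outdir / f"point_{j}")
        )
        log(f"sweep point {j}: {overrides}")
        run_experiment(sub, log=log)
        rows.append({"point": j, **overrides})
    pd.DataFrame(rows).to_csv(outdir / "sweep_points.csv", index=False)
    return outdir


def run_preset(name: str, scale: str = "desk", output_dir: str | None = None,
               n_replicates: int | None = None, base_seed: int = 0,
               log=print) -> dict:
    """Run a figure preset end to end and emit CSV + JSON (+ plots).

    ``scale='desk'`` runs a reduced replicate count (default 30, logged in
    the report); ``scale='full'`` runs the published 1000 replicates.
    """
    if name in PRESETS:
        group = [name]
    elif name in PRESET_GROUPS:
        group = PRESET_GROUPS[name]
    else:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS) + sorted(PRESET_GROUPS)}"
        )
    if scale not in ("desk", "full"):
        raise ValueError("scale must be 'desk' or 'full'")
    if n_replicates is None:
        n_replicates = 30 if scale == "desk" else 1000
    if n_replicates < 1:
        raise ValueError("replicate count must be >= 1")
    outdir = Path(output_dir or f"preset_{name}")
    outdir.mkdir(parents=True, exist_ok=True)
    want_fits = name.startswith(("fig4", "fig8", "table2", "fig6"))
    report: dict = {
        "preset": name,
        "scale": scale,
        "n_replicates": n_replicates,
        "base_seed": base_seed,
        "conditions": {},
    }
    summaries = {}
    for cond in group:
        params = preset_params(cond)
        log(f"[{name}] condition {cond}: {n_replicates} replicates")
        results = simulate_condition(
            params, n_replicates, base_seed,
            snapshot_interval=100, log=lambda m: log(m) if n_replicates <= 5 else None,
        )
        summary = analyze_condition(
            results, fit_models=("furth_dt", "fkk") if want_fits else ())
        summaries[cond] = (results, summary)
        msd = summary["msd"]
        pd.DataFrame({"lag": msd.lag, "msd": msd.msd}).to_csv(
            outdir / f"msd_{cond}.csv", index=False)
        dims = (params.width, params.height)
        T.write_track_csv(outdir / f"tracks_{cond}.csv", summary["trajectories"], dims)
        report["conditions"][cond] = {
            "params": params.to_dict(),
            "mean_speed": summary["mean_speed"],
            "mean_adh_fraction": summary["mean_adh_fraction"],
            "diffusion_coefficient": summary.get("diffusion_coefficient"),
            "fits": {m: f.to_dict() for m, f in summary["fits"].items()},
        }
    if name == "fig8-clusters" or set(group) == {"fig8-blue", "fig8-orange"}:
        report["cluster_analysis"] = _fig8_cluster_analysis(summaries, outdir)
    _plot_preset(name, summaries, outdir)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log(f"[{name}] report written to {outdir / 'report.json'}")
    return report


def cluster_morphology_analysis(
    conditions: dict[str, tuple[list[SimulationResult], list[T.Trajectory]]],
    cluster_interval: int = 1000,
) -> dict:
    """Adhesion-cluster sizes and front-rear distributions per condition.

    For every replicate: connected-component sizes of the adhesion layer
    (Moore connectivity, periodic) at ``cluster_interval`` snapshots after
    burn-in, and the pooled projections of adhesion sites on the
    instantaneous front-rear axis.  With exactly two conditions the
    two-sample K-S statistic between the pooled front-rear distributions
    is included under ``"ks_front_rear"``.
    """
    out: dict = {}
    proj = {}
    for cond, (results, trajs) in conditions.items():
        params = results[0].params
        dims = (params.width, params.height)
        sizes = []
        projections = []
        for res, traj in zip(results, trajs):
            cluster_snaps = [(m, s) for m, s in res.snapshots
                             if m % cluster_interval == 0 and m >= params.burn_in_mcs]
            for _, layer in _dense_layers(res, cluster_snaps):
                sizes.extend(T.adhesion_clusters(layer).sizes.tolist())
            usable = [(m, s) for m, s in res.snapshots
                      if params.burn_in_mcs <= m <= params.duration_mcs - 25]
            ap = T.front_rear_projection(usable, traj, dims)
            projections.append(ap.projections)
        proj[cond] = np.concatenate(projections) if projections else np.empty(0)
        csd = np.asarray(sizes, dtype=int)
        out[cond] = {
            "cluster_sizes": csd,
            "projections": proj[cond],
            "n_clusters": int(csd.size),
            "max_cluster_size": int(csd.max()) if csd.size else 0,
            "mean_projection": float(proj[cond].mean()) if proj[cond].size else None,
        }
    conds = list(conditions)
    if len(conds) == 2 and all(proj[c].size for c in conds):
        d, p = T.ks_statistic(proj[conds[0]], proj[conds[1]])
        out["ks_front_rear"] = {"D": d, "p": p}
    return out


def _fig8_cluster_analysis(summaries: dict, outdir: Path) -> dict:
    """Run the cluster-morphology pipeline and write its CSV outputs."""
    analysis = cluster_morphology_analysis(
        {cond: (results, summary["trajectories"])
         for cond, (results, summary) in summaries.items()})
    out: dict = {}
    for cond, entry in analysis.items():
        if cond == "ks_front_rear":
            out[cond] = entry
            continue
        pd.DataFrame({"size": entry["cluster_sizes"]}).to_csv(
            outdir / f"cluster_sizes_{cond}.csv", index=False)
        pd.DataFrame({"projection": entry["projections"]}).to_csv(
            outdir / f"projections_{cond}.csv", index=False)
        out[cond] = {k: entry[k] for k in
                     ("n_clusters", "max_cluster_size", "mean_projection")}
    return out


def _dense_layers(res: SimulationResult, snaps):
    n = res.height * res.width
    for m, sites in snaps:
        layer = np.zeros(n, dtype=bool)
        layer[sites] = True
        yield m, layer.reshape(res.height, res.width)


def _plot_preset(name: str, summaries: dict, outdir: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, (_, summary) in summaries.items():
        msd = summary["msd"]
        m = msd.lag > 0
        ax.loglog(msd.lag[m], msd.msd[m], label=cond)
        for model, fit in summary["fits"].items():
            ax.loglog(msd.lag[m], fit.predict(msd.lag[m]), "--", lw=0.8,
                      label=f"{cond} {model}")
    ax.set_xlabel("lag (MCS)")
    ax.set_ylabel("MSD (sites$^2$)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / f"msd_{name}.png", dpi=120)
    plt.close(fig)
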