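"""Experiment orchestration and command-line interface.

Reproduces the experiment layout of the study: optimize the normal model,
then — with the prosthesis applied and the ankle muscles removed — re-search
either the leg-symmetric or the per-leg (asymmetric) feedback parameters,
warm-started from the normal solution, across a list of seeds.  Every run
writes trial logs (CSV), metric summaries (JSON), GA histories (CSV), the
best controller weights (YAML) and a manifest with full provenance.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .body import (BodyModel, default_body, apply_prosthesis, save_body,
                   load_body)
from .controller import ControllerWeights, save_weights, load_weights
from .ga import (GAConfig, Scenario, make_scenario, scenario_body,
                 evaluate_genome, run_ga, warm_start_utta, FitnessRecord)
from .metrics import summarize_trial, NoStepsError
from .muscle import default_muscles, save_muscles
from .simulate import run_trial, TrialResult


@dataclass
class ScenarioConfig:
    """One experimental condition and its run settings."""

    scenario: str = "normal"
    prosthesis_side: str = "right"
    duration: float = 10.0
    dt: float = 1e-4
    stride_window: tuple[int, int] = (3, 8)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    ga: GAConfig = field(default_factory=GAConfig)
    warm_noise: float = 0.1

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seeds list must be non-empty")
        if self.scenario not in ("normal", "utta_symmetric", "utta_asymmetric"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _config_digest(cfg: ScenarioConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(cfg: ScenarioConfig, outdir,
                   normal_weights: ControllerWeights | None = None,
                   body: BodyModel | None = None,
                   map_fn=None) -> dict:
    """Run the GA for every seed and evaluate each best genome.

    For the prosthesis scenarios ``normal_weights`` (the previously
    acquired normal controller) is a prerequisite.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = make_scenario(cfg.scenario, cfg.prosthesis_side)
    if scenario.name != "normal" and normal_weights is None:
        raise FileNotFoundError(
            "prosthesis scenarios require the normal-model weights "
            "(run the normal scenario first)")
    body = scenario_body(scenario, body)

    files = []
    summaries = []
    for seed in cfg.seeds:
        ga_cfg = GAConfig(**{**asdict(cfg.ga), "seed": int(seed)})

        def eval_fn(genome):
            return evaluate_genome(genome, scenario, body=body,
                                   base=normal_weights,
                                   duration=cfg.duration, dt=cfg.dt)

        init = None
        if scenario.name != "normal":
            rng = np.random.default_rng(int(seed))
            init = warm_start_utta(normal_weights, scenario,
                                   ga_cfg.population, rng, cfg.warm_noise)
        res = run_ga(eval_fn, scenario.bounds, ga_cfg,
                     init_population=init, map_fn=map_fn)

        tag = f"{cfg.scenario}_seed{seed}"
        hist_path = outdir / f"ga_history_{tag}.csv"
        res.history.to_csv(hist_path, index=False)
        files.append(hist_path.name)

        weights = scenario.decode(res.best_genome, normal_weights)
        wpath = outdir / f"weights_{tag}.yaml"
        save_weights(weights, wpath)
        files.append(wpath.name)

        trial = run_trial(body=body, weights=weights,
                          duration=cfg.duration, dt=cfg.dt)
        tpath = outdir / f"trial_{tag}.csv"
        trial.to_csv(tpath)
        files.append(tpath.name)

        try:
            summary = summarize_trial(trial, cfg.stride_window)
        except (NoStepsError, ValueError) as err:
            summary = {"error": str(err), "distance": trial.distance,
                       "fell": bool(trial.fell), "speed": trial.speed}
        summary["seed"] = int(seed)
        summary["best_fitness"] = float(res.best_record.fitness)
        mpath = outdir / f"metrics_{tag}.json"
        mpath.write_text(json.dumps(summary, indent=2))
        files.append(mpath.name)
        summaries.append(summary)

    manifest = {
        "package_version": __version__,
        "scenario": asdict(cfg),
        "config_digest": _config_digest(cfg),
        "files": files,
        "complete": True,
    }
    (outdir / f"manifest_{cfg.scenario}.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return {"manifest": manifest, "summaries": summaries}


# ---------------------------------------------------------------------------
# fixtures for tests and smoke runs (no simulation involved)

def make_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Synthetic inputs with known properties.

    kinds: ``toy-grf`` (square-wave GRFs with encoded stance times),
    ``periodic-trial`` (a fully periodic trial log with known stance times
    and step lengths), ``controller-weights`` (bounded random weight
    files), ``body-configs`` (normal + prosthesis body YAMLs and the
    default muscle table).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    out = []
    if kind == "toy-grf":
        t = np.arange(0.0, 10.0, 1e-3)
        stance, cycle, shift = 0.6, 1.0, 0.5
        grf_l = ((t % cycle) < stance) * 700.0
        grf_r = (((t - shift) % cycle) < stance) * 700.0
        df = pd.DataFrame({"t": t, "grf_l": grf_l, "grf_r": grf_r})
        p = outdir / "toy_grf.csv"
        df.to_csv(p, index=False)
        out.append(p)
    elif kind == "periodic-trial":
        p = outdir / "periodic_trial.csv"
        synthetic_trial(stance=0.6, cycle=1.0, step=0.35).to_csv(p)
        out.append(p)
    elif kind == "controller-weights":
        for name, symmetric in (("weights_symmetric.yaml", True),
                                ("weights_random.yaml", False)):
            wf = rng.uniform(-2, 2, (2, 16))
            if symmetric:
                wf[1] = wf[0]
            w = ControllerWeights(u0=float(rng.uniform(0.5, 3.0)),
                                  w_feed=wf,
                                  w_cpg=rng.uniform(-3, 1, 11),
                                  w_pos=rng.uniform(-5, 5, 23))
            p = outdir / name
            save_weights(w, p)
            out.append(p)
    elif kind == "body-configs":
        normal = default_body()
        p = outdir / "body_normal.yaml"
        save_body(normal, p)
        out.append(p)
        p = outdir / "body_utta_right.yaml"
        save_body(apply_prosthesis(normal, "right"), p)
        out.append(p)
        p = outdir / "muscles.csv"
        save_muscles(default_muscles(), p)
        out.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return out


def synthetic_trial(stance: float = 0.6, cycle: float = 1.0,
                    step: float = 0.35, n_cycles: int = 12,
                    body_mass: float = 70.0, power: float = 100.0,
                    dt: float = 1e-3) -> TrialResult:
    """A perfectly periodic synthetic trial (no dynamics): square-wave
    GRFs, feet advancing one step length per half cycle, constant total
    metabolic rate.  Synthetic — for metric tests only."""
    t = np.arange(0.0, n_cycles * cycle, dt)
    n = len(t)
    grf = np.zeros((n, 2))
    grf[:, 0] = ((t % cycle) < stance) * 700.0
    grf[:, 1] = (((t - cycle / 2) % cycle) < stance) * 700.0
    speed = 2 * step / cycle
    # feet alternate: each foot advances 2*step once per cycle during swing
    foot_x = np.zeros((n, 4))
    phase_l = np.floor(t / cycle)
    phase_r = np.floor((t - cycle / 2) / cycle)
    foot_x[:, 0] = 2 * step * phase_l
    foot_x[:, 1] = foot_x[:, 0] + 0.25
    foot_x[:, 2] = 2 * step * phase_r + step
    foot_x[:, 3] = foot_x[:, 2] + 0.25
    q = np.zeros((n, 9))
    q[:, 0] = speed * t
    q[:, 1] = 0.89
    qd = np.zeros((n, 9))
    qd[:, 0] = speed
    edot = np.full((n, 18), power / 18.0)
    return TrialResult(t=t, q=q, qd=qd, grf=grf, foot_x=foot_x,
                       alpha=np.zeros((n, 18)), edot=edot,
                       distance=float(q[-1, 0]), fell=False,
                       t_end=float(t[-1]), energy=power * t[-1],
                       body_mass=body_mass)


# ---------------------------------------------------------------------------
# CLI

@click.group()
def cli():
    """cpgwalk: planar CPG-driven neuromusculoskeletal walking simulator."""


@cli.command("simulate")
@click.option("--weights", "weights_path", type=click.Path(exists=True),
              required=True, help="controller weight YAML")
@click.option("--body", "body_path", type=click.Path(exists=True),
              help="body YAML (default: built-in normal body)")
@click.option("--duration", default=10.0, show_default=True)
@click.option("--dt", default=1e-4, show_default=True)
@click.option("--out", "out_path", type=click.Path(), required=True,
              help="trial log CSV")
def cli_simulate(weights_path, body_path, duration, dt, out_path):
    """Run a single trial from a weight file."""
    body = load_body(body_path) if body_path else default_body()
    trial = run_trial(body=body, weights=load_weights(weights_path),
                      duration=duration, dt=dt)
    trial.to_csv(out_path)
    click.echo(f"distance={trial.distance:.3f} m fell={trial.fell} "
               f"t_end={trial.t_end:.2f} s speed={trial.speed:.3f} m/s")


@cli.command("optimize")
@click.option("--scenario", type=click.Choice(
    ["normal", "utta_symmetric", "utta_asymmetric"]), default="normal",
    show_default=True)
@click.option("--side", default="right", show_default=True)
@click.option("--seed", "seeds", multiple=True, type=int, default=(0,),
              show_default=True)
@click.option("--population", default=100, show_default=True)
@click.option("--generations", default=100, show_default=True)
@click.option("--duration", default=10.0, show_default=True)
@click.option("--normal-weights", "normal_path", type=click.Path(exists=True),
              help="normal-model weight YAML (required for UTTA scenarios)")
@click.option("--outdir", type=click.Path(), required=True)
def cli_optimize(scenario, side, seeds, population, generations, duration,
                 normal_path, outdir):
    """Run the GA for a scenario across seeds."""
    cfg = ScenarioConfig(
        scenario=scenario, prosthesis_side=side, duration=duration,
        seeds=tuple(seeds),
        ga=GAConfig(population=population, generations=generations))
    normal_weights = load_weights(normal_path) if normal_path else None
    try:
        res = run_experiment(cfg, outdir, normal_weights=normal_weights)
    except FileNotFoundError as err:
        raise click.ClickException(str(err))
    for s in res["summaries"]:
        click.echo(json.dumps(s))


@cli.command("metrics")
@click.argument("trial_csv", type=click.Path(exists=True))
@click.option("--window", nargs=2, type=int, default=(3, 8), show_default=True)
@click.option("--out", "out_path", type=click.Path())
def cli_metrics(trial_csv, window, out_path):
    """Recompute gait metrics from a trial log."""
    trial = TrialResult.from_csv(trial_csv)
    try:
        summary = summarize_trial(trial, tuple(window))
    except (NoStepsError, ValueError) as err:
        raise click.ClickException(str(err))
    text = json.dumps(summary, indent=2)
    if out_path:
        Path(out_path).write_text(text)
    click.echo(text)


@cli.command("fixtures")
@click.option("--kind", type=click.Choice(
    ["toy-grf", "periodic-trial", "controller-weights", "body-configs"]),
    required=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
def cli_fixtures(kind, seed, outdir):
    """Generate synthetic fixture files."""
    for p in make_fixtures(kind, seed, outdir):
        click.echo(str(p))
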