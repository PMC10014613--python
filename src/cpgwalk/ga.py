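"""Genetic-algorithm search over controller parameters.

The fitness of one trial is

    J = D + P                 (D < 3 m)
    J = D + P + 60 / C        (D >= 3 m)

where D is the distance walked until the model falls (or the trial ends),
P = -3.0 if the model fell (else 0), and C the gross metabolic cost of
transport over the trial, so short walks are rewarded for distance and
sustained walks additionally for economy.

Three scenario genomes are searched:

* ``normal``          — 51 genes: u0, the 16 leg-symmetric feedback
  coefficients, the 11 CPG connection strengths and the 23 posture
  coefficients;
* ``utta_symmetric``  — 17 genes: u0 + the 16 feedback coefficients tied
  across legs, everything else frozen at the normal solution;
* ``utta_asymmetric`` — 33 genes: u0 + all 32 per-leg feedback
  coefficients, everything else frozen at the normal solution.

The optimizer is a seeded generational GA: tournament selection, blend
crossover, Gaussian mutation (sigma = 5 % of each gene's range), elitism,
hard clipping to bounds.  Evaluations go through a pluggable map so they
can be dispatched to a process pool; a crashed trial yields a fall record
rather than killing the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body import BodyModel, default_body, apply_prosthesis
from .controller import ControllerWeights, N_FEED, N_CPG_PARAMS, N_POS
from .muscle import MuscleSpec
from .simulate import run_trial

FALL_PENALTY = -3.0
DISTANCE_GATE = 3.0   # m; beyond this the economy term enters

U0_BOUNDS = (0.0, 5.0)
FEED_BOUNDS = (-5.0, 5.0)
CPG_BOUNDS = (-5.0, 5.0)
POS_BOUNDS = (-10.0, 10.0)

SCENARIOS = ("normal", "utta_symmetric", "utta_asymmetric")


@dataclass
class Genome:
    """A parameter vector bound to a scenario (with seed provenance)."""

    values: np.ndarray
    scenario: str
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        expected = {"normal": 51, "utta_symmetric": 17, "utta_asymmetric": 33}
        if self.scenario not in expected:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.values.shape != (expected[self.scenario],):
            raise ValueError(
                f"{self.scenario} genome needs {expected[self.scenario]} "
                f"genes, got {self.values.shape}")


@dataclass
class FitnessRecord:
    """Outcome of one evaluated trial."""

    distance: float
    fell: bool
    cot: float          # gross cost of transport over the trial (J/kg/m)
    fitness: float = float("nan")
    t_end: float = 0.0


def fitness(record: FitnessRecord) -> float:
    """Trial fitness J (see module docstring)."""
    P = FALL_PENALTY if record.fell else 0.0
    if record.distance < DISTANCE_GATE:
        return record.distance + P
    if not record.cot > 0:
        raise ValueError("cost of transport must be positive when D >= 3 m")
    return record.distance + P + 60.0 / record.cot


@dataclass
class Scenario:
    """Genome layout for one experimental condition."""

    name: str
    n_genes: int
    bounds: np.ndarray          # (n_genes, 2)
    prosthesis_side: str | None = None

    def decode(self, genome, base: ControllerWeights | None = None
               ) -> ControllerWeights:
        """Controller weights from a genome (plus the frozen base for the
        prosthesis scenarios)."""
        g = np.asarray(genome, float)
        if g.shape != (self.n_genes,):
            raise ValueError(
                f"{self.name} genome must have {self.n_genes} genes, "
                f"got {g.shape}")
        if self.name == "normal":
            return ControllerWeights(
                u0=g[0],
                w_feed=np.vstack([g[1:17], g[1:17]]),
                w_cpg=g[17:28].copy(),
                w_pos=g[28:51].copy())
        if base is None:
            raise ValueError(f"{self.name} requires the normal-model weights")
        if self.name == "utta_symmetric":
            return ControllerWeights(
                u0=g[0], w_feed=np.vstack([g[1:17], g[1:17]]),
                w_cpg=base.w_cpg.copy(), w_pos=base.w_pos.copy(),
                tau=base.tau, taup=base.taup, beta=base.beta)
        return ControllerWeights(
            u0=g[0], w_feed=np.vstack([g[1:17], g[17:33]]),
            w_cpg=base.w_cpg.copy(), w_pos=base.w_pos.copy(),
            tau=base.tau, taup=base.taup, beta=base.beta)

    def encode_from(self, base: ControllerWeights) -> np.ndarray:
        """Genome whose decode reproduces ``base`` (used for warm starts)."""
        if self.name == "normal":
            return np.concatenate(
                [[base.u0], base.w_feed[0], base.w_cpg, base.w_pos])
        if self.name == "utta_symmetric":
            return np.concatenate([[base.u0], base.w_feed[0]])
        return np.concatenate([[base.u0], base.w_feed[0], base.w_feed[1]])


def _stack_bounds(parts) -> np.ndarray:
    rows = []
    for (lo, hi), n in parts:
        rows.extend([(lo, hi)] * n)
    return np.array(rows, float)


def make_scenario(name: str, prosthesis_side: str | None = None) -> Scenario:
    """Scenario genome layout: normal 51 genes, symmetric 17, asymmetric 33."""
    if name == "normal":
        bounds = _stack_bounds([(U0_BOUNDS, 1), (FEED_BOUNDS, N_FEED),
                                (CPG_BOUNDS, N_CPG_PARAMS), (POS_BOUNDS, N_POS)])
        return Scenario("normal", 51, bounds)
    if name == "utta_symmetric":
        bounds = _stack_bounds([(U0_BOUNDS, 1), (FEED_BOUNDS, N_FEED)])
        return Scenario("utta_symmetric", 17, bounds,
                        prosthesis_side=prosthesis_side or "right")
    if name == "utta_asymmetric":
        bounds = _stack_bounds([(U0_BOUNDS, 1), (FEED_BOUNDS, 2 * N_FEED)])
        return Scenario("utta_asymmetric", 33, bounds,
                        prosthesis_side=prosthesis_side or "right")
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


def scenario_body(scenario: Scenario, body: BodyModel | None = None) -> BodyModel:
    body = body if body is not None else default_body()
    if scenario.prosthesis_side is None:
        return body
    return apply_prosthesis(body, scenario.prosthesis_side)


def evaluate_genome(genome, scenario: Scenario,
                    body: BodyModel | None = None,
                    muscles: list[MuscleSpec] | None = None,
                    base: ControllerWeights | None = None,
                    duration: float = 10.0,
                    dt: float = 1e-4) -> FitnessRecord:
    """Decode a genome, run one trial from the standard initial posture and
    score it.  Deterministic given genome and configs; any simulation
    failure is reported as a fall at the current distance."""
    weights = scenario.decode(genome, base)  # mismatches raise
    body = scenario_body(scenario, body)
    try:
        trial = run_trial(body=body, muscles=muscles, weights=weights,
                          duration=duration, dt=dt)
        rec = FitnessRecord(distance=trial.distance, fell=trial.fell,
                            cot=trial.cost_of_transport, t_end=trial.t_end)
    except Exception:
        # fault isolation: a crashed trial scores as an immediate fall
        rec = FitnessRecord(distance=0.0, fell=True, cot=float("inf"))
    rec.fitness = fitness(rec)
    return rec


@dataclass
class GAConfig:
    population: int = 100
    generations: int = 100
    tournament: int = 3
    cx_prob: float = 0.8
    blend_alpha: float = 0.2
    mut_prob: float = 0.15
    mut_sigma_frac: float = 0.05
    elitism: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")


@dataclass
class GAResult:
    best_genome: np.ndarray
    best_record: FitnessRecord
    history: pd.DataFrame
    population: np.ndarray
    fitnesses: np.ndarray


def _clip(pop: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(pop, bounds[:, 0], bounds[:, 1])


def run_ga(eval_fn, bounds, config: GAConfig,
           init_population: np.ndarray | None = None,
           map_fn=None) -> GAResult:
    """Generational GA maximizing ``eval_fn(genome) -> FitnessRecord``.

    ``map_fn`` (default builtin map) lets callers plug a process-pool map;
    evaluation order never affects the result.  Elites carry their records
    forward without re-evaluation, making best fitness non-decreasing.
    """
    bounds = np.asarray(bounds, float)
    n_genes = len(bounds)
    rng = np.random.default_rng(config.seed)
    map_fn = map_fn or map
    span = bounds[:, 1] - bounds[:, 0]
    sigma = config.mut_sigma_frac * span

    if init_population is None:
        pop = rng.uniform(bounds[:, 0], bounds[:, 1],
                          size=(config.population, n_genes))
    else:
        pop = _clip(np.asarray(init_population, float).copy(), bounds)
        if pop.shape != (config.population, n_genes):
            raise ValueError("init_population shape mismatch")

    records = list(map_fn(eval_fn, pop))
    fits = np.array([r.fitness for r in records])
    hist_rows = []

    for gen in range(config.generations):
        order = np.argsort(fits)[::-1]
        best = order[0]
        hist_rows.append({
            "generation": gen,
            "best_fitness": fits[best],
            "mean_fitness": float(np.mean(fits)),
            "best_distance": records[best].distance,
            "best_cot": records[best].cot,
        })
        if gen == config.generations - 1:
            break

        elites = pop[order[:config.elitism]].copy()
        elite_recs = [records[i] for i in order[:config.elitism]]
        elite_fits = fits[order[:config.elitism]].copy()

        n_child = config.population - config.elitism
        children = np.empty((n_child, n_genes))
        for c in range(0, n_child, 2):
            i = _tournament(fits, rng, config.tournament)
            j = _tournament(fits, rng, config.tournament)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < config.cx_prob:
                a, b = _blend(a, b, config.blend_alpha, rng)
            children[c] = a
            if c + 1 < n_child:
                children[c + 1] = b
        mut = rng.random(children.shape) < config.mut_prob
        children = children + mut * rng.normal(0.0, 1.0, children.shape) * sigma
        children = _clip(children, bounds)

        child_records = list(map_fn(eval_fn, children))
        pop = np.vstack([elites, children])
        records = elite_recs + child_records
        fits = np.concatenate([elite_fits,
                               [r.fitness for r in child_records]])

    order = np.argsort(fits)[::-1]
    best = order[0]
    return GAResult(best_genome=pop[best].copy(), best_record=records[best],
                    history=pd.DataFrame(hist_rows), population=pop,
                    fitnesses=fits)


def _tournament(fits, rng, k):
    idx = rng.integers(0, len(fits), size=k)
    return idx[np.argmax(fits[idx])]


def _blend(a, b, alpha, rng):
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    d = hi - lo
    u = rng.uniform(lo - alpha * d, hi + alpha * d)
    v = rng.uniform(lo - alpha * d, hi + alpha * d)
    return u, v


def warm_start_utta(normal_weights: ControllerWeights, scenario: Scenario,
                    population: int, rng: np.random.Generator,
                    noise_frac: float = 0.1) -> np.ndarray:
    """Initial UTTA population around the normal model's free genes.

    The first individual is the normal solution verbatim (which no longer
    walks after amputation); the rest add Gaussian exploration noise with
    sigma = noise_frac * gene range, clipped to bounds.
    """
    if scenario.name == "normal":
        raise ValueError("warm start applies to the prosthesis scenarios")
    center = scenario.encode_from(normal_weights)
    span = scenario.bounds[:, 1] - scenario.bounds[:, 0]
    pop = np.tile(center, (population, 1))
    if noise_frac > 0:
        pop[1:] += rng.normal(0.0, noise_frac, (population - 1,
                                                scenario.n_genes)) * span
    return _clip(pop, scenario.bounds)
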