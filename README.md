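# cpgwalk

A planar neuromusculoskeletal walking simulator for studying how the spinal
control of locomotion adapts to a changed body — in particular to unilateral
transtibial amputation (UTTA) with a passive prosthesis.

The model is a minimal closed-loop system of human gait: a 7-segment biped
(head-arms-trunk, thighs, shanks, feet) actuated by 9 Hill-type muscles per
leg, driven by a 12-unit Matsuoka central pattern generator (CPG) with
sensory feedback, and optimized by a genetic algorithm (GA). Gaits are
scored by the gross metabolic cost of transport and by the symmetry of
spatiotemporal gait parameters. It is aimed at researchers in computational
neuromechanics and gait rehabilitation who want a small, fully inspectable
forward-dynamics sandbox rather than a full 3-D musculoskeletal stack.

## The model

**Muscles.** Each muscle produces tension from a contractile element (CE)
with force–length and force–velocity gains, a passive damper (PD) and a
passive elastic element (PE):

```
F = F̄CE · k(ξ) · h(η) · α  +  cPD · L̇  +  kPE (e^{15(L − L̄)} − 1)
k(ξ) = 0.32 + 0.71 e^{−1.112(ξ−1)} sin(3.722(ξ − 0.656))
h(η) = 1 + tanh(3η)
```

with ξ = L/L̄, η = L̇/L̇̄ and activation α ∈ [0, 1]. Paths use constant
moment arms, calibrated so L = L̄ in neutral standing.

**CPG.** Twelve Matsuoka units (a flexor/extensor oscillator per hip, knee
and ankle of each leg):

```
τ u̇ᵢ = −uᵢ + Σⱼ w^CPG_{ij} yⱼ − β vᵢ + u₀ + Feedᵢ
τ′ v̇ᵢ = −vᵢ + yᵢ ,   yᵢ = max(0, uᵢ)
```

`Feedᵢ` is a linear combination of segment-angle deviations and
contact-gated vertical ground reaction forces (GRFs) through 16 searchable
coefficients per leg. Motoneurons map CPG output plus a stance-gated
posture correction P through a saturating sigmoid into α.

**Mechanics.** Minimal coordinates (pelvis x, y + 7 absolute segment
angles), pin joints with linear viscosity (1.09 / 3.17 / 0.943 Nms/rad at
hip/knee/ankle), stiff one-sided springs locking the joints beyond their
range, and spring–damper ground contact at heel and toe. Everything is
integrated monolithically with classical RK4 at a 0.1 ms step.

**Optimization and scoring.** A generational GA maximizes

```
J = D + P              (D < 3 m)          P = −3 if the model fell
J = D + P + 60 / C     (D ≥ 3 m)          C = ∫ΣĖ dt / (T·M·V)  [J/kg/m]
```

Scenarios: `normal` (51 free parameters: u₀, 16 symmetric feedback weights,
11 CPG connections, 23 posture gains), `utta_symmetric` (re-search u₀ + the
16 leg-tied feedback weights after amputation) and `utta_asymmetric`
(u₀ + all 32 per-leg feedback weights). The prosthesis operator removes
TA/SO/GC on one side, scales the shank+foot mass to 65 % and inertia to
40 %, and adds a 400 Nm/rad passive ankle spring. Summaries report stance
time, step length, their symmetry indices `ASI = 2(R−L)/(R+L)·100`, and the
cost of transport over strides 3–8.

## Worked example

```python
import numpy as np
from cpgwalk import run_trial, make_scenario, evaluate_genome
from cpgwalk.ga import run_ga, GAConfig

# a passive controller cannot stand against the initial push
trial = run_trial(duration=10.0)
print(f"distance walked : {trial.distance:.3f} m")
print(f"fell            : {trial.fell} (at t = {trial.t_end:.2f} s)")

# a short controller search already finds forward progress
scenario = make_scenario("normal")
res = run_ga(lambda g: evaluate_genome(g, scenario, duration=4.0),
             scenario.bounds, GAConfig(population=16, generations=10, seed=1))
print(res.history[["generation", "best_fitness", "best_distance"]]
      .tail(1).to_string(index=False))
```

prints

```
distance walked : 0.215 m
fell            : True (at t = 0.79 s)
 generation  best_fitness  best_distance
          9     -1.938848       1.061152
```

The passive model topples 0.21 m forward in 0.79 s; ten GA generations of a
16-member population raise the best travelled distance to 1.06 m (fitness
is distance minus the −3 fall penalty until a genome sustains 3 m and the
economy term 60/C starts to matter). Full experiments use the CLI:

```
cpgwalk optimize --scenario normal --seed 0 --outdir runs/normal
cpgwalk optimize --scenario utta_asymmetric \
    --normal-weights runs/normal/weights_normal_seed0.yaml --outdir runs/utta
cpgwalk metrics runs/utta/trial_utta_asymmetric_seed0.csv
```

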