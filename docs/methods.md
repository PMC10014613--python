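# Methods

This note documents the modelling assumptions, default parameters, numerical
choices and limitations of `cpgwalk`. It states nothing the tests or
`scripts/acceptance.py` do not themselves compute.

## Skeletal model

Seven rigid segments — a lumped head-arms-trunk (HAT), two thighs, two
shanks, two feet — move in the sagittal plane. Generalized coordinates are
minimal: pelvis/hip position (x, y) plus the seven absolute segment angles
(9 DOF). This keeps the mass matrix 9×9 and avoids constraint
stabilization. The equations of motion are assembled Newton–Euler style
from analytic point Jacobians (each COM and contact point is the hip plus a
chain of rotated body-frame offsets); the symmetric positive-definite mass
matrix is factorized by Cholesky at every derivative evaluation. Two
consistency properties pin the assembly: total mechanical energy is
conserved to integrator accuracy when all dissipative elements are switched
off, and a full spatial mirror of state, torques and forces mirrors the
accelerations.

Hips, knees and ankles are pin joints with linear viscosities 1.09, 3.17
and 0.943 Nms/rad. Knee and ankle ranges of motion are enforced by stiff
one-sided torsional spring–dampers (1000 Nm/rad, 50 Nms/rad) engaged beyond
the limits — a "lock" implemented as a penalty rather than a hard
constraint so the whole system stays a smooth ODE for RK4. Default segment
parameters (70 kg, ~1.7 m: HAT 48 kg, thigh 7 kg/0.41 m, shank 3 kg/0.42 m,
foot 1 kg with heel 7 cm behind and toe 18 cm ahead of the ankle, sole 6 cm
below it) are **reconstructed** from standard anthropometric tables; this
model family does not come with a published parameter table, so these
defaults are editable via the YAML body configuration and should be treated as a
plausible adult, not a specific subject.

Ground contact acts at the heel and toe of each foot: vertical force
`k_v·depth + c_v·(−ẏ)` floored at zero (a spring–damper would otherwise
pull the foot down at lift-off), horizontal spring–damper anchored to the
touchdown point and reset at lift-off. Coefficients: 5.0e3 N/m and
1.0e3 Ns/m horizontally, 2.5e4 N/m and 5.0e2 Ns/m vertically. Anchors and
contact activity are event states updated once per full integration step.

## Muscles

Nine muscles per leg (GM, IL, BFL, RF, BFS, VA, GC, SO, TA) follow the
Hill-type form given in the README. Design choices:

* **Constant moment arms, reference-posture calibration.** No path
  geometry is published for this model family, so muscle length is linear
  in joint angles, `L = L̄ + Σ ρⱼ θⱼ`, with L = L̄ at neutral standing.
  ρ magnitudes (3.5–6.2 cm) sit in the anatomical range; signs encode
  anatomy (e.g. VA tension extends the knee, RF lengthens with hip
  extension and with knee flexion).
* **Force–velocity sign.** `h(η) = 1 + tanh(3η)` with η > 0 on
  *lengthening* by default, giving the usual concentric deficit / eccentric
  enhancement. The convention is exposed as `fv_sign` because "contraction
  velocity" is sign-ambiguous as usually written.
* **PE active in stretch only** (floored at 0): the exponential would
  otherwise produce a compressive passive force in shortening.
* **No activation dynamics**: motoneuron output feeds the CE instantly.
* Per-muscle constants (F̄CE 0.8–3 kN, L̄ 6–40 cm, L̇̄ ≈ 4 L̄/s, cPD
  30–70 Ns/m, kPE 8–20 N) are **reconstructed** defaults in the editable
  CSV muscle table; no canonical table exists for this model family.

## Neural controller

The 12 Matsuoka units are organized as hip/knee/ankle flexor–extensor
pairs per leg. Defaults τ = 0.05 s, τ′ = 0.6 s, β = 2.5 put the isolated
network in a stable limit-cycle regime with a period near 1 s (the
two-unit analysis in the acceptance script measures ~0.89 s for τ = 0.1,
τ′ = 0.2, β = 2.5, mutual inhibition −2.5, invariant to initial conditions
to <0.1 %). The connection matrix is generated from 11 shared strengths:
within-pair mutual inhibition per joint, contralateral hip–hip coupling,
and ipsilateral hip→knee→ankle couplings; these 11 are GA-searched.

**Feedback wiring.** The 16 per-leg slots map {HAT pitch, ipsi/contra
thigh angle, ipsi shank angle, ipsi foot angle} to the corresponding
flexor/extensor units and {ipsi, contra} body-weight-normalized vertical
GRF to extensor (ipsi) and flexor (contra) units of all three joints. No
canonical slot semantics exist for this model family; the table here is a
documented, editable reconstruction — the GA searches the signed
coefficients regardless of slot semantics, which is what the scenario
contrast (16 tied vs 32 free) actually exercises.

**Motoneurons.** `α = clamp(2/(1+exp(−0.25(Σ wᵅ y + P))) − 1, 0, 1)`.
Two deliberate choices: the sigmoid is increasing (a positive exponent
argument would invert the drive–activation relation and violate
0 ≤ α ≤ 1), and the drive sum runs over the 12 CPG units through a fixed
18×12 map. Each muscle is driven by
its joint's flexor or extensor unit; biarticular muscles by both joints
with half gains. wᵅ is structural, not searched — consistent with the free
parameter set being u₀, feedback, CPG and posture weights only.

**Posture control.** 23 searchable coefficients mix PD terms on HAT pitch
(target −0.1 rad, slight forward lean), stance-leg joint angles and
normalized GRF into per-muscle corrections, gated by ipsilateral foot
contact so swing-leg muscles receive none.

## Trials, falls and initial conditions

A trial integrates the monolithic 42-state system (mechanics + CPG) for up
to 10 s at dt = 0.1 ms, logging every 1 ms. The initial condition is a
standing posture with a small fore-aft leg split (±0.15 rad), a slight
trunk lean and a 0.35 m/s forward push, with the hip height solved so the
lowest contact point just touches the ground; the CPG receives a fixed
antisymmetric kick so the leg oscillators start in antiphase. Initial
conditions are a free modelling choice; these are shipped in config for
reproducibility. A fall is declared when the HAT COM drops below 60 %
of its standing height, the hip drops below 0.45 m, or the state leaves
the finite range (numerical blow-up under aggressive GA samples is scored
as an immediate fall, never an exception).

## Energetics

The per-muscle metabolic rate behind the cost of transport is a documented
three-term model, isolated behind `metrics.metabolic_rate` so it can be
swapped:

```
Ė = c_act·α²·F̄CE·L̇̄  +  c_short·α·F̄CE·max(0, −L̇)  +  max(0, F_CE·(−L̇))
```

activation/maintenance heat, shortening heat, and positive CE mechanical
work, with c_act = 0.15 and c_short = 0.25. The coefficients were chosen
once so that total power during moderate activity lands in the hundreds of
watts for a 70 kg body (cost-of-transport magnitudes in the low J/kg/m
range). Absolute CoT values from this package are
model-specific and should be compared only across conditions, not against
treadmill respirometry.

## Gait metrics

Foot-strike/toe-off are threshold crossings of the vertical GRF (default
10 N) with a 20 ms merge debounce against contact chatter; both defaults
are configurable and were picked to reject the spring–damper's lift-off
transients. Stance time is off − strike; step length is the anterior
distance between the feet at each strike. "Strides 3–8" (1-based,
inclusive — six strides bounding five steps of settled gait) is the default
summary window; step-versus-stride conventions differ across the gait
literature, so the window is fully configurable. The symmetry index
is computed signed and reported both signed and absolute. The cost of
transport integrates the logged rates by the trapezoid rule; halving the
logging step changes it by <0.1 %.

## Optimization

The GA is generational with tournament selection (k = 3), blend crossover
(probability 0.8, α = 0.2), per-gene Gaussian mutation (probability 0.15,
σ = 5 % of the gene range), elitism (2) and hard clipping to bounds —
conventional values, all in config. Gene bounds: u₀ ∈ [0, 5], feedback and CPG weights
∈ [−5, 5], posture gains ∈ [−10, 10]. The normal scenario's 51 free
parameters are u₀ + 16
symmetric feedback + 11 CPG connections + 23 posture gains, shipped as the
scenario mask. UTTA scenarios freeze everything at the normal solution and
re-search only their free genes, warm-started from the normal values plus
10 % exploration noise (the unperturbed normal genome — which no longer
walks after amputation — is kept verbatim as the first individual).
Evaluations run through a pluggable map (serial by default) and a crashed
trial scores as a fall.

## Problem sizes in tests and the acceptance script

The test suite and acceptance script use desk-scale runs chosen as the
package's own verification sizes: a 32×200-generation GA on a surrogate
sphere objective (converges below 1e-2), and a 16×30-generation GA on the
real simulator with 4-s trials, which demonstrates monotone best fitness
under elitism and forward progress beyond 1 m. Acquiring *sustained*
walking in this model family takes population-scale searches over ~2000
generations, which is an experiment to run with the CLI, not a unit test;
nothing in the package asserts gait quality beyond the smoke scale.

## Known limitations

* Two-dimensional; no toe joints (flattening the late-stance GRF peaks),
  no trunk articulation, no muscle wrapping, no tendon compliance or
  activation dynamics, no neural noise or transduction dynamics.
* The default anthropometrics, muscle constants, CPG constants and
  feedback wiring are reconstructions typical of this model family, not a
  specific published subject; results are qualitatively comparable across
  implementations, not parameter-identical.
* The energetics model sets the absolute CoT scale; only relative
  comparisons across scenarios are meaningful.
* The fall definition and initial conditions are package choices; distance
  D near the fall threshold depends mildly on both.
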