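# Methods

`osteoadapt` simulates bone functional adaptation (Wolff's law) in a 2D bone
cross-section containing a biodegradable implant, and scores the osteogenic
effect of the implant's elastic modulus and degradation period.  This note
documents the model, its numerical treatment, the synthetic domains, and the
limits of what the simulations can show.

## The adaptation model

Bone is treated as a self-optimizing structure.  The state variable is the
per-element apparent density ρ_j (g·cm⁻³); stiffness follows the cubic
power law

    E_j = 2315 ρ_j³   (MPa),

a standard apparent-density–modulus relation for cancellous/cortical bone.
At every step the *target* density field ρ̂ minimizes the total strain
energy of the loaded structure,

    F(ρ) = Σ_j ½ σ_jᵀ S_j σ_j v_j ,

subject to the total-mass constraint Σ_j ρ_j v_j = M (bone mass is
conserved by the remodeling process itself) and the density bounds
ρ_min < ρ_j ≤ 1.8 g·cm⁻³, where 1.8 is the maximum (cortical) density and
S_j is the plane-stress compliance matrix.  With E ∝ ρ³ this is the classic
penalized compliance-minimization problem, so the converged structures show
the familiar dense-shell / resorbed-interior patterns.

The actual density moves only a small fraction of the way toward the target
each day, and implanted elements additionally lose the day's degraded
implant mass:

    ρ_j(t+1) = ρ_j(t) + c·(ρ̂_j(t+1) − ρ_j(t)) − [r(t+1) − r(t)]·1{j ∈ implant},

with recycling control rate c = 0.02 per day and a 1-day step.  The run
stops when max_j |Δρ_j| < 0.001 g·cm⁻³ (and, for implant runs, not before
the degradation period has elapsed).  Results are clipped to
[ρ_min, 1.8]; the clip is part of the update contract.

## Implant laws and metrics

An implant with initial modulus E1₀ fills the 36 defect elements with the
equivalent density ρ_imp = (E1₀/2315)^{1/3}.  Two independent empirical
laws govern its disappearance over the degradation period T:

* stiffness: E1(t) = (1 − t/T)^{0.5}·E1₀ — fast early stiffness loss;
* mass: r(t) = ρ_imp·(t/T)² — slow-then-fast cumulative density loss.

The laws are deliberately *not* linked through the density–modulus power
law; they describe different observables of real degradable materials.  The
FEM always uses E = 2315ρ³ for every element (the bookkeeping density of an
implant element already encodes its mechanical contribution); E1(t) enters
only the metrics.

Metrics over the 36 defect elements:

* **osteogenesis score** — mean of max(0, 2315ρ_j³ − E1), the
  bone-attributable modulus.  At day d the score pairs ρ(d) with
  E1 = (1 − (d−1)/T)^{0.5} E1₀, reading the source formula's time index as
  contemporaneous with the updated density; at implantation the score is 0
  by construction.
* **new-bone fraction** — percent of defect elements whose
  bone-attributable density ρ_j − max(ρ_imp − r(t), 0) reaches
  θ = 0.9 of that element's pre-defect converged baseline density.
* **refilled area** — total area of defect elements whose density exceeds
  half the initial implant density, the simulated analogue of the
  radio-visible (micro-CT) refilled defect cross-section.

## Numerical treatment

**Finite elements.**  4-node bilinear isoparametric quadrilaterals, 2×2
Gauss quadrature, plane stress.  Coordinates are stored in cm and converted
to mm internally so N and MPa are consistent (1 N/mm² = 1 MPa); unit
out-of-plane thickness of 1 cm is assumed for element volumes.  Per-element
energy is integrated at the Gauss points (U_j = ½u_eᵀk_e u_e), so ΣU_j
equals ½uᵀKu to round-off; reported stress is the mean over Gauss points.
Supports fully clamp the distal edge; near-void elements keep a modulus
floor of 0.01 MPa so the system stays nonsingular.  The three femur load
rows (joint reaction + trochanter tension at three gait instants) are
treated as alternating load cases solved against one factorization, their
element energies averaged with equal weights.

**Density prediction.**  The mass-constrained minimization is solved with
the optimality-criteria (OC) method: per-unit-mass energy sensitivities
s_j = 3U_j/(ρ̂_j v_j) drive a damped multiplicative update
ρ̂ ← ρ̂·(s/λ)^η with η = 0.5 and a move limit ζ = 0.2 per inner iteration;
the multiplier λ is found by geometric bisection on the mass constraint
(relative tolerance 10⁻⁹).  By default each inner iteration re-solves the
FEM at the candidate field, so the returned ρ̂ is a KKT point of the true
constrained problem (sensitivities equalized over interior elements); a
fixed-stress variant extrapolates U_j(ρ̂) = U_j(ρ/ρ̂)³ from a single solve
and is exact for statically determinate states.  Period-2 OC oscillations
are detected by a step-reversal test and damped by averaging the iterates
(mass-preserving) while tightening the move limit.  Elements clipped at a
bound are naturally held there by the bisection (standard active-set
behavior).  Day-to-day the iteration is warm-started from the previous
day's target, which both accelerates convergence and gives the physically
meaningful history dependence of remodeling.

**Tie-breaks and degenerate inputs.**  Zero total load returns the current
density unchanged (every feasible field is optimal).  Zero-sensitivity
elements resorb at the move-limit rate toward the floor.  An infeasible
mass reference (more mass than the bounds admit) raises immediately.

## Synthetic domains

The source geometries come from CT and are not available, so the package
generates parametric stand-ins with the right topology, loading and
discretization scale, but not the true outlines:

* **Femur-like domain** — union of a shaft rectangle, spherical head, neck
  capsule and greater-trochanter lobe, meshed on a structured grid of
  0.25 cm² quads (1,152 elements).  Node sets: clamped distal edge, femoral
  head crown (joint force), trochanter crown (abductor pull).  The 6×6
  (36-element) defect block sits by default in the lateral
  intertrochanteric metaphysis — the usual drilled-defect site — spanning
  the cortical shell and cancellous interior.
* **Rat metaphysis** — a 5 mm × 8 mm cross-section at the anatomical scale
  of a ~200 g rat, with 0.5 mm cortical walls split into a stiffer
  diaphyseal segment (7000 MPa) and a softer metaphyseal segment
  (2000 MPa), a 900 MPa cancellous core and a 3 mm × 3 mm defect through
  the lateral metaphyseal cortex filled with 800 MPa calcium sulfate
  cement; 0.65 N vertical joint load (one third of body weight); CSC
  degradation period 28 days (within the 4–8-week in-vivo range).
  Initial densities derive from the region moduli through the power law.
* **Rectangular plates** — structured fixtures for unit tests and oracles.

All generators are deterministic; there is no randomness anywhere in the
method, so identical configurations produce bit-identical traces.

## What the stand-ins can and cannot show

The adaptation physics transfers: dense shells form along load paths, the
defect plug regrows where it carries load, degradation-versus-growth race
dynamics appear (the osteogenesis score dips to zero mid-period when
stiffness loss outpaces regrowth, then recovers).  The rat refilled-area
time course reproduces the monotone shrinkage, with the late (day-27) value
landing on the reference and the mid-course value dropping too sharply: on
the stand-in the threshold crossings of shielded plug elements cluster into
one step, where the real cylindrical-defect geometry spreads them out.

Two limits are structural rather than incidental:

1. *Two-phase baselines.*  Unfiltered penalized compliance minimization
   drives converged densities to the bounds; the stand-in baseline is
   essentially bimodal (≈0.06 or ≈1.76 g·cm⁻³), with graded intermediate
   densities only near the head.  Classification thresholds defined
   relative to the local baseline therefore see almost no mid-range
   thresholds inside the defect, which flattens the day-17/19 new-bone
   fraction time course that graded cancellous baselines would produce.
   (Checkerboard/sensitivity filtering would soften this but is explicitly
   out of scope.)
2. *Path-insensitivity of the converged end state.*  Because the daily
   target is the true constrained minimum, runs with different implant
   moduli or degradation periods converge to nearly the same final
   structure (final scores within ~±1 %, hysteresis only).  Implant
   stiffness never enters the elastic solve directly, so a mechanically
   useful void is rebuilt regardless of how weak the implant was — the
   "too-weak-to-support" failure mode requires local-stimulus dead-zone
   dynamics or a bypassable defect, neither of which the global optimizer
   reproduces.  Ordering claims among implant parameters on this stand-in
   are therefore decided by small hysteresis differences, not by robust
   mechanism.

## Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `c` | 0.02 | 1/day | fraction of the gap to the target closed per day |
| `rho_max` | 1.8 | g·cm⁻³ | cortical maximum density (attainable bound) |
| `rho_min_floor` | 0.01 | g·cm⁻³ | numerical void floor |
| `convergence_tol` | 0.001 | g·cm⁻³ | max |Δρ| stopping threshold |
| `density_modulus_coeff/_exp` | 2315 / 3 | MPa | power law E = 2315ρ³ |
| `poisson` | 0.3 | – | all regions |
| `oc_damping` (η) | 0.5 | – | OC update damping exponent |
| `oc_move_limit` (ζ) | 0.2 | g·cm⁻³ | per-inner-iteration move limit |
| `implant_modulus` | 1000 | MPa | default femur experiment E1₀ |
| `degradation_period` | 20 | days | default femur experiment T |
| `new_bone_theta` | 0.9 | – | restored-fraction classification threshold |
| `refill_threshold` | ρ_imp/2 | g·cm⁻³ | radio-visibility superlevel threshold |
| `rat_degradation_period` | 28 | days | CSC resorption time |

The initial intact state is uniform ρ = 1.0 g·cm⁻³, remodeled to
convergence (~150 days) before any defect is introduced.  The femur
baseline and every defect experiment run in well under a minute on one CPU
at the default 1,152-element discretization; the rat run (640 elements of
0.25 mm) takes a similar time.
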