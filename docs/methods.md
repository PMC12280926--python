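# Methods

This note documents the models, estimators and numerical choices behind
`hoverstab`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The scientific setting

A fish with a swim bladder is close to neutrally buoyant, but its center
of mass (COM, set by muscle and skeleton, typically dorsal) and center of
buoyancy (COB, set by the bladder and viscera, typically ventral) do not
coincide. Whenever the COM sits dorsal of the COB the upright posture is
an unstable equilibrium: any small tilt produces a torque that grows the
tilt, exactly as in an inverted pendulum. Hovering — holding position and
orientation at zero net translation — therefore requires continuous
corrective fin forces, and that fine motor control costs energy. The
package quantifies this chain from morphology through kinematics to
metabolic rate.

## Stability model (`hoverstab.stability`)

Posture about one rotational axis obeys

    I * dω/dt = m g d sin(θ) − D(ω) + τ_fin + τ_perturb(t)

with `I = m r_g²` the moment of inertia (`r_g` the radius of gyration:
proportional to body width for roll, body length for pitch), `d` the
COM–COB separation, `D = c ω` a linear rotational damping with `c`
scaling with body surface area, and `τ_fin` the corrective torque.
Solving the balance for `τ_fin` recovers the required-torque reading
(fin torque = destabilising torque − inertial term − drag).

Assumptions and choices:

* **Single axis.** Roll and pitch are run as independent single-axis
  instances differing in `r_g`; cross-axis coupling is ignored.
* **Linear drag.** Rotational damping at the small angular velocities of
  hovering is taken linear in ω. The coefficient is a free parameter
  mapped from surface area in sweeps.
* **PD controller with saturation.** The animal is modelled as sensing θ
  and ω and opposing both: `τ_fin = clip(−kp θ − kd ω, ±F_max·lever)`.
  Defaults via `FinController.tuned_for`: `kp = 5 m g d` (five times the
  critical stiffness below which no proportional controller can
  stabilise) and `kd` at critical damping of the closed loop. Both are
  exposed.
* **Perturbations.** A sinusoidal "ventilation" torque plus white torque
  noise (held constant within an integration step), representing
  broadband internal and environmental disturbance. The noise sequence is
  seeded; identical seeds give bit-identical trajectories.
* **Integration.** Fixed-step classical RK4, default `dt = 1 ms`.
  Halving the step changes the accumulated cost by ≲ 1e-4 relative at the
  default settings. Runs exceeding |θ| = π/2 are truncated and flagged
  `capsized` rather than raised.
* **Linear growth check.** With control and drag off, a small tilt grows
  at `λ = sqrt(m g d / I)`; the simulator reproduces λ to better than 2%
  when the log-slope is fitted over the late window (the exact solution
  is a cosh, whose log-slope approaches λ from below).

### Two cost functionals

* `SimResult.cost` is the mechanical stabilisation work
  `∫ |τ_fin ω| dt`: positive and negative work are both paid (no elastic
  storage). `stabilization_cost` divides it by a muscle/hydrodynamic
  efficiency in (0, 1].
* `fin_force_cost` is `∫ (|τ_fin|/lever)^1.5 dt`. Fin force production in
  water is drag-based (force ∝ velocity²), so the hydrodynamic power
  needed to hold a force F scales as F^(3/2); a fin farther from the COM
  needs less force for the same torque and pays less. The mechanical work
  alone cannot express this — the lever arm cancels between force and fin
  speed — so sweeps over fin position use the force-based functional.

### Morphology sweep (`sweep_and_fit`)

Factors {mass, COM–COB offset (dorsal-origin sign convention, negative =
COB ventral), fin lever proportion, fineness ratio} are mapped to physics
by isometry: body length `L = 0.45 m^(1/3)` (≈10 cm at 10 g), depth
`L/fineness`, width `L/(1.3·fineness)`, `r_g = 0.35·width`, physical
separation `|offset|·depth`, drag coefficient ∝ lateral surface × depth.
Every cell experiences the same absolute seeded perturbation torque
(smaller bodies are therefore relatively more disturbed, which is the
comparative claim under test), and the response is the mass-specific
force-based cost at 20% efficiency. OLS of cost on the four factors then
yields the sign pattern: negative for mass, COM–COB offset and lever
arm; positive for fineness. The default 3×3×3×3 grid at 5 s per cell
runs in a few seconds.

The linear fit summarises a visibly non-linear cost surface (R² ≈ 0.4);
only the signs, not the magnitudes, are interpreted.

## Respirometry (`hoverstab.respirometry`)

The oxygen decline in a closed chamber is fitted by OLS; the
mass-specific rate is

    MO2 [mg O2 kg^-1 h^-1] = slope [mg L^-1 min^-1] × 60 × (V_chamber − V_fish) × M^(−0.9)

with `M` in kg and 0.9 the allometric exponent. The ×60 converts the
per-minute slope to hourly units. Fish volume defaults to the
near-neutral-buoyancy displacement (1 L per kg) when unmeasured. Net cost
is hover − rest; energy uses 3.25 cal per mg O₂ and the thermodynamic
calorie (4.184 J). The default fit window is the full trace. Background
respiration, flush-cycle parsing and solubility corrections are out of
scope.

## Kinematics (`hoverstab.kinematics`)

Coordinates: x anterior–posterior, y lateral (left fins at negative y),
z up. Roll is the transverse-plane angle of the eye → bottom-of-eye
segment from the vertical (an absolute reference, so a statically rolled
posture reads as roll; a `roll_reference="mean"` option uses the
time-mean axis instead). Pitch is the snout → peduncle elevation relative
to its time mean, since the absolute head-up/-down angle is reported
separately as body angle (arcsine of vertical rise over 3-D distance).
Body curvature is the Menger curvature of the snout/peduncle/tail-tip
triplet — four times the triangle area over the product of side lengths,
the inverse circumradius — which is exact for circular arcs and
parameter-free.

**Phase lag.** The left and right pectoral abduction signals (outward
lateral displacement of tip relative to base) are mean-centred and
cross-correlated; the time shift of maximal correlation, converted
through the dominant period, gives the lag folded into [0°, 180°]. Two
numerical points matter: (1) the dominant period comes from the mean
spacing of upward zero crossings of the lightly smoothed signal (seeded
by the periodogram peak), because the finite-sample autocorrelation's
triangular taper biases peak lags short; (2) the correlation is circular
over a whole number of periods, which removes the same taper from the
lag estimate. Both choices make the estimator exact (0°, 90°, 180°) on
sinusoids sampled over whole periods and stable under noise.

**Cycles.** Complete fin-beat cycles are delimited by successive upward
zero crossings of the smoothed, mean-centred signal; crossings closer
than half a period are merged, and exact zeros at the window edges count
so that n sampled periods yield n cycles.

**Fin distance** is the summed inter-frame 3-D displacement per second,
in body lengths; at 1,000 fps the chordal discretisation error for a
smooth stroke is well under 0.5%.

## Morphometry (`hoverstab.morphometry`)

The COM is the least-squares intersection of the suspension axes
(minimising summed squared perpendicular distances; the RMS residual is
reported as a quality measure), computed in the 2-D lateral frame that
matches the photographic protocol. The COB is the unweighted centroid of
the segmented swim-bladder voxel mask. Both are expressed proportionally:
AP as the projection on the snout → caudal-peduncle axis over its length,
DV from the dorsal-most point over the dorsal–ventral span — so a COB
ventral of the COM gives a negative DV offset, and the regression's
negative DV coefficient means cost *rises* with separation. An
absolute-value AP variant supports asking whether direction (anterior vs
posterior COB) matters beyond distance. Fin positions are taken at the
fin-base landmark (configurable; tip vs base is not pinned down by the
measurement protocol).

## Statistics (`hoverstab.stats`)

OLS is fitted on raw (uncentred) predictor scales so the intercept is
interpretable; rank-deficient designs are rejected with the collinear
columns named. Variable importance is the drop in R² from (a) refitting
without a predictor or (b) shuffling its values (seeded, mean over
permutations, fitted coefficients reused — so permuted R² can go
negative and permutation ΔR² can exceed 1). Species fall into the high
metabolic group (G2) when either MO₂net or the hover/rest ratio is
strictly above the across-species mean. One-way ANOVA uses the classical
sum-of-squares decomposition; Tukey HSD the studentized-range
distribution; group contrasts Welch t-tests.

**Abouheif's test.** The proximity between tips i and j is
`1 / prod(direct-descendant counts of the internal nodes on the i→j
path, MRCA included)`; the matrix has zero diagonal and is
row-normalised; Abouheif's C is Moran's I of the centred trait under
that weight matrix. Significance comes from tip permutations with the +1
correction, `p = (1 + #{C_perm ≥ C_obs}) / (n_perm + 1)` (default 999,
seeded); an exhaustive mode enumerates all n! permutations for n ≤ 8.
On the balanced four-taxon tree with a cherry-aligned ±1 trait, C = 1/3
and the exhaustive p is exactly 1/3. The statistic uses topology only —
no branch lengths — and is invariant to affine transforms of the trait.

## Synthetic data (`hoverstab.synthetic`)

The generator reproduces the *structure* of the study — 13 species,
seven morphological predictors, linear metabolic responses with the
packaged reference coefficient vectors, per-minute oxygen traces,
1,000 fps landmark series with sinusoidal roll/pitch and circular or
figure-8 (1:2 Lissajous) pectoral strokes, and a random bifurcating
topology with an optional Brownian trait on unit branches.

Deliberate simplifications, and what they mean for the tests:

* Predictors are independent uniforms. Real morphologies are correlated
  (deep-bodied fishes are also wide); a `fineness_correlation` knob can
  couple the fineness ratios but defaults to off because independence
  maximises identifiability in coefficient-recovery tests. A consequence
  is that the synthetic response *level* (MO₂net roughly 600–1,700 under
  the defaults) is higher than real hovering data, where correlated
  predictors partially cancel; recovery tests are about coefficients,
  not about reproducing empirical MO₂ ranges.
* Response noise defaults (115 mg O₂ kg⁻¹ h⁻¹ for MO₂net, 0.59 for the
  ratio) are derived analytically from the default predictor ranges so
  the full models explain ≈86% and ≈63% of response variance,
  mirroring the explanatory power a full fit should have.
* The within-species individual variance is not identified by any
  species-level quantity; it is exposed as a free coefficient of
  variation (default 0.12).
* Landmark series carry no ventilation perturbation — kinematic
  measurement and perturbation dynamics are deliberately separated
  (perturbations live in the stability simulator).
* Passing the generator round trips shows the estimators are correct and
  unbiased under the generating model; it does not validate digitisation
  error, fin-surface deformation, or non-sinusoidal gaits in real video.

Every generator consumes a single `SyntheticPlan` seed and is
byte-reproducible; the pipeline derives per-stage seeds by stable
hashing of the stage name so stages are reproducible independently of
execution order.

## Problem sizes

Defaults throughout are desk scale, chosen so the full suite and the
reproduction script each run in well under a minute of numerics per
component: 13-species tables (consistency checks use up to 320 species ×
100 replicates), 3 s landmark series at 1,000 fps, 5 s simulations at
1 ms steps, a 3⁴ sweep grid, 199–999 permutations, and 200-replicate
calibration runs.

## Known limitations

* The stability model has no translational degrees of freedom, no
  vortex-resolved hydrodynamics, no ground/wall effect and no multi-fin
  force allocation; "too much leverage can itself destabilise" is noted
  but not modelled.
* Quadratic drag, elastic energy storage and sensory delays are absent
  from the controller.
* The sweep's sign predictions are a property of the stated regime
  (fixed absolute perturbation, isometric shape mapping, force-based
  cost); other regimes — e.g. perturbations scaling with body size —
  can flip the mass sign.
* Phylogenetic regression (PGLS) is out of scope; the phylogenetic layer
  tests signal only.
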