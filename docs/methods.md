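# Methods

`synapse-sim` simulates the population dynamics of immunological synapse
(IS) formation induced by a CD3×CD19 bispecific T-cell engager (BiTE,
blinatumomab-like) with three nested agent-based models sharing one
physical core. This note records the model, its assumptions, the
parameters that matter, and the numerical choices, in that order.

## 1. Physical core

### 1.1 Soluble binding equilibrium ("3D" step)

Before any cell-scale event the drug Y equilibrates against the two
competing antigen pools, CD3 (A) on effector cells and CD19 (B) on target
cells, forming the binary complexes AY and YB. Membrane antigens are
treated as well-mixed solutes in the co-incubation volume. Two mass-action
laws (`AY = [A][Y]/KD_A`, `YB = [B][Y]/KD_B`) and three conservation laws
leave a cubic in the free ligand `[Y]`, solved as a bracketed monotone
scalar root on `[0, Y_tot]` (Brent) polished by Newton steps. This is
unconditionally stable for arbitrary KD ratios; conservation is enforced
to 1e-9 relative and violations raise rather than clamp.

Default arm kinetics are blinatumomab-like: `KD_CD3 = 2.6e-7 M`
(kon 1e4 M⁻¹s⁻¹, koff 2.6e-3 s⁻¹) and `KD_CD19 = 1.5e-9 M`
(koff 1.5e-5 s⁻¹). The CD19 affinity is a literature-typical value for
the construct; both arms are config fields, and the affinity-sweep
analyses vary `koff_A` at fixed on-rate. Drug mass concentration converts
to molar with a 54 kDa molar mass.

### 1.2 Cell populations

Per-cell receptor counts are log-normal (the flow-cytometry convention),
parameterised so the arithmetic mean equals the configured level and with
log-space SD 0.4 by default (chosen once to resemble sorted-subpopulation
histogram widths; overridable). Expression levels, receptors/cell:

| antigen | L | M | H |
|---|---|---|---|
| CD3 (effectors) | 5e4 | 1e5 | 2e5 |
| CD19 (targets) | 4e4 | **1.45e5** (measured) | 3e5 |

Only the CD19 medium level is an experimentally quantified value; the
others are plausible sorted-level defaults. The bulk equilibrium is
distributed to cells proportionally: every cell carries the bulk occupancy
fraction of its own total (a binomial sampling option exists behind a
config flag).

Two receptor processes run during incubation:

* **CD3 downregulation.** Engagement removes surface CD3. We model the
  cumulative removal D as a first-order approach,
  `dD/dt = k (D_max - D)` with a saturable plateau
  `D_max = f_max · A_tot' · [AY]'/(K_half + [AY]')`
  (defaults `f_max = 0.8`, `K_half = 200` complexes/cell,
  `k = 1.2e-3 s⁻¹`), so that under constant engagement the trajectory is
  >98% complete by 60 min. This is an explicit empirical stand-in chosen
  to reproduce the known ~1 h plateau of CD3 loss; its constants are
  config fields.
* **CD19 internalization.** The bound CD19–BiTE pool decays at
  0.002 /min. Active in the one-hour base model only; the longer models
  drop it.

### 1.3 Encounter ("step 2")

Free effector cells move by Brownian motion (default
`D = 0.2 µm²/s`); target cells are immotile. The probability that one
effector meets at least one target in a round of Δt = 60 s at target
density C is the diffusion-limited survival against absorbing spheres of
radius `R = r_E + r_T` (defaults 5.5 + 5.0 µm):

    P_e = 1 − exp(−s · C · V(Δt)),   V(Δt) = 4πDR (Δt + 2R √(Δt/(πD)))

At cell scale `DΔt ≲ R²`, so the transient `√t` term dominates and must
not be dropped; the formula as implemented agrees with an explicit
random-walk simulation among absorbing spheres to within Monte-Carlo
error (see the test suite). `s` is a unitless spatial coefficient per
encountering-entity class (free effector = 1 by convention; all classes
default to 1 and a warning is emitted when a scenario file does not set
them). Engaged entities count as single movers. Probabilities are
recomputed every round from current free-entity densities.

### 1.4 Adhesion ("step 3")

A contact lasts 0.1–5 s (uniform; maximum-entropy choice on the stated
range). On the contact patch (default area 1 µm²) ternary CD3–BiTE–CD19
bonds (AYB) form by 2D mass action from either binary complex plus the
opposing free antigen:

    A + YB ⇌ AYB (kon2D_A / koff_A)     AY + B ⇌ AYB (kon2D_B / koff_B)

2D on-rates derive from 3D ones by a single-step model,
`kon2D = kon3D/(N_A σ)` with confinement length σ = 20 nm; off-rates are
unchanged. The five-species surface ODE system (with reactant depletion)
is integrated by fixed-step RK4 from zero bonds; bond counts can never
exceed either side's available partners (a conservation property of the
scheme). Adhesion succeeds with

    P_a = 1 − exp(−α N)

α is the **single calibrated parameter** of the model. It was fitted once
by grid search (shipped utility `synapse_sim.calibrate`) against pooled
in vitro engagement fractions across density and concentration, then
frozen at **α = 0.01**. Everything else is literature-derived or
measured.

Because lower CD19 expression gives fewer bonds and hence lower P_a,
adhesion is the mechanistic filter that drives antigen escape in the
longer models.

## 2. Base model (≤ 1 h)

Round loop (60 s/round): recompute probabilities → each free effector has
one encounter chance against free targets (success: contact + adhesion
test; failure leaves both free) → each existing 2–3-cell entity may
recruit one free cell → receptor updates. Synapses are unbreakable within
the hour and the binding equilibrium is frozen after t = 0. Entities grow
one cell at a time to at most 4 members, labelled ET, ETE, ETT, ETET,
ETEE, ETTT; compositions not reachable from ET by single accretion are
classification errors.

Recruitment is flux-weighted: the entity's encounter rate sums a
free-effector term (relative diffusivity ~2D, both parties move) and a
free-target term (targets immotile), and the recruit's class is drawn in
proportion to those fluxes. This follows from the motility assumptions
and yields the observed slight effector excess in variants.

The simulation runs in a scaled subvolume (default 0.1 µL; several tests
and the acceptance script use 0.2–0.5 µL for tighter statistics), so
densities, never agent counts, drive all rates. Ties (two effectors
hitting one target in a round) resolve first-come in shuffled order under
the round RNG.

## 3. In vitro model (≤ 72 h)

Adds synapse turnover: every entity detaches 150 min after formation; all
its target members are lysed and all effector members return to the free
pool (serial killing; no per-member distinction). The equilibrium is
recalibrated hourly from surviving cells' antigen totals, CD3
downregulation freezes after the first hour, CD19 internalization is off,
and the drug concentration is constant. Mid-lifetime entities may still
recruit up to 4 members. Survivor CD19 snapshots are reconstructed from
the initial distribution minus kills, so bookkeeping closure
(initial = survivors + lysed) is exact by construction.

## 4. In vivo model

Compartments: blood, bone marrow, lymph nodes, spleen, lung, gut,
remainder. Blood is a pure trafficking route and cannot form synapses
(constructor-enforced). A fixed partition repertoire sets each
population's organ fractions; blood holds 2% of lymphocytes. The
remaining fractions and organ volumes are literature-plausible defaults
for a reference human — B cells enriched in marrow, T cells in lymph
nodes — and are fully overridable:

| organ | volume (mL) | B fraction | T fraction |
|---|---|---|---|
| blood | 5000 | 0.02 | 0.02 |
| bone marrow | 1750 | 0.30 | 0.05 |
| lymph nodes | 250 | 0.25 | 0.45 |
| spleen | 200 | 0.15 | 0.20 |
| lung | 1000 | 0.03 | 0.08 |
| gut | 1200 | 0.10 | 0.10 |
| remainder | 30000 | 0.15 | 0.10 |

Hourly loop: dose → per-organ concentration (steady-state plasma =
infusion rate / clearance, default 2 L/h, times a per-organ exposure
scaling, default 1) → per-organ serial-engagement kinetics (60 inner
rounds reusing the in vitro machinery at organ densities) → trafficking →
turnover. Every hour each organ releases 4.17% of its free B cells to the
blood, and the pool is reassigned multinomially by the repertoire;
trafficking alone conserves the B count exactly. B cells grow
exponentially per organ (default rates 0.071 or 0.0071 /day); daughters
inherit the parent's CD19, so selection — not mutation — drives antigen
escape. T cells are exogenous (repertoire densities, optional
patient-specific time multiplier); T-cell death and trafficking are not
modelled.

The whole body is simulated at one density-preserving scale factor
(default ≈4000 B agents system-wide), so organ agent counts are
proportional to real counts and trafficking moves agents directly.
Blood B output is derived from residual systemic B via the repertoire.

Dosing regimens are piecewise-constant weekly infusion rates. The shipped
presets are **synthetic**: scheme 1 high dose follows the approved
blinatumomab pattern (9 µg/day week 1, then 28 µg/day, 4-week-on /
2-week-off cycles), medium/low scale it down, scheme 2 is an
alternating-week variant with lower cumulative dose. They are editable
YAML. Regimen ranking is lexicographic — B-cell killing efficacy, then
survivor-mean CD19 (less escape wins), then total dose — with relative
equivalence tolerances of 10% and 5% at the first two tiers.

## 5. Numerical choices

* RK4 step count 40–60 per contact; when consumption and dissociation are
  both below 2% over a contact, the exact linear-production solution is
  used instead (agrees with RK4 to better than the regime threshold,
  ~20× faster on the hot path).
* Equilibrium solve: Brent bracketing then Newton polish; trivial
  zero-ligand/zero-antigen branches are exact.
* All randomness flows from one seed through named substreams
  (population, contacts, trafficking); per-replicate seeds derive from
  `seed·100003 + replicate`. Identical config + seed is bitwise
  reproducible.
* Per-round membership audits (every engaged cell in exactly one entity,
  entity size 2–4) run in the base/in vitro models and are sampled hourly
  in the organ loop for speed.
* Degenerate inputs: zero dispersion gives delta-distributed expression;
  zero drug short-circuits to an all-free equilibrium; empty entity sets
  summarize to an explicit sentinel rather than raising.

## 6. What the generator emulates — and what it does not

The synthetic populations emulate sorted effector/target subpopulations
with log-normal receptor heterogeneity at measured or plausible means,
co-incubated at controlled densities. They do not emulate: adhesion
molecules as explicit species (assumed uniform), intracellular activation
signalling, killing-efficiency differences between variant types,
directed/chemotactic motion, effector exhaustion or death, or soluble
ternary complexes. Passing tests therefore demonstrate the cellular-scale
encounter/adhesion mechanism under idealised mixing, not a full account
of tissue microenvironments.

## 7. Problem sizes

Default desk-scale runs use 0.1–0.5 µL subvolumes (hundreds to a few
thousand agents), 8–16 replicates for base-model statistics, 72 h in
vitro horizons, and ~4000-agent, 3–7-day in vivo runs with 3–10
replicates. These sizes put every reported statistic within a few percent
Monte-Carlo error of its large-system value while remaining laptop-fast.

## 8. Known limitations

* The CD3-downregulation law is an empirical stand-in with the correct
  plateau behaviour; its constants are exposed but not individually
  identified by the calibration data.
* Organ volumes, partition repertoire, exposure scalings and clearance
  are representative defaults, not fitted patient values; organ-level
  outputs should be read as relative gradients, not absolute predictions.
* Dose-preset amounts for the non-approved arms are synthetic
  placeholders for exploration.
* The blood compartment ignores margination and shear effects entirely
  (it forms no synapses by assumption).
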