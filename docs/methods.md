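# Methods

## Scope of the model

The package models the terminal processing of IgG N-glycans in the Golgi
apparatus.  Synthesis of the oligomannose precursor M5 (ER and cis-Golgi
network) is outside the model: M5 is the boundary condition, entering the
first modelled compartment at a fixed 1000 µM.  Processing is restricted to
the 45 species needed to express the 22 retained chromatographic peaks and
their obligatory intermediates; the full human N-glycosylation rule space
(thousands of structures) is deliberately not enumerated.

## Network construction

Glycans are represented as feature records (mannose count, per-arm antenna
GlcNAc, bisecting GlcNAc, core fucose, per-arm galactose and sialic acid
with a shared α2,3/α2,6 linkage tag), not full trees: the modelled species
set is small enough that these features separate every species, and they
keep the enzyme rules data-driven.

Eight catalytic activities (GnT I, GnT II, GnT III, Man II, FucT, GalT,
SiaT-α2,3, SiaT-α2,6) are encoded as site-specific rules with
required/forbidden feature predicates.  The precedence constraints follow
the established rule set for the mammalian N-glycosylation network:

* Man II requires the GnT I product and removes both outer mannoses in one
  catalytic event; it is blocked by the bisecting GlcNAc.
* GnT II requires the trimmed three-mannose core and is blocked by the
  bisecting GlcNAc and by galactosylation.
* GnT III acts on complex (trimmed) structures and is blocked by
  sialylation; galactosylated substrates are still accepted.
* FucT is blocked by the bisecting GlcNAc and by galactose on the α1,3 arm.
* GalT caps any free antenna; SiaT sialylates any free galactose, with all
  sialic acids of one glycan sharing a linkage.

The network is the breadth-first closure of these rules from M5, restricted
to the 45-species whitelist; with the shipped configuration this closure
produces exactly 61 reactions.  Species are ordered lexicographically by
(total residue count, name) and reactions by (substrate, product, activity),
so builds are deterministic and matrix indices stable.  The same network
can be loaded verbatim from the shipped JSON model file; the test suite
asserts the two paths agree.

**Arm-isomer convention.**  Chromatographic nomenclature does not resolve
which arm carries a single galactose or sialic acid.  The package places a
single galactose on the α1,6 arm of biantennary species (the dominant IgG
isomer) and a single sialic acid on the α1,6-arm galactose; names therefore
collapse arm isomers and the parser returns the canonical one.  Species
with mixed sialyl linkages are outside the modelled set.

**Peak membership.**  The peak table maps each retained peak GP1–GP24
(excluding GP3, contaminated, and GP20, unidentified) to its co-eluting
species.  Anchor assignments: GP4 = {FA2}, GP5 ∋ M5, GP6 = {FA2B},
GP14 = {FA2G2}, GP18 = {A23BG2S1, A26BG2S1, FA23G2S1, FA26G2S1}.  Twelve
processing intermediates (hybrids, mono-antennary species, A2B and the
bisected G1S1 group) belong to no peak; the coverage constraint (below)
keeps their steady-state share small.

## Kinetics and transport

Reaction rates follow competitive Michaelis–Menten kinetics; the
competition sum runs over the substrates of all reactions catalysed by the
same enzyme, including the substrate itself, so a single-substrate enzyme
reduces exactly to kf·U·C/(Km+C).  There are 8 kf values (one per
activity) and 7 Km values (one per enzyme; the two SiaT activities share
one Km) — 15 base kinetic constants — plus 22 kf correction factors
grouped by reaction class, 37 kinetic parameters in total.

The four compartments have equal volumes and a residence time τ = 10 min
each (≈40 min total Golgi transit), so transport is pure concentration
exchange: μ(C) = (C^(k−1) − C)/τ.  Because every reaction converts one
glycan into one glycan, the stoichiometric columns sum to zero and total
glycan concentration at steady state equals 1000 µM in every compartment —
an exact invariant used as a continuous correctness check.

The stoichiometric matrix is oriented species × reactions (45 × 61), with
one −1 (substrate) and one +1 (product) per column, so that
dC/dt = N·v is dimensionally immediate.

**Default parameter values.**  Turnover numbers (kf ∈ 18–6000 min⁻¹),
Michaelis constants (Km ∈ 110–260 µM), enzyme distribution fractions over
the four compartments, and median total concentrations (0.09–0.55 µM) were
fixed once, as literature-plausible magnitudes calibrated so the median
simulation yields a realistic IgG glycogram: FA2/FA2G1/FA2G2 dominant
(~23/25/16%), ~95% core fucosylation, ~10% bisected species, modest
sialylation, and ≥96.5% of total glycan inside the 22 peaks.  Early-acting
enzymes (GnT I, Man II) concentrate in compartments I–II, GalT in III–IV
and SiaT in IV.

## Steady states and the time-switching equivalent

Per compartment the algebraic system N·v(Ĉ) + (inflow − Ĉ)/τ = 0 is solved
by damped Newton iteration with an analytic Jacobian, starting from the
inflow profile; the default convergence criterion is a residual
infinity-norm below 1e−8 µM/min.  Iterates may swing transiently negative
(the line search only keeps competition denominators away from zero); a
converged state must be non-negative, otherwise a stiff long-time
integration (BDF) re-seeds the iteration.  The four compartments are
solved sequentially, each receiving the previous steady state as inflow.

The equivalent time-switching formulation integrates one pool through four
100-min phases, switching enzyme concentrations at each phase boundary and
clamping the transport inflow to the previous phase's end state; the pool
starts as the M5 bolus already inside compartment I.  With τ = 10 min,
100 min is ten e-folding times, so the phase-truncation error is bounded by
≈e⁻¹⁰ of the redistributed mass; the cross-method agreement between the
switching trajectory and the sequential algebraic solution is asserted at
1e−4 relative (the measured agreement is ~7e−6).  This truncation bound,
not the algebraic solver tolerance, is the meaningful comparison scale for
a finite-phase time-course.  Convergence within a phase is measured as the
right-hand-side infinity-norm relative to the 1000 µM input; each phase
falls below 1e−6 by ≈90 min.

## Fitting

The per-subject objective is φ = Σ ω_i (GP_i − GP_i^exp)² with weights
ω_i = min_j(GP_j^exp)/GP_i^exp (the smallest experimental peak has weight
one), plus the coverage penalty ψ = max(0, 0.965 − GP_peaks/GP_all)².  The
penalty weight λ defaults to 1: φ and ψ share a dimensionless scale and no
other weighting is documented for the original procedure; λ is
configurable.  The deviation metric reported across cohorts is the mean of
|GP_sim − GP_exp|/GP_exp in percent — implemented with absolute values so
subject- and peak-level errors cannot cancel.

Personalization fits six totals (GnT I, GnT II, GnT III, GalT, FucT, SiaT)
with Man II held at its common value, inside per-enzyme bounds defaulting
to [0, 1.1] µM (1.1 µM is the documented ceiling of the GnT I search
range; the other ranges are not documented and default to the same span).
Two optimizer modes satisfy the same contract:

* `method="de"` (default): seeded differential evolution — a
  population-based evolutionary search, matching the class of optimizer
  used in the original study — followed by an L-BFGS-B polish.  Used for
  single-subject fits and all recovery experiments.
* `method="local"`: bounded L-BFGS-B warm-started at the population
  medians.  Deterministic and ~6× cheaper; appropriate at cohort scale
  where subjects are moderate perturbations of the medians (the
  200-subject association round trip uses it).

Simulator failures during a search are penalized (objective 1e6), not
fatal; a search in which every candidate fails raises.

The two-stage common-parameter calibration is implemented at configurable,
reduced scale: stage 1 fits kf correction factors jointly with seven totals
(Man II included) per subject and fixes the factors at their population
medians; stage 2 re-fits the five non-literature distribution coefficients
(FucT in compartments I–III, GnT I in I–II), replaces them with medians
(renormalized per enzyme), and fixes the common Man II total at the median
of the stage-1 estimates.  The full-cohort version of this procedure is
research-scale; the shipped defaults and tests run it on a handful of
subjects with a reduced search budget, which recovers the rank structure of
perturbed factors (the absolute level of a factor trades off against the
corresponding enzyme total, so ranks — not magnitudes — are the honest
recovery target at this scale).

## Identifiability

Each fitted parameter is profiled on a log-spaced multiplicative grid
(default five steps per side spanning ×/÷2, clipped at the search bounds)
with the remaining five totals re-optimized per point — locally,
warm-started from the fit optimum, which is adequate around a converged
fit.  A parameter is identifiable if the re-optimized objective rises by at
least 5% (configurable) on both sides, partially identifiable if on one
side only (bound-clipped profiles count as one-sided), unidentifiable
otherwise.  Because noise-free fits reach near-zero objectives, the
relative rise uses an absolute floor (1e−4) in the denominator.  The
classification is monotone in the threshold by construction.

## Sensitivity

Global sensitivity uses the Saltelli two-matrix scheme with (2+k)·N model
evaluations: first-order indices by the Saltelli-2010 estimator
S_j = mean(Y_B·(Y_AB_j − Y_A))/Var(Y) and total-effect indices by the
Jansen estimator ST_j = mean((Y_A − Y_AB_j)²)/(2·Var(Y)).  Inputs vary
uniformly within ±50% of the median totals; outputs with negligible
variance are excluded.  Default sampling is plain seeded uniform; a
scrambled low-discrepancy (`sampler="qmc"`) option reduces estimator error
by roughly an order of magnitude at equal N and is used when verifying the
estimators against analytic oracles (at N = 10⁴ the plain-MC error of the
first-order estimator is ±0.02–0.04 for the linear test function, larger
than the oracle tolerance itself).  Local sensitivity is the forward
finite-difference log-log slope SS = ΔC/Δα · α/C with Δα = 1% of α by
default.

At the shipped median point the total-effect structure mirrors the
biosynthetic roles: GalT dominates GP4, GP6, GP14 and GP18; GnT I dominates
GP5; GnT II GP1; GnT III GP10; SiaT GP23.

## Synthetic cohorts

The generator emulates the structure of island-cohort IgG glycomics data:
ages uniform on [18, 100]; per-enzyme totals log-normal (CV 0.25) around
the model medians; a linear age trend on GalT only (default −0.004 µM/year
about the mid-age point), which is the minimal structure needed to test the
age-inference chain; multiplicative log-normal measurement noise per peak
(default CV 5%, a typical UHPLC area reproducibility scale; chromatographic
areas are positive and roughly constant-CV, hence multiplicative); and
per-subject rescaling of the 22-peak sum to a uniform draw from
[96.5, 99.9]%, the observed coverage range.  Ground-truth totals are
retained alongside the observable table.  Totals are clipped to the search
bounds; a spec whose clipping rate exceeds 1% is rejected as infeasible.

What the generator does **not** emulate: the empirical covariance of real
peak measurements beyond what the model itself induces, age-acquisition
biases, batch effects, or genetic structure.  Passing recovery and
association tests therefore demonstrates the correctness and statistical
power of the inference chain under the model's own assumptions, not
performance on real cohorts.

## Association statistics

Enzyme–age association is simple OLS per enzyme with Bonferroni and
Benjamini–Hochberg adjustment across the family of six fitted enzymes.
Age prediction uses leave-one-subject-out cross-validation of a
single-predictor OLS model; MSE, RMSE and MAE are all reported explicitly
because the squared and root scales of "prediction error" are easy to
conflate.  Experimental-vs-simulated peak comparisons use the two-sided
Mann–Whitney test — exact null up to 20 subjects per group (without ties),
tie-corrected normal approximation above — with BH adjustment across peaks.

## Problem sizes in the shipped tests and acceptance script

Recovery experiments use 3 noise-free subjects and a 30-subject noisy
cohort (test suite) or 12 (acceptance script); the association round trip
uses 200 subjects (tests) or 120 (script) fitted in local mode; model-level
Sobol dominance uses N = 256 with fixed seed (the dominant total-effect
gaps are ~0.8, far above estimator noise at that N); estimator oracles use
N = 10⁴.  Conservation is checked over 100 (tests) or 50 (script) random
parameter draws.  These sizes are the package's chosen desk-scale defaults;
all are arguments, not constants.

## Known limitations

* Fitting six totals cannot reproduce all 22 peaks exactly on real data;
  the original study reports systematic deviations in specific peaks, and
  the same structural limitation applies here.
* Correction factors and enzyme totals are partially confounded
  (kf·U products); the two-stage calibration resolves ranks, not scales,
  at reduced cohort sizes.
* GnT I/II can saturate against their bounds for subjects with extreme
  peak ratios, making them only partially identifiable — the profiling
  stage exists precisely to flag this.
* The peak-membership table and kinetic defaults are package choices
  consistent with the documented anchor assignments, not transcriptions of
  a published appendix; absolute simulated percentages should be read as
  realistic, not as reproductions of any specific cohort.
* No SBML export; the JSON model file is the source of truth.
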