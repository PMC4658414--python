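# Methods

`motordcm` re-implements, as a tested pipeline, an effective-connectivity
analysis of the cortical motor network during metronome-paced sequential
finger tapping, contrasting healthy controls (HC) with pre-symptomatic
(preHD) and early-manifest (earlyHD) carriers of the expanded huntingtin
CAG repeat.  This note documents the models, the defaults and their
rationale, the synthetic-data design, and the numerical choices.

## Task and model inputs

The paradigm crosses sequence complexity (simple `1-2-3-4` vs complex
`4-2-3-1`, right hand, buttons = index/middle/ring/little finger) with
metronome speed (0.5 vs 1.5 Hz), plus auditory rest at both speeds: six
block types of 20 s, each presented five times in a pseudo-randomised
order with no immediate repeats (rejection-sampled uniform shuffles,
seeded).  The scan is 225 volumes at TR = 3 s with the first four
discarded, so the analysed run is 663 s.  Each block is preceded by a 2-s
instruction gap and the run starts with a 3-s lead-in so the schedule
fills the analysed scan exactly; both gaps are parameters, not constants,
because only the scan length and block structure are pinned down.

Three boxcar inputs are sampled on a microtime grid (default dt = TR/16):
`task` (the four tapping block types), `complexity` (complex tapping),
and `speed` (fast tapping).  Inputs are 0/1; mean-centring of the
modulatory columns is available but off by default, because the inputs
describe conditions rather than contrasts.  Whether `speed` should also
be active during rest-fast blocks (clicks present, no movement) is
genuinely open; the default is off, on the argument that speed modulation
of motor couplings expresses movement execution, which rest lacks.

## Network model

Seven regions: pre-SMA (pSMA), caudal SMA (cSMA), left M1 (lM1), left and
right dorsal premotor cortex (lPMd, rPMd), left and right superior
parietal cortex (lSPC, rSPC), with fixed MNI coordinates as metadata.
Neural dynamics are the bilinear one-state form

    dz/dt = (A + Σ_j u_j B_j) z + C u

with `A[i, j]` the coupling from region j to region i (Hz), B the
condition-dependent coupling changes, and C the driving weights.  The
full model's intrinsic structure is 15 reciprocally connected pairs = 30
directed couplings (self-connections are always present and not counted):
pSMA connects with cSMA, both PMd and both SPC; cSMA with lM1 and both
PMd; lM1 with lPMd; PMd and SPC are interconnected within and across
hemispheres; there is deliberately no direct pSMA–lM1 coupling (their
influence is routed via lPMd and cSMA).  Seventeen modulatory couplings
(10 complexity, 7 speed) cover the regions engaged by each manipulation;
the task input drives bilateral SPC only.  The winning (reduced) model
removes every modulatory coupling whose source is rPMd and the complexity
modulations from pSMA to cSMA and bilateral SPC, leaving 10.

The verbal description of the figure-level structure under-determines the
exact edge list; the transcription above was chosen to satisfy the stated
counts (30/17) together with the anatomical constraints, and the counts
are asserted in tests.

## Hemodynamics and integration

Each region's neural state drives a Balloon–Windkessel cascade
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q)
with the canonical deterministic constants κ = 0.64 s⁻¹, γ = 0.32 s⁻¹,
τ = 2 s (per-region, estimable), α = 0.32, E0 = 0.4, V0 = 0.04, and
observation y = V0(k1(1−q) + k2(1−q/v) + k3(1−v)), k1 = 7E0, k2 = 2,
k3 = 2E0 − 0.2.  Integration is fixed-step RK4 with inputs held constant
per microtime bin, implemented as a numba kernel batched over parameter
sets so a finite-difference Jacobian costs one kernel call.  Tests check
the integrator against `scipy.integrate.solve_ivp` at tight tolerance and
assert grid convergence (halving dt changes sampled BOLD by < 1e-3
relative, on grids commensurate with the block edges so only integration
error changes).

A physical limitation matters for data synthesis: at a sustained neural
state below −γ = −0.32 the model's equilibrium inflow is non-positive, so
strong deactivations are unrepresentable.  The simulator raises when a
hemodynamic state becomes non-positive, naming the step.

## Inversion (variational Laplace)

Per-subject estimation is fixed-form Gaussian variational inference:
Gauss–Newton ascent on the free energy with Levenberg–Marquardt damping,
forward-difference sensitivities (step 1e-4), and one iid noise precision
per region updated by EM.  Slow drift is handled by projecting data and
predictions onto the complement of a discrete-cosine set with a 152-s
high-pass cutoff (9 regressors at 221 volumes).  Off-diagonal A, B and C
are estimated in Hz; self-connections as −0.5·exp(θ) and transit times as
2·exp(θ) on log scales with tight priors (variance 1/256), which makes
positive self-coupling unreachable.  Prior variances: 1/64 for
off-diagonal A, 1/16 for B and C.  The A variance is deliberately
tighter than the B/C default: at variance 1/16 roughly a fifth of random
prior draws are unstable at rest (measured over 1000 draws), while 1/64
keeps 99.9% stable, which the simulation guard and the recovery suite
rely on.

Candidate steps are accepted only if the free energy does not decrease,
so the recorded history is non-decreasing by construction; when no
damped step improves the bound, the mode has been reached within
numerical resolution and the fit is reported converged.  `converged =
False` is reserved for hitting the iteration cap while still improving.
Convergence is |ΔF| < tol (default 1e-2) for three consecutive accepted
steps, cap 64 iterations (pipeline default 12 — see below).  Inversion is
deterministic: initialisation at the prior mean, no randomness.

The forward model inside the inversion may run on a coarser microtime
grid than the simulator (pipeline default dt = 1.5 s = TR/2; the
recovery suite uses the matched TR/16 grid).  RK4 at TR/2 is accurate for
these time constants and cuts the Jacobian cost 8-fold; the grid is a
caller-visible option.

Subject-level quality control follows the ≥ 10% variance-explained rule,
requiring convergence as well.

## Post-hoc reduction (Savage–Dickey)

Only the full model is inverted.  For a reduced prior that shrinks
selected parameter variances toward zero (off = variance 1e-8, mean 0,
a numerically proper stand-in for removal), the log-evidence difference
has the closed Gaussian form implemented in `reduction.py` and verified
against 1-D numerical quadrature.  The search is greedy backward
elimination over the modulatory couplings (optionally intrinsic ones),
switching off whichever parameter most increases the evidence until no
removal helps; exact ties favour the simpler model, so a zero-information
posterior prunes everything.  Group-level search pools per-subject
log-evidence differences by summation (fixed effects), which is invariant
to subject order.  For ≤ 10 candidates the greedy winner is within 1 nat
of exhaustive enumeration on linear-Gaussian test problems.

The sparsity-recovery suite simulates subjects whose absent modulatory
couplings are truly zero and whose present ones are ±0.3 Hz, with full
drive and low observation noise, then inverts the full model and searches.
That regime is chosen deliberately: it isolates the search's validity
from estimation noise.  At the cohort's default SNR the limiting factor
is posterior identifiability (couplings into weakly driven regions such
as lM1 are partially confounded), not the search itself.

## Behavioral scoring

Timing inaccuracy is the signed cue–response interval between each
metronome click and the press matched to it (nearest click within half
the inter-click interval; the earlier press wins a contested click).
Block scores are the mean and sample (n−1) SD over matched pairs, on
signed intervals (the magnitude-vs-signed ambiguity in how SDs are
reported is resolved toward signed; accuracy and mistake counting are
unaffected).  Omitted clicks, unmatched presses and wrong buttons each
count one mistake; a block with more than two mistakes is re-scored by
crediting only maximal runs of ≥ 3 presses that follow the cyclic
expected sequence.  A subject is flagged for exclusion below 50%
click-weighted accuracy or when any block was performed as a wrong
condition (< 50% accuracy against the assigned sequence but ≥ 50% against
the alternative; for rest blocks, pressing on at least half the clicks).
The disease burden score is DBS = age × (CAG − 35.5).

## Synthetic cohort

Defaults emulate the study population: 77 HC / 62 preHD / 16 earlyHD;
age, gender, CAG and TIV-adjusted putamen volume drawn from the reported
per-group moments and ranges; site uniform over four centres; education
N(13, 3) years (not reported; an invented default).  Ground-truth
couplings for the winning structure are drawn about baseline means
(off-diagonal A 0.05 Hz, task drive 0.2 Hz, self −0.5 Hz) with
between-subject sd 0.1 Hz, plus the group effect table (Hz):

| modulatory coupling   | HC   | preHD | earlyHD |
|-----------------------|------|-------|---------|
| lSPC→lPMd (complexity)| 0.0  | −0.3  | +0.3    |
| rSPC→pSMA (speed)     | −0.2 | −0.2  | +0.3    |
| cSMA→pSMA (speed)     | 0.0  | 0.0   | −0.4    |

and a planted sub-cluster of 9 preHD whose cSMA→pSMA speed coupling is
shifted +0.4 and lSPC→lPMd complexity coupling −0.4 — the reversed third
sub-group.  Draws are rejected and redrawn unless every input pattern
leaves the system stable with ≥ 0.15 Hz margin and neural steady states
within (−0.22, 1.2); the lower bound reflects the Balloon-model inflow
constraint above, which also caps the baseline drive at 0.2 Hz (larger
drives make the planted −0.7 Hz coupling infeasible).

A latent severity construction links putamen volume to the lSPC→lPMd
coupling: the between-group part of their carrier-wide covariance is
computed analytically from the defaults and the residual within-group
correlation is solved so the total matches the target (−0.302 by
default).  With the default effect table the between-group structure
already accounts for nearly all of it (solved within-group correlation
≈ −0.04); measured over 20 seeds the carrier-wide correlation averages
−0.30.

BOLD is simulated at TR/16 and white observation noise is added per
region at SNR = signal sd / noise sd = 1.0 (spec default), giving ~50%
variance explained at the subject level.  Press logs put one press per
click at click + 50 ms + Gaussian jitter (sd 0.08/0.10/0.15 s for
HC/preHD/earlyHD), correct button with probability 0.97; rest blocks
produce no presses.

What the generator does **not** emulate: scanner drift and physiological
noise spectra (noise is white; the 152-s high-pass in the inversion is
therefore exercised but not stressed), head motion, hemodynamic
variability across subjects (hemodynamics are fixed at the canonical
constants; the inversion still estimates transit times), regional
timing/slice differences, and behavioral lapses beyond button errors.
Passing tests therefore show the estimator and statistics are correct
and calibrated under the model's own assumptions, not that they are
robust to structured fMRI artefacts.

## Group statistics and clustering

Connection-wise inference is an OLS ANCOVA: group dummies plus age and
education (continuous) and gender and site (categorical dummies), with
the group effect tested by extra sum of squares; the family-wise level is
Bonferroni over the 47 couplings (exact quotient 0.05/47 ≈ 0.00106 by
default; the rounded 0.001 is available by passing the level directly).
Significant connections get three pairwise contrasts on the pooled ANCOVA
residual error (Welch on raw values as a flag), Bonferroni ×3.  Pearson
partial correlations residualise both variables on the covariates;
p-values use the t transform with df = n − 2 − k.  Monte-Carlo null
calibration of the ANCOVA (1000 replicates, n = 150) keeps the type-I
rate within (0.03, 0.07) at nominal 0.05.

Clustering of carrier coupling estimates is Ward linkage with squared
Euclidean proximity (via `scipy.cluster.hierarchy`), reported as an
agglomeration schedule whose coefficient is the cumulative total
within-cluster sum of squares (first merge of singletons a, b contributes
d²(a,b)/2); a brute-force O(n³) recomputation is the test oracle.
Features are the free intrinsic + modulatory couplings, unstandardised by
default.  The cluster count is chosen from the schedule by the scree
rule: reading from many clusters toward few, pick the largest k whose
merge shows a sustained run of marked jumps in the coefficient increments
(every increment ratio from k down to 2 ≥ 1.8).  Sustainment matters: an
isolated noise jump qualifies under a single-jump rule, while merges of
genuinely distinct clusters stay expensive all the way to k = 1.  When no
candidate qualifies — uniform data need not have an elbow — the argmax is
returned with a low-confidence flag.  On the default carrier ground
truth this selects k = 3 and recovers the planted sub-group structure
with adjusted Rand ≥ 0.9.

## Pipeline and reproducibility

`run_pipeline` chains synthesize-or-load → behavioral screening →
inversion → QC → optional group-level reduction → connection-wise ANCOVA
with post-hocs → carrier clustering → putamen partial correlations, and
writes a manifest (seed, option and input hashes, versions, per-stage
counts).  All randomness flows from one seed through named sub-streams;
identical configurations reproduce output tables byte for byte.  The
pipeline defaults (inversion grid TR/2, iteration cap 12, scaled cohort
sizes in the test suite) are sized so a full scaled run completes in a
few minutes on one CPU; caps and grids are ordinary options for larger
runs.

## Known limitations

* Parameter recovery at the default SNR is information-limited: the
  posterior is calibrated (z-scored errors have sd ≈ 1), but intrinsic
  couplings retain posterior sds comparable to the between-subject spread,
  capping the pooled true-vs-estimate correlation near 0.75 (modulatory
  block ≈ 0.82, driving ≈ 0.9).  This is a property of the design
  (221 volumes, inputs entering via SPC only), not of the estimator.
* The reduction search inherits any posterior confounding; couplings into
  weakly driven regions can be mis-pruned at low SNR.
* Deterministic one-state bilinear DCM only; no stochastic, two-state or
  nonlinear variants, and no hierarchical (empirical Bayes) group
  inversion.
* The elbow rule's threshold (1.8) is a heuristic; it was chosen on
  constructed scenario batteries and is exposed as a parameter.
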