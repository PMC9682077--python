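# Methods

`catabarrier` is a quantitative-systems-pharmacology pipeline that links
daily medication doses to a clinical catatonia severity score (the
Bush-Francis Catatonia Rating Scale, BFCRS, an item-sum instrument on
0–69) through a mechanistic model of cortical bistability.  This note
records the model, the constants, the numerical choices, and the places
where the design was genuinely open.

## 1. Cortical circuit model

Two coupled rate equations describe an inhibitory population `x0`
(parvalbumin-positive interneurons) and an excitatory population `x1`
(pyramidal cells), both expressed as fractions of maximal rate:

    dx0/dt = -x0 + S0(w01*x1 - w00*x0)
    dx1/dt = -x1 + S1(w11*x1 - w10*x0)

with the rest-normalized logistic rate function

    Sa(x) = 1/(1 + exp(-mu_a*(x - theta_a))) - 1/(1 + exp(mu_a*theta_a)).

Weight indices are postsynaptic-first: `w01` is the excitatory drive onto
the inhibitory population, `w00` the inhibitory self-coupling, and so on.
The rest term makes `S(0) = 0`, so the quiescent state (0, 0) is an exact
fixed point — the ground state of the circuit.  The baseline parameter set

    mu0=1.0, mu1=1.2, theta0=4.0, theta1=2.8,
    w00=9, w01=13, w10=4, w11=8.65

places the circuit in a bistable regime with three fixed points: the
quiescent attractor at the origin, a high-rate attractor at
(x0, x1) = (0.713, 0.878), and a saddle at (0.311, 0.468) whose stable
manifold separates the basins.  Catatonia is modeled as over-persistence
of the high-rate state: symptoms such as posturing and perseveration
correspond to the circuit being stuck in sustained activity, and clinical
improvement corresponds to easier escape into the quiescent state.

A note on the sign convention: the defining feature of this regime — a
zero-rate ground state, a high-rate attractor near 0.9, and an
intermediate saddle — is obtained only with inhibition entering the
drive negatively and with the rest-normalized rate function.  We surveyed
the alternative formulations (plain logistic, refractory `(1-x)` factor,
presynaptic-first indexing, all sign patterns) and none reproduces this
geometry; the plain logistic comes closest but puts the high-rate
attractor at 0.93 and the low state off zero.  The saddle of the chosen
formulation sits at x1 = 0.468 rather than the nominal ~0.4 sometimes
quoted for this parameter set; no formulation in the survey places the
saddle at 0.4 while keeping the high state near 0.85–0.9.

### Barrier statistic

The escape difficulty of the high-rate state is summarized by a scalar
barrier `B`: the cumulative sum of `dx1/dt` over a lattice of `n` evenly
spaced `x1` values on the x0-nullcline from the high-rate fixed point to
the saddle — the discrete line integral of the excitatory rate gradient,
i.e. the depth of the high-rate well of the effective one-dimensional
potential along the nullcline.  We scale the sum by `100/n` so the value
is stable under lattice refinement and coincides with the plain 100-point
sum at the default resolution (`B = 3.543` at baseline; refinement from
100 to 10 000 points moves it by 1.0%).  `B` is validated as an escape
proxy in two independent ways: it rank-correlates (Spearman ≥ 0.9,
observed 1.0) with the minimal instantaneous kick that escapes the basin
under noiseless dynamics, and stochastic simulations show shorter dwell
times in the high-rate state when `B` is reduced.

### Numerics

* x0-nullcline: `x0 = S0(w01*x1 - w00*x0)` has a unique root in `x0`
  (the right side is strictly decreasing); vectorized bisection on
  [0, 1.5] drives residuals below 1e-8.
* Fixed points: every fixed point lies on the x0-nullcline, so we scan
  `dx1/dt` along it (512-point grid) for sign changes and refine each
  bracket by damped 2-D Newton with the analytic Jacobian (fallback:
  Brent on the nullcline).  Duplicates are merged at 1e-4.  The result is
  verified in tests against an independent 15x15 multi-start `fsolve`
  search.  Classification uses the Jacobian eigenvalues (both real parts
  negative = stable; opposite signs = saddle).
* Stochastic simulation: forward Euler at `dt = 0.1` with an independent
  Gaussian kick (default SD 0.19) added to each population per step, as a
  per-step perturbation rather than a `sqrt(dt)`-scaled Wiener increment;
  `dt` is therefore part of the noise model and is held fixed.  Rates are
  clipped to [0, 1].  A "transition" is declared when `x1` stays below
  0.2 (well under the saddle) for 10 consecutive steps.

## 2. Pharmacokinetics

Doses are converted to average CSF concentrations with linear,
steady-state kinetics:

    C_ave [nM] = F*D / (CL*tau) * Kp / M * 1e6

F bioavailability (fraction), D daily dose (mg), CL volume-normalized
clearance (L/hr), tau = 24 h dose interval, Kp brain(CSF)/blood transfer
ratio, M molecular weight (g/mol).  Clearance is read as L/hr — the only
dimensionally consistent interpretation that yields a concentration.
Registry defaults (all overridable from YAML/JSON):

| drug        | F    | CL (L/hr) | Kp   | M      | note |
|-------------|------|-----------|------|--------|------|
| clozapine   | 0.55 | 30        | 0.03 | 326.82 | Kp = free CSF fraction (~97% protein bound) |
| olanzapine  | 0.60 | 25        | 0.07 | 312.44 | ~93% protein bound |
| lamotrigine | 0.98 | 2.5       | 1.0  | 256.09 | CSF ~ plasma |
| lorazepam   | 0.90 | 4.0       | 0.15 | 321.16 | ~91% bound |
| clonazepam  | 0.90 | 4.5       | 0.15 | 315.71 | ~85% bound |

The benzodiazepine occupancy law uses ng per gram of tissue; 1 nM of a
compound with molecular weight M is M/1000 ng/g at unit tissue density.

## 3. Drug -> parameter coupling

Each mechanism yields a multiplicative transform of the parameter vector;
multi-drug effects compose as elementwise products (hence commute), and
the composed raw transform `p_raw` is blended with baseline through the
medication response factor `a`:

    p' = p0 + a*(p_raw - p0),      a = 0.35 (population default).

Scaling the *change* (rather than multiplying all parameters by `a`)
keeps the system bistable over the clinical dose range, which is the
stated purpose of the response factor.  Any multiplicative factor is
floored at 0.05 with a warning to prevent sign flips at absurd doses, and
a regime guard (on by default) raises `RegimeError` if a regimen
destroys bistability.

* **Lamotrigine** (CSF concentration C in uM): three pyramidal-cell
  mechanisms.  Na+ block `dI_Na = 1 - (C/(C+K_C))^n` with K_C = 513 uM,
  n = 0.9; Ih shift `dx1 = max(0, 1 - 0.004*C)`; glutamate release
  `dG = max(0, 1 - 0.004*C)`.  Each enters through an effect
  `E = 1 - p_lam*(1 - delta)` with p_lam = 0.15: the two excitability
  effects raise `theta1` by `1/E`, the release effect scales `w11` and
  `w10` by `E_glu`.  The linear laws clamp at C = 250 uM, where
  `E = 0.85` exactly.  The 0.004 slopes are interpreted per uM.
* **Benzodiazepines** (C in ng/g): GABA-A site occupancy
  `R = C^A/(C^A + B_half)` with A = 1.4328 and B_half = 73.89 for
  lorazepam (half occupancy at 20.1 ng/g); clonazepam, clinically about
  twice as potent, uses B_half = 36.9.  Occupancy scales the inhibitory
  synaptic weights: `w00, w01 -> (1+R)`.
* **Antipsychotics** (C in nM): competitive antagonism of endogenous
  transmitters at D1, D2, 5-HT1A, 5-HT2A and M1.  The endogenous
  occupancy under competition is the exact real root of the two-ligand
  equilibrium cubic (total receptor normalized to 1 nM), cross-checked
  against a bisection equilibrium solver to 1e-6.  The control occupancy
  `R_con` is the same quantity at zero drug.  With
  `dr = (R_oc - R_con)/R_con`, the per-receptor couplings are:
  D1: `mu1, theta0 -> (1-dr)`, `w11, w10, w01 -> (1+dr)`;
  D2: `w11, w10 -> (1-dr)`, `mu1 -> (1+dr)`;
  5-HT1A: `theta1 -> (1+dr)`; 5-HT2A and M1: `theta1 -> (1-dr)`.
  Antagonism gives `R_oc < R_con`, flipping each activation effect.

Endogenous tone (nM): dopamine 37 tonic / 200 burst, serotonin 3.9,
acetylcholine 10.  D1 effects are evaluated against burst tone (phasic
signaling) and D2 against tonic tone (sustained signaling).  Endogenous
affinities (nM): DA–D1 1000, DA–D2 25, 5-HT–5-HT1A 4, 5-HT–5-HT2A 200,
ACh–M1 300.

The drug constants `K_B` in the registry are *effective potency
constants* for the receptor-level modulation, not raw binding Ki.  Raw Ki
values (clozapine M1 ~ 2 nM) against clinical CSF concentrations of tens
of nM saturate the relative deviation `dr -> -1`, which under the
couplings above would double `theta1` and destroy bistability — behavior
incompatible with the modest, near-linear dose responses this model is
built to produce.  The defaults (clozapine: D1 10000, D2 8000, 5-HT1A
12000, 5-HT2A 3000, M1 2000; olanzapine: D1 8000, D2 1200, 5-HT2A 2200,
M1 4000, no appreciable 5-HT1A) therefore sit on the uM scale of
functional modulation while preserving the qualitative ordering:
clozapine is the stronger antimuscarinic/anti-5-HT2A agent (hence the
larger `theta1` shift and barrier reduction), olanzapine relatively
D2-weighted.  At clinical doses every receptor operates in the shallow,
near-linear part of the competition curve.

With these defaults the single-drug barrier reductions at representative
post-treatment doses are roughly: benzodiazepine 0.4–0.6, lamotrigine
0.3, clozapine 0.2, olanzapine 0.05 (baseline B = 3.543), and all five
dose-response curves are linear to r^2 >= 0.98 over their clinical
ranges.  The three-drug combination is additive within ~1%, because the
mechanisms act on disjoint or weakly interacting parameters in a regime
where B responds near-linearly.

## 4. Synthetic cohort

The generator emulates the statistical shape of a residential cohort:
polypharmacy on admission narrowing to a fixed three-class protocol
(clozapine or olanzapine + lamotrigine + one benzodiazepine), severity
17.3 +- 3.9 before and ~4 after treatment, per-subject improvement
confined to [9, 23] BFCRS points.  A Gaussian copula (hand-built on
scipy: Cholesky factor, latent normals, marginal quantile transforms)
couples twelve variables: five dose-presence latents, five dose-value
latents, severity, and improvement.

Design choices that matter:

* **Presence and value are separate latents.**  Regimen-structure filters
  (exactly one antipsychotic, exactly one benzodiazepine, ...) condition
  the presence latents; keeping those independent of severity prevents
  the filters from distorting the retained score distribution.
* **Improvement, not the post score, is a copula variable**, with a
  truncated-normal marginal directly on the [9, 23] window (mean 12.5,
  SD 3.4 before truncation); `post = pre - reduction`.  This builds the
  observed improvement window into the sampler instead of imposing it by
  rejection, which would shrink the retained variances and inflate the
  effect size.
* **Correlations** (latent scale): severity–dose 0.3 (sicker patients
  receive higher doses), severity–improvement 0.25, improvement–dose 0.3
  (higher doses produce larger improvements through the same response
  factor — this is also what decorrelates the two personalization
  parameters downstream).
* **Dose marginals are deliberately wide** (e.g. clozapine N(350, 280)
  mg, rounded to 25 mg formulary steps) so that a realistic fraction of
  raw draws is clinically implausible; plausibility filters then cut the
  raw pool of 700 to a retained cohort with median near 58 across seeds.
* **Filters** (all counted in a rejection report): exactly one
  antipsychotic post, exactly one benzodiazepine post, lamotrigine
  present, all post doses inside clinical ranges, improvement inside the
  window, no clozapine before admission (the protocol introduces it), and
  treatment intensification (catatonia-directed doses never decrease
  pre -> post; benzodiazepine load compared in lorazepam-equivalents,
  clonazepam ~ 2x).  The last two rules encode the clinical narrative and
  also guarantee that the modeled pharmacology reduces the barrier for
  every retained subject.
* **Outcome assignment** rounds scores to integers; where rounding breaks
  the window or the 0–69 instrument range, the improvement is resampled
  conditionally on the subject's severity (falling back to redrawing the
  pair only when the severity admits no valid improvement).  Resampling
  only the improvement leaves the retained severity distribution
  unbiased.
* Pre-treatment regimens add 2–6 uncoupled medications from a named pool
  (haloperidol, valproate, sertraline, ...) plus occasional modeled drugs
  at modest doses; uncoupled drugs carry placeholder PK records and do
  not touch model parameters.

What the generator does *not* emulate: item-level BFCRS structure,
longitudinal titration, adherence, dropout, or any estimate of a real
cohort's joint distribution — the marginals and correlations are
documented stand-ins chosen to reproduce printed summary statistics, so
passing cohort-level tests demonstrates internal consistency of the
pipeline, not fidelity to any patient population.

## 5. Cohort statistics

* **Effect size**: difference in group means divided by
  `sqrt(s1^2 + s2^2)`.  This convention jointly reproduces the clinical
  summary pattern the generator targets (means 17.3/4.1 with SDs 3.9/2.8
  giving d ~ 2.7; mean barrier reduction 0.80 with effect size ~ 2.14),
  which the pooled-SD convention does not (it gives 3.9); Cohen's
  pooled-SD `d` is available via `sd_mode="pooled"`.  p-values from
  one-way ANOVA.
* **Severity map**: the affine map `BFCRS = slope*B + intercept` through
  the two population mean points (mean barrier, mean BFCRS) pre and post;
  it reproduces the two means exactly by construction.
* **Regressions**: squared Pearson correlation, either pooling the pre
  and post points of every subject (2n pairs) or on per-subject changes;
  both modes are exposed because the pooled and change-score correlations
  answer different questions (population-level association vs individual
  prediction).
* **Dose-response**: 12 evenly spaced doses per drug over the registry's
  clinical range, each evaluated drug-alone on baseline parameters, with
  an ordinary least-squares line and r^2.
* **Combinations**: all 2^k subsets of up to five (drug, dose) pairs,
  with barrier change per subset and optional mapped-BFCRS prediction.

## 6. Personalization

Two per-subject parameters: `w00_factor` in [0.8, 1.2] multiplying the
baseline inhibitory self-coupling (intrinsic barrier height, i.e.
admission severity) and an individual response factor `a_i` in (0, 1]
replacing the population a = 0.35 (dose sensitivity).  The calibration
minimizes squared error on the clinical scale,

    J(w, a_i) = sum over epochs ( map(B_epoch(w, a_i)) - BFCRS_epoch )^2,

by a 7x6 bounded grid plus Nelder-Mead polish (objective tolerance 1e-4),
always compared against the population default (1.0, 0.35) so the
calibrated objective never exceeds the default's.  Non-bistable parameter
combinations receive a large penalty; a subject with no bistable point in
the bounds raises `CalibrationFailure`.  With two observations and two
monotone parameters the fit is typically exact (objective ~ 0), so the
personalized change-score and pooled correlations sit at or near r^2 = 1
depending on how often the bounds bind; the model's two parameters are
exactly identified by a subject's two scores.  Tuning the excitatory
drive `w01` instead of `w00` is implemented nowhere: exploratory attempts
at that parameterization are reported as unresolved in the source
literature of this model class, and we keep the single well-identified
pair.

Parameter recovery (forward-simulating subjects from known personal
parameters and re-calibrating) recovers both parameters with median
error well under 10% of the bound widths, and the recovered parameters
across a default cohort are mutually uncorrelated (cross r^2 < 0.1).

## 7. Problem sizes and determinism

Default sizes used throughout the tests and the reproduction script: 700
raw subjects per cohort (retained ~58), 100-point barrier lattice
(10 000 for refinement checks), 12-dose response grids, 300–1000-point
random grids for the occupancy oracle, 20–40 seeds for stochastic
simulation checks.  One integer seed drives every stochastic stage
through `numpy.random.SeedSequence` spawning, so cohorts are reproducible
to the byte; model-side quantities (fixed points, barriers, dose
responses) are fully deterministic.

## 8. Known limitations

* The two-population model has no striatal/thalamic circuitry; all
  pharmacology funnels into eight cortical parameters.
* Average-concentration PK ignores dosing schedule, nonlinear clearance,
  and drug-drug interactions; all coupling constants are population
  values except the two personalized parameters.
* The saddle of the chosen formulation sits at x1 = 0.468 (see §1);
  quantities that depend only on barrier *differences* are insensitive to
  this, but the saddle coordinate itself differs from the ~0.4 nominal
  value.
* The synthetic cohort is a statistical stand-in; effect sizes and
  correlations computed on it validate the pipeline's mechanics, not
  clinical performance.
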