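# Methods

This note documents the model, the numerical choices and the synthetic
data underlying `hepg1s`, in enough detail to judge what a passing test
suite does and does not demonstrate.

## Model structure

### Input layer

Receptor-level and MAPK/PI3K kinetics are deliberately replaced by an
algebraic layer mapping HGF dose to activities in [0, 1] of five nodes:
Akt, ERK, GSK3β, a lumped transcription-factor node TF (AP-1/Myc/p53)
and p53. Dose dependence is hyperbolic (Michaelis-type) by default, with
a Hill-exponent variant available in the configuration; the hyperbolic
default reflects the smooth pAkt dose response such layers are built on.
AND gates are realized as products of activities — smooth, differentiable
and exact at the {0,1} corners of the logic they encode. GSK3β is the
complement of Akt (pure inhibitory edge). p53 follows TF by default and
is configurable; it is carried as a separate node because p21 induction
by E2F-1 requires p53 as co-factor. Inputs are not compartmentalized:
the same activity acts in cytoplasm and nucleus.

Parameters, with defaults: basal activities `alpha_akt` = 0.25 and
`alpha_erk` = 0.15 (dimensionless, fixed from inhibitor-controlled
measurements through the background-corrected fraction
(basal − inhibited)/(stimulated − inhibited)); half-saturation doses
`k_akt` = 3 ng/ml and `k_erk` = 8 ng/ml; basal TF activity
`tf_basal` = 0.05. The free input parameters are
{`k_akt`, `k_erk`, `tf_basal`}.

### Dynamic layer

The rule set tracks six molecular units across cytoplasm and nucleus —
the lumped Cyclin D1:CDK4 unit (free Cyclin D1, free CDK4 and the
p21-assembled complex are not distinguished, and p21 does not impair CDK4
activity), Cyclin E, CDK2 with its T160 site, p21, Rb with a CDK4-class
site (S788) and a CDK2-class site (S800/S804), and E2F-1 — plus the DNA
content state. Core mechanisms: p21 is both assembly/import factor and
(for CDK2) catalytic inhibitor; CAK acts only on nuclear, p21-free
Cyclin E:CDK2 (CAK itself is constitutive and implicit); Rb is
phosphorylated sequentially (CDK4-class site first, then by active
pCDK2 T160), binds E2F-1 in its hypo- and mono-phosphorylated forms and
releases it upon full phosphorylation; E2F-1 auto-amplifies its own
synthesis gated by TF; Rb:E2F-1 complexes turn over slowly (binding
stabilizes the complex — the stabilization is assigned to the complex as
a unit, one of two readings of the underlying observation, and is
configurable by editing the degradation rules). DNA synthesis is the AND
of free nuclear E2F-1 and active pCDK2 T160 with a hard capacity bound:
dDNA/dt = k·[E2F-1]·[pCDK2]·(2 − DNA), which confines DNA to [1, 2] for
any non-negative parameters.

One rule carries an input factor beyond synthesis: nuclear p21 release
from unphosphorylated Cyclin E:CDK2 scales with Akt·ERK activity,
encoding signaling-dependent p21 phosphorylation that controls its CDK
binding. This makes T160 accessibility — and with it pCDK2 — demand
strong pathway activation, and is the structural origin of the
right-shifted pCDK2 dose response in the reference parameterization.

### Expansion and counts

Rules are patterns; expansion applies every rule to the growing species
set until closure, with canonical (sorted) species naming so generation
is reproducible. Binding rules also match existing complexes (e.g. ones
that arrived by import) and generate their dissociation channels. A
configurable species cap (200) turns unbounded polymerization into an
error. The default rule set expands to 24 dynamic species, 69 reactions
and 55 distinct kinetic parameters: rate constants are per-reaction
except that (i) the four Rb-S788 phosphorylation reactions share two
constants (free vs p21-bound CDK4 complexes are equally active, so only
the substrate context differentiates the rate), and (ii) the 23
degradation reactions share 11 constants (a complex degrades as a unit
at the rate of its dominant constituent; Rb:E2F-1 complexes and nuclear
pools of p21/E2F-1 have their own constants). Rate laws are mass action
with input activities as multiplicative factors (zeroth-order synthesis,
linear-in-activator catalysis); Michaelis variants are a deliberate
non-default.

### Observables

Nine protein observables are scaling parameter × sum of matching species
(totals sum every species containing the molecule; phospho-observables
every species carrying the site); DNA content is the state itself,
scale-free, equal to 1 at stimulation by construction. Free parameters:
45 of 55 kinetic constants (held fixed: the constitutive CAK step,
Cyclin E–CDK2 affinity, CDK2 turnover, the fast E2F-1 release, p21
export, and the p21-bound T160/E2F-bound Rb dephosphorylation rates,
which mirror their measurable counterparts), 4 of 9 scaling parameters
(the co-IP observables whose calibrator-derived scale is least certain),
and 3 input parameters — 52 in total, estimated in log10 space over
±6 decades (12 orders of magnitude) unless a parameter carries narrower
physiological bounds (`k_akt`, `k_erk`, `tf_basal`).

## Simulation

`scipy.integrate.solve_ivp` with LSODA (stiff-capable), default
tolerances rtol 1e−6 / atol 1e−9, integration restarted at every
protocol event (stimulation, washout) with inputs piecewise-constant per
segment. On failure the segment retries with BDF at 100× tighter
tolerance; during parameter estimation the retry is disabled and a
budget on right-hand-side evaluations (default 50 000 per simulation)
bounds the cost of pathological parameter regions, which then report an
infinite-objective equivalent (large finite residuals) rather than
aborting a run. Initial conditions: all protein species 0 at plating,
DNA = 1; the basal input activities drive the growth-factor-independent
pre-stimulation rise. Washout sets HGF to 0 with instantaneous
relaxation of Akt/ERK to basal (ideal receptor shut-off); PD0332991
multiplies the CDK4-catalyzed Rb phosphorylation rates by 0 (complete
inhibition; partial factors can be passed as clamps). Trajectories are
clipped at 0 post hoc; violations beyond solver tolerance warn.

The SBML interface writes Level 3 Version 2 with MathML product kinetic
laws, input activities as placeholder parameters and the DNA capacity
factor inline; the reader inverts exactly this subset, giving a
round-trip that reproduces trajectories to solver precision. It is not a
general SBML consumer.

## Data processing

Calibrator correction divides each intensity by its replicate's spiked
recombinant-calibrator signal. Scaling/merging alternates a cubic
smoothing-spline consensus (penalty parameter on a normalized [0, 1]
scale, default 0.5, i.e. λ = (1 − p)/p = 1 in
`make_smoothing_spline`; duplicate abscissae are merged with weights)
with per-replicate least-squares scale factors, normalized to geometric
mean 1, until scales move by less than 1e−6 (max 50 iterations) — the
estimator itself is this package's choice; exact numerical equivalence
with any particular legacy spline tool is not promised, only shape-level
agreement, which the closed-loop tests verify. Merged means carry an SD
only where ≥ 3 replicates contribute. The linear error model is the
through-origin regression slope Σ(mean·SD)/Σ(mean²), fit per observable
(a pooled variant is a one-line change); DNA-content data use a constant
error model (average SD over the data set). SEM = mean·relative_error/√n
(linear) or sd/√n (constant). Normalization: protein observables to
overall mean 1; DNA anchored to 1 at the stimulation time.

## Calibration

χ² = Σ((model − mean)/SEM)², points with SEM = 0 excluded with a
warning. Multi-start estimation perturbs every start by
p·10^(s·ε), s = 1.5, clipped to bounds, and runs
`scipy.optimize.least_squares` (trf) in log10 space with ftol = xtol =
1e−5 ("χ² tolerance" and "fit parameter tolerance" both read as the
corresponding scipy convergence tolerances) and an iteration budget of
300 (implemented as max_nfev = 300·(n_free + 1)). Results sort by χ²
with ties broken by start index; the best ten form the ensemble, whose
per-parameter log10 median and 10/25/75/90th percentiles summarize
identifiability (no profile likelihoods). The production profile is
1000 starts (the run count is configuration, not a constant); tests and
examples use 8–20 starts with a reduced free mask of 4 parameters — a
scaled-down recovery study sized so the suite completes quickly, with
simulation tolerances relaxed to rtol 1e−5 during fitting.

## Analyses

Control coefficients use the two-sided finite-difference formula at
f = 0.9 and 1.1 with DNA content at 72 h as the readout, mapped over the
ensemble; ranking filters by sign per context (parameters whose increase
raises basal synthesis; parameters whose increase lowers stimulated
synthesis) and reports the top 16 by |median|. Dose–response curves use
the maximal observable value over a 72-h post-stimulation window by
default (the 72-h point value is the alternative definition, used where
a direct comparison with the two-input surfaces is wanted); the EC50 is
the monotone piecewise-linear (log-dose) interpolation of the crossing
of min + (max − min)/2 — evaluation of the simulated curve, not a
refit — with flat curves (range < 1% of baseline) flagged undefined. A
Hill-refit pathway exists for parity with experimental data. Response
surfaces clamp two input nodes on a grid, simulate to 72 h and carry the
basal point and the HGF dose path, so the surface restricted to the path
equals the one-dimensional dose response. Four-parameter Hill fits
(base + amp·xⁿ/(kⁿ + xⁿ)) run five multi-starts over the inflection
and slope (the 4PL objective has well-known local minima); the
inflection's standard error comes from the Gauss–Newton covariance via
the delta method. The component-vs-proliferation regression is OLS per
component with two-sided slope p-values and Bonferroni adjustment
min(1, m·p), m defaulting to the number of components tested.

## Synthetic data

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment.

* **Blot-like time courses**: per-replicate multiplicative scale factors,
  log-normal with median 1 and log10-SD 0.3 (the spread is a package
  choice — real inter-gel spread is rarely reported — and is flagged in
  the configuration), signal-proportional noise
  intensity = scale·y(t)·(1 + cv·ε) with default cv 0.1, and a
  spiked-calibrator column with its own log-normal scale.
* **DNA-content assays**: additive Gaussian noise, default SD 0.06, on
  the DNA state normalized to 1 at stimulation.
* **Dose–response tables**: one readout per dose/observable/replicate at
  48 h post-stimulation (default), blot-like noise.
* **Single-cell tracks**: 15-min sampling for 60 h from stimulation.
  Each cell responds with probability given by a four-parameter Hill
  curve in dose (default: baseline 0, amplitude 0.92, EC50 16 ng/ml,
  slope 2 — a ~92% ceiling of competent cells). Responders traverse
  G1 → G1/S → S/G2/M → early G1 with truncated-normal dwell times
  (G1 onset 30 ± 6 h, G1/S 3 ± 1 h, S/G2/M 12 ± 2 h; all truncated at
  four sampling intervals so a genuine transition always satisfies the
  4+4 caller, and onsets are clipped so the excursion fits the track).
  The onset and G1/S dwell defaults put the mean transition time near
  33 h after stimulation. Non-responders idle in G1 with occasional
  abortive G1/S excursions (10% of cells, 1.5 ± 0.5 h) that return to G1
  without entering S/G2/M. Channel intensities are high/low means
  (RFP 100/10, YFP 80/8) plus Gaussian noise (SD 4), and only one
  daughter is followed after division (no re-entry).

A single integer seed drives all sub-generators through spawned
independent streams.

What the generator does **not** emulate: image-level artifacts
(segmentation error, background drift, focus loss), correlated noise
across time points within a gel, replicate-specific time offsets,
cell-cycle re-entry and lineage structure, cell death, and outliers.
Passing closed-loop tests therefore demonstrate that the pipeline's
estimators are consistent under the stated noise model at realistic
sizes — not that they are robust to every failure mode of real imaging
or blotting data.

## Single-cell statistics

Quadrant thresholds come from the unstimulated reference condition: the
5th percentile of its RFP distribution and the 97.5th of its YFP
distribution (package defaults, chosen so a quiescent reference
classifies ≥ 90% G1 under independent channel noise). Ties classify as
"high" on both axes. Events cannot be called in a track's first four
samples (insufficient history), and the manual false-negative curation
step of interactive workflows is replaced by an optional single-gap
tolerance that is off by default — irreproducible curation is out of
scope. Snapshot fractions pool all (cell, time) points in the 42–54 h
post-stimulation window; the S/G2/M percentage feeds the
cycling-fraction dose–response fit. Field-level quality control keeps
imaging positions with 10–50 seeded and ≥ 5 infected nuclei (bounds
inclusive). Thresholds are derived per experiment from its matched
unstimulated control.

## Reference parameterization

The shipped defaults (units: hours and arbitrary concentration units of
order 1) are a reference state chosen once to reproduce the qualitative
physiology the package is organized around: DNA pinned at 1 without
stimulation (1.0003 at 72 h), DNA approaching 2 within 48 h of a
saturating dose (1.91 at 40 ng/ml, 1.99 at 400), growth-factor-
independent accumulation of G1/S components during depletion, and
pCDK2 T160 as the protein observable with the highest HGF EC50, with the
DNA EC50 within a factor 3 of it. They are simultaneously the ground
truth of the synthetic-data module, so every recovery test reports
errors against a known answer.

## Problem sizes and limitations

Test and example workloads are sized for quick iteration: 20-start
recovery fits over a 4-parameter free mask, 13-point time grids, 12–16
point dose grids, 100–200 cells per dose and ~100-repeat Monte-Carlo
loops; the same code paths scale to the production profile (52 free
parameters, 1000 starts) unchanged. Known limitations: no stochastic
(SSA) simulation and no mechanistic S/G2/M phase; the input layer is
algebraic, so pathway dynamics (adaptation, pulsing) are invisible;
identifiability is summarized by ensemble spread rather than profile
likelihood; EC50s from the default max-over-window response are not
comparable across response definitions; and the 52-parameter production
fit is computationally heavy — expect hours, not the minutes of the
scaled-down profile.
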