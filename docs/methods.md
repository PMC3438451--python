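# Methods

This note documents the models, algorithms and numerical choices behind
`gaindcm`, in the spirit of a model-description appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic studies do and do not demonstrate.

## The scientific question

Predictive-coding accounts of perception hold that superficial
pyramidal (sp) cells broadcast precision-weighted prediction errors up
the cortical hierarchy, and that the *precision* (inverse variance) of
sensory signals is encoded by the synaptic gain of those cells.
Stimulus contrast manipulates sensory signal-to-noise, so increasing
contrast should increase sp gain — strongly in early visual areas,
progressively less at higher levels.  The package implements the full
inference chain needed to test that hypothesis on evoked EEG responses:
a biophysical source model, an electromagnetic observation model,
Bayesian inversion, and model comparison over connectivity and
gain-modulation hypotheses.  Because the original multi-subject EEG
recordings are not publicly available, the chain is exercised
end-to-end on synthetic data with known ground truth; every headline
number in the README is a recovery result on such data.

## Canonical microcircuit dynamics (`gaindcm.dynamics`)

Each cortical source contains four populations — spiny stellate (ss),
superficial pyramidal (sp), inhibitory interneuron (ii), deep pyramidal
(dp) — with second-order synaptic kinetics per population,

    v̇ = u,
    u̇ = κ·drive − 2κ·u − κ²·v,        κ = 1/τ,

and a centred firing-rate sigmoid σ(v) = 1/(1+e^{−ρv}) − ½ (odd,
bounded in ±½, slope ρ/4 at rest).  Ten intrinsic connections γ1–γ10
couple the populations; the wiring and signs are listed in the module
docstring.  γ7 (sp→sp self-inhibition) is the *negative gain* of the
superficial pyramidal population; γ10 the corresponding deep-pyramidal
quantity.  Extrinsic forward connections are excitatory, sp→ss of the
next area up; backward connections inhibitory, dp→sp of the next area
down.  Exogenous input — a Gaussian bump (onset 64 ms, dispersion
16 ms), the standard evoked-response drive — enters the spiny stellate
populations of the two lowest (input) areas.

Defaults: γ = (8, 4, 4, 4, 4, 2, 4, 4, 2, 1) in multiples of a base
rate of 200 s⁻¹; τ = (2, 2, 16, 28) ms for (ss, sp, ii, dp); ρ = 2;
forward/backward extrinsic strengths 6 and 3 base-rate units.  The
extrinsic defaults were chosen jointly so that (a) an evoked response
propagates visibly to the top of a four-level hierarchy (peak sp
depolarisation falls by roughly 2.5–3× per level rather than
vanishing) and (b) the resting state remains linearly stable even when
*all* extrinsic connections are scaled coherently by ±2 prior standard
deviations.  All defaults are configurable; none is presented as an
empirical estimate.

Condition effects act multiplicatively on the targeted self-connection:
in condition *c*, γ7 (or γ10) of area *a* becomes
γ7·exp(β_a·x_c), where x is a single mean-centred covariate
proportional to physical stimulus contrast ((0.10, 0.25, 0.90) of
maximum by default) and β_a is one free parameter per area.  Negative
β therefore means *less* self-inhibition — more gain — at higher
contrast; reports use gain change = −β so that a contrast-dependent
gain increase is a positive number.

### Integration

Trajectories start from rest and are integrated with classical
fixed-step fourth-order Runge–Kutta.  At the default time constants
the system is not stiff (‖hJ‖ is far inside the RK4 stability region
at h = 0.5 ms), and the scheme vectorises over large batches of
parameter sets — the property that makes finite-difference
sensitivities affordable.  The generator integrates at h = 0.5 ms in
double precision; inversions use h = 1 ms in single precision — the
step-halving error (~3×10⁻⁶ relative) and the single-precision error
(~3×10⁻⁷) are both far below sensor noise, and together cut the cost
of finite-difference sensitivity sweeps by ~4×.  Output is sampled on the epoch
grid −100…400 ms at 200 Hz (101 samples).  A trajectory whose membrane
excursion exceeds 10³ mV raises a divergence error naming the batch
elements; the sigmoid bounds firing, so this triggers only for
pathological couplings.

## Observation model (`gaindcm.observation`)

Only sp depolarisation contributes to the measured signal (the
EEG-generating population).  A fixed synthetic lead field — seeded
Gaussian columns, unit norm, pairwise |cosine| ≤ 0.6, full column rank
— maps 8 sources to 32 sensors.  It mimics the mixing of a
volume-conductor forward model while remaining reproducible without
head geometry; it is stored with each dataset.

For inversion, sensor data are reduced to 8 orthonormal spatial modes:
the leading eigenvectors of the sensor covariance of data *predicted
under the prior* (prior-mean prediction plus first-order propagation of
prior parameter scatter, J·diag(prior var)·Jᵀ).  The reference model
for this covariance is the fullest candidate architecture, so the mode
basis spans every candidate's predictions; an empirical-covariance
option exists.  Modes are computed once per dataset (a per-subject
flag would change little here because all subjects share the lead
field).  Eigenvector sign is fixed by making each row's
largest-magnitude entry positive, so the decomposition is
deterministic.

## Variational Laplace (`gaindcm.vl`)

The inversion fits a Gaussian posterior q(θ) = N(μ, Σ) over the free
parameters together with a log noise precision λ (IID Gaussian noise
in mode space, covariance e^{−λ}I — one pooled λ by default; the
module is agnostic about richer noise models).  All free parameters
are log-scale factors on their baselines, Gaussian priors centred at 0
with variances 1/16 (intrinsic and extrinsic log-scales, β) and 1/8
(input gain); λ has prior mean 4, variance 1.  The free parameters of
a network model are: the four intrinsic self-connections (γ1, γ4, γ7,
γ10) per area — the gain parameters, the natural minimal free set
containing the two modulation targets — every extrinsic connection
strength, one input gain per input area, and β per area when a
condition-effect model is attached.

The free energy is the standard fixed-form bound

    F = ⟨log p(y|θ,λ)⟩_q − KL(q(θ)‖p(θ)) − KL(q(λ)‖p(λ)),

computed with the Gauss–Newton curvature Σ = (e^λ JᵀJ + Π₀)⁻¹, where J
are central finite-difference sensitivities of the predicted mode
responses (step 10⁻³ on the log scale).  Accuracy and the two
complexity terms are reported separately for audit.  For a
linear-Gaussian model with fixed λ this F equals the closed-form log
marginal likelihood exactly, which the tests verify to better than
10⁻⁹ nats.

Optimisation: Levenberg–Marquardt-damped Gauss–Newton steps on μ, with
a step accepted only if it improves the best F attained so far —
hence the recorded free-energy trace is non-decreasing by
construction.  The initial damping is small (10⁻³) so linear problems
converge in essentially one step; rejected steps quadruple the
damping, accepted ones halve it.  A trial step whose simulation
diverges counts as rejected.  After every accepted step λ is
re-optimised by a bounded one-dimensional search of F (the current λ
is kept if the search does not improve it, so F still never
decreases).  Convergence: |ΔF| < 0.05 nats on three consecutive
accepted steps, or an iteration cap (64 by default; the pipeline uses
8, see below); if the cap is hit, the best state is returned with a
non-convergence flag.  The scheme is fully deterministic — randomness
enters only through the synthetic data.

## Model space and selection (`gaindcm.model_space`, `gaindcm.model_selection`)

Eight sources: IOG, SOG, IPC, SOrbG in both hemispheres, hierarchical
levels 1–4 with IOG the input level.  Six candidate architectures:
(1) serial chain IOG→SOG→IPC→SOrbG per hemisphere, (2) parallel
fan-out IOG→{SOG, IPC}→SOrbG, (3) serial chain plus an IOG→IPC skip,
and (4–6) the same three augmented with diagonal interhemispheric
connections between adjacent levels.  Backward edges always mirror
forward edges.  Architecture 5 (serial + diagonal interhemispheric) is
the generating model of the synthetic study.  Three condition-effect
hypotheses share whatever architecture they are attached to and differ
only in the modulation target — sp self-inhibition, dp
self-inhibition, or none — so evidence differences isolate the
gain-modulation question.

Fixed-effects Bayesian model selection: pooled evidence of a model is
the *sum* of its log evidences over subjects (or conditions, in stage
1); posterior model probabilities are the softmax of pooled evidences
under a uniform model prior; ties are flagged and broken by lowest
model id.  All comparisons are reported in nats with explicit unit
labels.

## Synthetic study (`gaindcm.synthetic`)

The generator emulates the structure the analysis assumes: 18 subjects
(configurable) × 3 contrast conditions, epochs −100…400 ms at 200 Hz,
baseline-corrected on the pre-stimulus window.  Per subject,
non-modulation parameters receive independent Gaussian log-scale
perturbations (SD 0.1 — a between-subject spread that keeps every
subject's dynamics stable while making subjects distinguishable); the
per-area modulations are the level profile β = −0.5·(1, ¾, ½, ¼)
(a 4:3:2:1 magnitude ladder, negative because gain rises with
contrast) scaled by one subject-level factor with SD 0.2.  White
Gaussian sensor noise is added at the averaged-epoch level — the
inversion consumes averages, so trial-level simulation would add cost
without touching any modelled quantity — scaled so signal power /
noise power equals the target SNR of 8; a pink-noise option and an
optional 0.5–45 Hz band-pass of the noise exist for robustness
experiments.  Unstable parameter draws are redrawn (bounded retries).
Every dataset carries its full ground truth, sufficient to regenerate
the noiseless signal bit-exactly.

What the generator does *not* emulate: real head geometry and
volume-conduction, per-trial variability and artefacts (eye movements,
trial rejection), temporally correlated or spatially structured noise
(beyond the pink option), non-stationary gain, and source
localisation error — the lead field is known exactly to the inversion.
Recovery results on these data therefore demonstrate the correctness
and calibration of the inference chain, not its robustness to the
mis-specifications real EEG would add.

## Pipeline (`gaindcm.pipeline`, `gaindcm.stats`)

* **Stage 1** — each of the six architectures (no condition effects) is
  inverted on the grand-average response for each contrast level
  separately; log evidences are pooled over levels; the winner is the
  architecture with the highest pooled evidence.
* **Stage 2** — within the winning architecture, the three
  condition-effect models are inverted on each subject's
  condition-specific averages; evidences are pooled over subjects; the
  winning model's per-area MAP β (one per area and hemisphere) form
  the beta table.
* **Stage 3** — classical summary statistics on gain changes (−β):
  a two-way fixed-effects ANOVA with factors source level (4) and
  hemisphere (2) including their interaction (error df = N−8), and a
  one-way planned linear-trend contrast across levels weighting the
  groups bottom-to-top 4, 3, 2, 1.  The raw weights do not sum to
  zero, so they are centred to (1.5, 0.5, −0.5, −1.5) by default —
  the same linear trend, but a valid contrast that does not confound
  the grand mean; a fidelity flag applies the raw weights.  The error
  term pools the within-group variance over the four level groups
  (df = N−4; with 18 subjects × 8 parameters this gives the
  144-observation, 140-df design).  Equal variances are assumed.
  Hemispheres are pooled when the two-way ANOVA shows no hemisphere
  effect at α = 0.05, otherwise pooled and per-hemisphere contrasts
  are both reported.  With a single subject, stage 3 is skipped with
  an explicit notice.

Pipeline inversions use the 1 ms single-precision integration step, an
iteration cap of 8, and declare convergence after two consecutive sub-tolerance
improvements; at the study's signal-to-noise ratio the winning models
converge in 3–6 iterations, while mis-specified models keep finding
small improvements up to the cap.  Truncating a losing model's search
can only understate its evidence, never inflate the winner's margin.

### Direction of the trend statistic

Recovered gain changes *decrease* with level, and the centred weights
decrease with level, so the planned contrast is positive under the
hypothesised pattern.  A report that parameterises the same effect as
the change in *self-inhibition* (the raw β) would flip the sign; only
the direction convention differs.

## Replicate studies (`gaindcm.studies`) and problem sizes

Three seeded studies quantify recovery; the test suite runs them at 10
replicates, the reproduction script defaults to 5:

* architecture recovery — 18-subject studies; the six-way stage-1
  comparison (the winner margins run >100 nats at this grand-average
  SNR);
* gain-model recovery — 6-subject studies for the three-way stage-2
  comparison, the rank correlation between true and recovered β
  (areas × subjects, Spearman), and the planned trend test on
  recovered gains — the 6-subject groups keep per-replicate cost near
  one minute while leaving the comparison non-trivial at
  subject-level SNR;
* null-data evidence — with no true modulation, the null model must
  win or trail by at most the ~3-nat Occam margin.

The stage-3-only calibration study (flat gain profile, 500 replicates)
checks that the trend test rejects at ≈ α, and its power under a
medium trend is validated against the closed-form noncentral-t power.

## Known limitations

* The CMC here implements exactly the two extrinsic projection rules
  stated above; variants with additional forward sp→dp or backward
  dp→ii targets are not enabled by default.
* Fixed-effects selection only; no random-effects BMS, family
  inference or model averaging.
* The noise model is IID in mode space; no AR temporal structure.
* Finite-difference sensitivities assume smoothness; very large steps
  in parameter space during early LM iterations are handled by
  damping, not by line search.
* Evidence values depend on data scale through λ; only *differences*
  between models fitted to the same data are interpretable.
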