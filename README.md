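# gaindcm — dynamic causal modelling of contrast-dependent synaptic gain

`gaindcm` implements, as a tested and reusable pipeline, the inference
chain needed to ask where stimulus contrast acts in a cortical
hierarchy: on the gain of superficial pyramidal cells (the population
hypothesised to broadcast precision-weighted prediction errors), on
deep pyramidal cells, or nowhere.  It is aimed at computational
neuroscientists who want a self-contained, fully synthetic testbed for
dynamic causal modelling (DCM) of evoked EEG responses: every
component — neural mass model, observation model, variational
inversion, Bayesian model selection, classical statistics — is
implemented here and validated against independent oracles.

The chain, end to end:

* **Canonical microcircuit (CMC) sources.**  Eight sources (four
  bilateral areas in a four-level hierarchy) with four populations each
  — spiny stellate *ss*, superficial pyramidal *sp*, inhibitory
  interneuron *ii*, deep pyramidal *dp* — coupled by ten intrinsic
  connections γ₁…γ₁₀ with second-order kinetics
  `v̈ = κ·drive − 2κv̇ − κ²v`.  γ₇ (sp→sp self-inhibition) is the
  negative gain of the sp population; stimulus contrast modulates it as
  `γ₇ · exp(β_a · x_c)` with one parameter β per area and a single
  mean-centred covariate x proportional to physical contrast.
  Extrinsic forward connections are excitatory (sp→ss, ascending),
  backward connections inhibitory (dp→sp, descending).
* **Observation model.**  sp depolarisation × a fixed lead field →
  32 sensors, reduced to 8 orthonormal spatial modes (eigenvectors of
  the prior-predicted data covariance) for inversion.
* **Variational Laplace.**  Gaussian posterior over log-scale
  parameters plus a log noise precision, fitted by damped Gauss–Newton
  on finite-difference sensitivities; the attained free energy
  `F = accuracy − complexity` approximates the log model evidence.
* **Fixed-effects Bayesian model selection.**  Pooled log evidences
  (sums over subjects/conditions), log Bayes factors and posterior
  model probabilities over six extrinsic architectures and three
  gain-modulation hypotheses.
* **Classical statistics.**  Two-way ANOVA (source level × hemisphere)
  on the recovered gain changes and a planned linear-trend contrast
  across levels with centred 4,3,2,1 weights.

The original study's EEG recordings are not publicly available, so the
package ships a first-class synthetic-data generator whose ground
truth is the serial hierarchy with diagonal interhemispheric
connections, contrast-dependent sp gain that decreases with level in a
4:3:2:1 profile, and sensor noise at SNR 8.  All headline numbers are
recovery results on such data.  See `docs/methods.md` for the model
details and every default.

## Worked example

```bash
python analysis/01_simulate_study.py      # 18 subjects x 3 contrasts
python analysis/02_architecture_comparison.py
python analysis/03_gain_model_comparison.py
python analysis/04_hierarchy_stats.py
```

`02` inverts the six candidate architectures on the per-contrast grand
averages and pools log evidences.  On the default study (seed 42) it
prints:

```
Fixed-effects Bayesian model comparison (log evidences in nats)
 model  pooled_log_evidence_nats  delta_to_best_nats  posterior_probability
     1                 11630.660            -148.772                  0.000
     2                 11300.933            -478.499                  0.000
     3                 11485.796            -293.636                  0.000
     4                 11593.398            -186.035                  0.000
     5                 11779.433               0.000                  1.000
     6                 11618.197            -161.236                  0.000
winner: 5

winner matches the generating architecture (5: serial hierarchy with
diagonal interhemispheric connections)
```

The generating architecture wins with every rival trailing by at
least ~149 nats — including its own superset (6, the same hierarchy
plus skip connections), which fits no better and pays the complexity
penalty.  `03` then compares the three gain hypotheses on
subject-specific averages:

```
model  pooled_log_evidence_nats  delta_to_best_nats  posterior_probability
 null                145192.642           -6588.108                  0.000
   sp                151780.751               0.000                  1.000
   dp                149243.993           -2536.757                  0.000
winner: sp

log Bayes factor sp vs dp: 2536.8 nats
log Bayes factor sp vs null: 6588.1 nats
```

— decisive evidence that contrast acts on *superficial* pyramidal
gain, as in the generating model.  Finally `04` tests the hierarchy of
the recovered gain changes (gain = −β, so positive values mean more
gain at higher contrast):

```
two-way ANOVA (gain ~ source level x hemisphere):
                          sum_sq     df           F        PR(>F)
C(level)                3.991265    3.0  113.247627  8.290213e-37
C(hemisphere)           0.014722    1.0    1.253184  2.649184e-01
...
hemisphere effect p = 0.265 -> pooled hemispheres
planned linear trend (weights (1.5, 0.5, -0.5, -1.5)): t(140) = 18.228, p = 8.685e-39
group-mean gain change by level (bottom to top): [0.461 0.321 0.218 0.005]
```

The contrast-dependent gain increase shrinks monotonically from the
bottom of the hierarchy to the top — the signature of precision being
set at the sensory level.

A `gaindcm` command-line tool exposes the same stages
(`gaindcm simulate | invert | compare | stats | run-all`); library
entry points are `gaindcm.simulate_dataset`, `gaindcm.run_stage1/2/3`
and `gaindcm.run_all`.

## Layout

```
src/gaindcm/
  model_space.py     six architectures, effect hypotheses, ground truth
  dynamics.py        CMC neural mass model + batched RK4 integrator
  network.py         parameter packing, priors, forward model
  observation.py     lead field, spatial modes, reduction
  vl.py              variational Laplace inversion, free energy
  model_selection.py fixed-effects Bayesian model selection
  synthetic.py       multi-subject synthetic ERP study generator
  stats.py           ANOVA, planned trend contrast, power oracle
  pipeline.py        stages 1-3, reports
  studies.py         seeded replicate recovery studies
  io.py, cli.py      HDF5/CSV/JSON persistence, command line
analysis/            numbered drivers for the worked example
tests/               unit + property + acceptance suites
docs/methods.md      models, assumptions, defaults, limitations
```
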