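# Methods

This note documents the models implemented in `wmdecode`, the assumptions
behind the synthetic-data generators, the numerical choices that were
genuinely open, and what the test suite does and does not establish about
real recordings.

## Task and behavior model

A session is a continuous alternation of delay and stimulus epochs with no
inter-trial interval; a trial is one delay–stimulus pair, and each trial's
stimulus is the cue for the next. Trial types follow a three-state Markov
chain: after a cue, the next stimulus is a cue with probability 0.8, a probe
with 0.1 and a target with 0.1; after a probe or target a cue is mandatory.
The stationary type frequencies are therefore 10/12, 1/12 and 1/12, while
the *conditional* target probability after a cue is the nominal 10%.

Delay durations are `offset + Exponential(mean)` with offset and mean both
800 ms; draws above the 4,000 ms cap are replaced by a uniform draw on
[3,600, 4,000] ms, which keeps the cap's effect on the mean small. The
resulting mean is exactly `1600 − 1000·e⁻⁴ ≈ 1581.7 ms` (the sampler's
closed form is exposed as `expected_delay_mean_ms` and checked against a
numerical-integration oracle in the tests). Stimulus durations are
locomotion-dependent in the real task and are simulated as lognormal with
median 1,967 ms and σ_log = 0.2 — the variability is preserved without a
locomotion model.

Responses are Bernoulli: the WM-task cue false-alarm probability is linear
in the preceding delay (`fa_base + fa_slope_per_s × delay`, clipped to
[0, 1]; default slope 0.119 s⁻¹), Discrimination-cue and probe responses are
delay-independent, and targets are hit with probability
`hit_rate·(1 − lapse)`. Lick latencies are Gaussian around 400 ms with WM
engagement shifting cue-response latencies by 163 ms and target latencies by
70 ms by default; the reaction-time peak estimator uses the mode of a
16.67 ms-binned histogram, so lags are resolved to one display frame.
`BehaviorParams` also carries `opto_fa_boost` and `opto_recovery_ms`: a
delay-onset silencing trial raises the WM-cue false-alarm probability by
the boost unless the delay outlasts the recovery time. This is the minimal
behavioral counterpart of the neural silencing model below and is what links
"short-only" behavioral deficits to cue-code recovery in the two regimes.

## Population-activity model

Activity (deconvolved ΔF/F0 units) for each cell is a baseline plus four
components, then i.i.d. Gaussian noise, then rectification at zero:

1. **Sequential delay dynamics** — `n_seq_bumps` Gaussian bumps (σ = 300 ms)
   tiling the 0–3.2 s delay, each cell loading one bump. These dynamics are
   identical in expectation across tasks: they emulate timing/preparatory
   structure, not memory.
2. **Task and cue codes** — fixed sparse directions over
   `code_participation` of the cells, orthogonalized against the bump
   subspace, active only during WM-task delays. The cue code is signed by
   the preceding cue (A negative, B positive); the task code is one-sided
   (present in WM, absent in Discrimination) and scaled by
   `task_code_scale` so the two contrasts have comparable separations.
3. **Stimulus response** — a dense shared transient (exponential decay,
   τ = 800 ms) plus an orientation-sign component along a second dense
   direction. Both are deliberately high-variance: they dominate the top
   PCs of single-trial activity, which is what makes the stimulus code
   low-dimensional in the PC-sweep sense.
4. **Amplitude process** — each code's per-trial amplitude is lognormal
   (CV = `code_trial_cv`) with separate early-half and late-half values
   whose *linear* Pearson correlation equals `persistence_rho` exactly (the
   latent-normal correlation is solved in closed form,
   `ρ_z = ln(1 + ρ(e^{σ²} − 1))/σ²`). This makes the late-vs-early slope of
   z-scored projections an unbiased estimator of `persistence_rho`, which
   the recovery tests exploit.

Default amplitudes were chosen once so that the generator sits in the
paradigm's operating regime: delay codes decodable at roughly 0.75–0.9
leave-one-out accuracy from ~300 cells, yet with per-frame variance inside
the noise bulk of the single-trial PCA spectrum — so excluding the top 100
PCs leaves the delay codes decodable while collapsing the stimulus code.
The absolute activity scale (baseline 0.4, noise σ 0.16) also makes the
fixed discriminant ridge γ = 10⁻⁴ a meaningful fraction of the smallest
covariance eigenvalues, matching the magnitude of real deconvolved
ΔF/F0 traces.

Axonal boutons: each axon's latent trace is the population model at the
axonal frame rate (22.78 Hz) plus a private per-axon Gaussian signal (the
generator's `noise_sigma`, default 0.5); each bouton is its axon's latent
plus i.i.d. noise (`bouton_noise_sigma`, default 0.1, i.e. bouton SNR 5).
Bouton counts are Poisson with mean 8 (floored at 1). Delay-onset silencing
multiplies the cue-code amplitude by `1 − silencing_cue_attenuation` from
delay onset, recovering after `silencing_recovery_ms` if finite. Because
only the cue code is attenuated, the net (mean or PC1) activity is
unchanged — the modulatory-feedback dissociation is a generator-level
property. One caveat: with rectification enabled, removing code variance
shifts the post-rectification mean by a few parts per thousand, so the
strict "zero mean effect" property is tested with rectification off.

## Analysis conventions

- **Time** is milliseconds, 0-based; windows are half-open `[start, end)`;
  a frame belongs to a window iff its temporal midpoint falls inside both
  the window and the trial's epoch (delay and stimulus windows never share
  a frame). Trials whose epoch or the recording truncates the window are
  flagged incomplete, never padded.
- **Trial filtering** removes halted trials, delay-lick trials, trials
  following probes/targets (the mandatory cues), and delay-end silencing
  trials; imaging analyses additionally drop delays above 3.2 s. The filter
  is idempotent.
- **Experiments** pair Discrimination and WM blocks whose cue orientations
  match across opposite ±15° rotation blocks (−15° and +15° matched, up to
  two experiments per session); with fewer than two pairings the experiment
  is the whole session, and a single-task session defines none.
- **Pooled PCA** trial-averages delay and stimulus responses per cell,
  concatenates them in time, stacks cells across experiments, and fits PCA
  over the time dimension with per-cell mean centering. Per-experiment
  projections slice the pooled components to the experiment's cells.
  Display trajectories may be smoothed with a causal half-normal filter
  (σ = 100 ms); the statistics path never smooths or interpolates.
- **Distance null**: task labels are shuffled across trials within
  experiment, without delay-duration stratification (the stratified
  alternative would only tighten the null if delay composition differed
  between tasks, which the generator excludes by construction). The
  Bonferroni divisor is the realized timepoint count, not a constant.
- **Coding dimensions** solve `(Σ + γI)w = μ_a − μ_b` with Σ the covariance
  of all training trials (not class-pooled), γ = 10⁻⁴, ddof = 1. The
  decision rule is the nearest projected training-class mean (midpoint
  threshold). The positive class is the lexicographically larger label,
  which puts the WM task and cue B on the positive side. Incorrect and
  silenced trials are excluded from training and scored with the models
  trained on correct control trials.
- **Leave-one-out decoding** downdates the full-sample covariance and class
  means by rank-one updates per fold (algebraically identical to refitting;
  the naive refit is kept as `loo_decode_naive` and equivalence is tested
  to 10⁻¹⁰). Held-out projections are z-scored with training-fold
  statistics only.
- **Persistence** uses trials with delays ≥ 2 s; early/late projections are
  the means over [0, 1.6) s and [1.6 s, delay end), z-scored across included
  trials after sign inversion of Discrimination-task (task code) or cue-A
  (cue code) projections.
- **Responsiveness** is conjunctive: post-minus-pre effect above 0.2
  (deconvolved ΔF/F0, or 0.2 z for axons) *and* a paired two-sided t-test at
  α = 0.01. Pre/post windows default to 800 ms each (a package default;
  nothing in the paradigm pins the window length). The axonal criterion slides 1-s delay windows in
  200 ms steps against the last second of the preceding stimulus, with
  Bonferroni correction over windows.
- **Latency** is the mean of a Gaussian (plus offset) fit to the
  odd-numbered-trial average; even trials are reserved for display, so the
  latency ordering is cross-validated. A fit is valid only if it converges
  with the mean inside the window, width between one frame and the window
  length, and positive amplitude; widths above half the window are flagged.
- **Bouton clustering** embeds boutons in a 40-D ICA temporal feature space
  and fits Gaussian mixtures (tied covariance, 3 restarts) over a k range,
  selecting k by AICc where the small-sample correction is defined and by
  BIC for the whole range otherwise — with 40-D features and O(10²) boutons
  AICc's denominator `n − p − 1` is negative for every useful k, so BIC is
  the operative criterion at realistic sizes. Boutons beyond the 0.99 χ²₄₀
  Mahalanobis quantile of their component, and members of singleton
  components, are left unassigned. When the requested 40 components exceed
  the rank of the shared signals, FastICA is rotation-degenerate in the
  surplus dimensions and cannot converge; after three reseeded attempts the
  last fit is accepted with a warning, since any rotation of the whitened
  space is an equally valid clustering embedding.
- **Silencing effects** compare silenced-minus-control delay-averaged
  activity against a null built by resampling control trials into two
  pseudo-arms (percentile p, two-sided, α = 0.05); a t-statistic of the
  observed value against the null is reported alongside. Effects on
  cue-code projections are computed separately for the early and late delay
  halves; the recovery index is their difference (positive = recovery).
- **Silencing-regime classification** (used when simulating the two
  feedback regimes): an experiment shows *persistent* disruption if the
  early cue-code effect is significant, the late/early effect ratio is at
  least 1/2, and behavioral deficits exceed 5 percentage points in both
  short (<1.6 s) and long (≥1.6 s) delay bins; *transient* if the ratio and
  the long-bin deficit fall below half their early/short counterparts. The
  1/2 threshold sits midway between the no-recovery expectation (ratio ≈ 1)
  and the full-recovery expectation (ratio ≈ 0); a conjunction of null
  non-rejections could not classify reliably, since two independent correct
  non-rejections at α = 0.05 already cap the rate at ≈ 0.90.

## Multiple-comparison and interval choices

Fisher exact tests on silencing contingency tables are Bonferroni-adjusted
across trial types within (area, epoch, task); raw p-values are reported
alongside. Binomial intervals are Clopper–Pearson throughout. d′ uses the
inverse Gaussian CDF; quartiles with no misses give +∞ and are treated as
missing data points.

## What the synthetic data do and do not establish

The generators reproduce the *statistical structure* the analyses assume —
Markov trial types, capped-exponential delays, delay-dependent false
alarms, low-dimensional shared dynamics with high-dimensional embedded
codes, bouton-sharing axons, code-specific silencing. Passing tests
therefore demonstrate that the estimators are correct, calibrated
(type-I ≈ α), and able to recover planted parameters (FA slope, persistence
correlation, axon partitions, recovery regimes) at realistic sample sizes.
They do not validate biological claims: real deconvolved calcium data have
non-Gaussian noise, neuropil and movement artefacts, inter-mouse
variability and unmodelled behavioral covariates. Problem sizes in the test
suite (hundreds of cells, hundreds to tens of thousands of trials, 2–3
replicates for bias checks) were chosen as the smallest that give the
estimators their asymptotic behavior.

## Known limitations

- The linear false-alarm model is clipped rather than a proper link
  function; slopes near the [0, 1] boundary are attenuated.
- Codes are single fixed directions with scalar amplitude variability;
  genuinely trial-varying code *patterns* are not modelled.
- The stimulus-duration model ignores the closed-loop coupling to running
  speed; halting is a Bernoulli flag only.
- Rectification makes the activity model weakly nonlinear; all decoding
  analyses treat it as linear, as the discriminant framework assumes.
- `eigenspectrum_compare` regularizes nothing when trials exceed cells; in
  the opposite regime trailing eigenvalues are rank-deficient zeros and
  only leading ranks are informative.
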