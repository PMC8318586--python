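# Methods

## Decision model

Choices and response times are modelled as a Wiener diffusion with unit
diffusion coefficient between absorbing boundaries at 0 (reject) and
`threshold` (accept), starting at `sp_bias · threshold`. The drift on a
trial is `w_tastiness · tastiness + w_healthiness · healthiness +
val_const`; response time is the first-passage time plus the non-decision
time `ndt`. Six free parameters per subject × condition; no inter-trial
variability parameters and no outlier mixture. Fixing the diffusion
coefficient at 1 sets the scale of the boundary and weights.

Attribute ratings are mean-centred within subject × condition before they
enter the drift and all regressions (raw 1–6 coding is available by flag).
Centring decorrelates the attribute weights from the value constant; the
same coding is used for generation and fitting so the two are consistent.

**Likelihood.** The first-passage density is evaluated with the standard
small-time / large-time series for the zero-drift unit-boundary process,
tilted exponentially for drift, with term counts chosen per time point for
an absolute accuracy of 1e-7 and the cheaper branch selected per element.
Decision times `rt − ndt` are floored at 1e-4 s so implausibly fast trials
contribute a large finite penalty rather than NaN. No-response trials
(4 s deadline) are excluded from the likelihood and counted.

**Estimation.** Per-cell maximum likelihood with L-BFGS-B from 8 seeded
starts (one heuristic start, the rest drawn uniformly inside the bounds:
weights and constant in (−5, 5), boundary in (0.1, 6), bias in (0.05,
0.95), `ndt` in (0, min rt − 1e-4)). Cells whose choices are constant with
near-zero RT variance return `converged=False` with a diagnostic instead
of a spurious optimum. A random-walk Metropolis hierarchical sampler with
group-normal priors (subject blocks updated jointly; conjugate draws for
group means, log-scale random walk for group SDs; defaults 11000 samples
after 1000 burn-in) is provided for fidelity experiments only — the
maximum-likelihood path is the estimator used everywhere else.

**Simulation.** Euler–Maruyama at dt = 1 ms, with the exact
Brownian-bridge within-step crossing probability applied to both
boundaries. This removes the discretisation bias of naive endpoint
detection: simulated accept fractions match the closed-form absorption
probability to < 0.005 at dt = 1 ms, where naive Euler is off by ~0.01.

## Model-simulated neural signals

Each trial yields three signals on a 1 ms grid (0–2 s, food-locked):

* **taste-AC / health-AC** — boxcars with onset `max(0, ndt − 0.080)`
  (80 ms motor-preparation constant), offset at the simulated response,
  height equal to the coded attribute value;
* **EA** — the evidence path relative to its starting point, re-indexed to
  begin at the same onset. Between the boundary crossing and the response
  (the 80 ms motor window) the path is held at the absorbing boundary, so
  the signal's support is exactly [onset, rt] like the boxcars; it is 0
  outside.

Signals are averaged pointwise over 1000 simulated datasets per trial
(the per-trial mean simulated RT is recorded); simulations that have not
crossed by the grid end are censored at the grid end. Optional white noise
of configurable SD can be added to the attribute signals; the EA noise is
the diffusion itself. Model 1 regresses each averaged signal, per time
point, on coded tastiness, coded healthiness and the *mean simulated* RT
(with intercept). Using simulated rather than observed RTs keeps the
regressor consistent with the signal-generating process; observed-RT
regressors are a caller-side substitution away since the regression takes
plain arrays.

Peak latencies are arg-extrema (largest magnitude by default) within a
window, ties resolving to the earliest sample — relevant because the
per-subject AC coefficient course is flat at 1 while all simulations
remain active, so its peak sits at the onset plateau's first sample. The
AC-before-EA ordering is compared across subjects with a paired t-test.

## EEG features

Epochs span −1.0 to 1.5 s around food onset. Preprocessing is a zero-phase
4th-order Butterworth band-pass (0.5–100 Hz), a 60 Hz IIR notch (2 Hz
width), and subtraction of the per-trial, per-channel mean over
[−0.2, 0] s. Time-frequency power uses complex Morlet wavelets at 1–80 Hz
(1 Hz steps) with cycles rising linearly from 3 at 1 Hz to 10 at 80 Hz;
epochs are reflection-padded so the 1 Hz wavelet fits, and samples within
a half wavelet length of the true epoch edges are flagged. Power is
`10·log10(A_t / A_baseline)` with a per-trial baseline over [−0.2, 0] s
(a condition-average baseline is a config option). Band power is the mean
over in-band frequencies (delta 1–3, theta 4–8, alpha 9–12, beta 13–35,
gamma1 36–59, gamma2 61–80 Hz — gamma2 starts above the line frequency by
design), then the mean within each time bin.

The bin grid is 25 contiguous bins from −200 ms; 48 ms bins by default
(ending at 1.0 s), or exactly 25 samples per bin at 512 Hz (48.83 ms)
via `BinGrid.from_sampling`. Model 2 applies the same per-bin OLS to ERP
amplitude and each band's power, per channel, per subject × condition.
The OLS engine is a single vectorised normal-equations solve with exact
SEs, verified against statsmodels on scalar cases. RT enters in seconds,
uncentred. RT-based splits (median or 33rd/66th tertiles, ties to the
faster bin) and response-locked realignment support the descriptive
analyses.

## Model–EEG comparison

For each channel (× band) the group-mean Model-2 coefficient course is
regressed onto the group-mean Model-1 course (the recorded scaling), and
the signed Pearson correlation over bins with centres in [0, 1.0 s] is
`r_eeg_model`, with a t-based two-sided p (df = bins − 2, ignoring bin
autocorrelation). The nominal correlation window in the source design runs
to 1.2 s but the bin grid ends at 1.0 s, so the default window is the
overlap; extending the grid extends the window.

The joint criterion flags a channel × band when (1) |r| > 0.85 and the
r-test p is below 0.05 after Bonferroni correction for channels × 7
components (six bands + ERP, scaling with the montage), and (2) the
group-level coefficient is significant (p < 0.05) with a uniform sign in
*every* bin whose centre lies within ±100 ms of the model-course peak,
truncated at 1.0 s. Requiring all bins (not any) and sign uniformity is
the stricter reading of a contiguous-window requirement; both choices were
open and the strict one keeps the null family-wise error below nominal.
The exploratory variant instead requires ≥ 6 consecutive significant
same-sign bins before 1.0 s. Dependent correlations sharing the EEG series
are compared with the Meng–Rosenthal–Rubin z-test.

## Group statistics

The three-condition within-subject design is analysed with a one-way
repeated-measures ANOVA (F with df (k−1, (k−1)(n−1)); no sphericity
correction by default, Greenhouse–Geisser optional), uncorrected post-hoc
paired t-tests, Pearson correlations of per-subject condition differences,
and Cousineau–Morey within-subject SEMs (subject means removed, grand mean
restored, J/(J−1) correction).

## Synthetic study generator

The generator emulates the study design: 20 subjects by default (50 at
study scale), 3 conditions × 180 trials, integer 1–6 ratings with a −0.2
taste–health correlation (discretised bivariate normal), DDM behaviour at
dt = 1 ms with a 4 s deadline (late trials become no-responses).
Per-condition parameter means centre NATURAL on the worked-example set
(w_t = 0.7, w_h = 0.1, ValConst = 0.5, a = 0.9, z = 0.45, ndt = 0.462 s);
HEALTH lowers w_t and raises w_h, DECREASE lowers w_t and ValConst and
raises the threshold — the directions regulation is expected to produce.
Subject parameters are normal draws (SDs 0.05–0.15) truncated to bounds.

EEG epochs contain 1/f background (spectral shaping, exponent 1), white
noise, and ongoing 10 Hz alpha and 6 Hz theta oscillations with random
phase per trial × channel. Effects are injected as the minimal structure
the analysis assumes:

* **ERP** — an additive transient equal to `erp_gain` × coded tastiness ×
  the trial's AC boxcar on fronto-central channels, all conditions;
* **alpha** — multiplicative envelope modulation `1 + gain × coded
  tastiness × ramp(t)` (clipped at 0.05), where the ramp rises from 0 at
  onset to 1 at the response — the noiseless EA shape per trial — with
  negative gain (suppression) on frontal + parieto-occipital channels, in
  NATURAL only by default;
* **theta** — the same construction with a smooth 0.2–0.5 s window
  template and positive gain in the regulation conditions.

Per-subject NATURAL alpha gains are normal (mean −0.22, SD 0.05); the
DECREASE − NATURAL gain change is constructed from the subject's true
tastiness-weight change so that their sample correlation equals the
configured target (−0.5) exactly — the noise component is orthogonalised
against the weight change — leaving criterion-level variation to the
measurement chain rather than to double sampling noise. HEALTH alpha gains
are 0; DECREASE gains are centred on 0 so regulation conditions carry no
group-level alpha effect. Effect sizes and noise amplitudes were fixed
once by pilot simulation so the injected effects sit comfortably above the
detection threshold at the test scale; they are study conditions, not
tuning knobs. Everything is deterministic under the master seed
(per-subject streams are spawned from it).

What the generator does **not** emulate: volume conduction and realistic
topographies, eye/muscle artifacts, non-stationary background spectra,
rating noise or session effects. Passing tests therefore show the
*pipeline* recovers what it assumes — not that real EEG satisfies those
assumptions.

## Problem sizes used by the evaluation runs

The evaluation experiments (tests and `scripts/acceptance.py`) choose
desk-scale sizes: oracle agreement at 1e5 trials per parameter set
(density histogram at 5e5 paths, dt = 0.2 ms, bin-averaged theoretical
density so the comparison carries no curvature bias); parameter recovery
at 20 subjects × 3 × 180 trials; latency ordering at 20 subjects with
200-dataset ensembles on a 2 ms grid; end-to-end detection at the test
preset (8 subjects, 16-channel montage, 256 Hz, 100-dataset ensembles,
alpha-band-only decomposition, with the Bonferroni m still counting the
full montage × 7 components); the null family-wise-error check simulates
subject-level coefficient courses directly for 64 × 7 components at
n = 50 (the criterion operates on those courses, so the raw-EEG stages
add nothing to its null behaviour); coupling recovery at n = 50 with a
7-channel parieto-occipital montage, the per-subject alpha correlate
taken as the mean alpha b_tastiness over 0.4–1.0 s averaged across the
parieto-occipital set. The "paper" preset (50 subjects, 64 channels,
512 Hz, 1000 datasets, full 1–80 Hz) runs the same code end to end.

## Numerical choices and edge cases

* Absorption probability uses `expm1` with series/asymptotic branches so
  it is continuous at zero drift and stable at |2va| > 700.
* Peak-latency ties break to the earliest sample; flat series therefore
  report the window start.
* Group bin tests report p at the smallest positive float (not NaN) for
  zero-variance bins; constant series in the matching step report NaN
  (missing) rather than raising.
* RT-split boundary ties go to the faster bin; all-equal RTs raise.
* Rank-deficient regression designs raise with the offending predictors
  named; predictor pairs with |r| ≥ 0.99 are rejected at design
  construction.

## Known limitations

* The per-cell maximum-likelihood estimator has no pooling, so single-cell
  estimates at 180 trials are noisier than a hierarchical posterior mean;
  recovery correlations (≈ 0.84 for the weights) reflect that.
* p-values for r_eeg_model ignore bin autocorrelation, as does the
  analysis this package follows; a block-permutation diagnostic would be
  the conservative alternative.
* The EA-shaped envelope template in the generator is the deterministic
  ramp, not a stochastic accumulation path; injected-effect recovery is
  accordingly cleaner than real data would allow.
* The coupling between the alpha-gain change and the weight change is
  imposed exactly in-sample; the recovered correlation (≈ −0.4) is the
  target attenuated by per-subject estimation noise.
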