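# Methods

This note documents the models implemented in `dpxdyn`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Task structure and containers

Trials are cue-probe pairs from the DPX / AX-CPT family: cue A or B at 0 s,
probe X or Y at the stimulus-onset asynchrony (default 2.5 s), a target
response required only for AX. The default block holds 129 pairs at
90/13/13/13 (AX/AY/BX/BY), two blocks per subject (258 trials, AX share
90/129 ≈ 0.70 per block, exact by construction). Epochs are stored as
trials × channels × time in microvolts, time in seconds with the locking
event at 0; trial metadata rows align one-to-one with epoch slices.
Vectorisation flattens each trial channel-major (all samples of channel 1,
then channel 2, …) with an explicit feature → (channel, time) index map, so
the round trip is exact. Window selection uses closed intervals on sample
times. Archives store amplitudes as float32 while all computation is
float64; round trips are bit-exact at the stored precision. No baseline
correction is applied anywhere: the generator's pre-stimulus interval is
zero-mean noise by construction, and users feeding their own epochs should
baseline-correct beforehand if needed.

## Mass-univariate model

Level 1 solves `Y = Xβ + ε` per subject with `β = pinv(X) · Y` (SVD
pseudo-inverse), which equals OLS for full-rank designs and the minimum-norm
solution otherwise. Factor predictors are effect coded (A/X = −1, B/Y = +1);
condition-specific coefficient maps for the second level come from
per-condition indicator fits (i.e. condition means), and the standard
contrasts are cue B−A and probe AY−AX (the probe analysis re-locks epochs to
probe onset and keeps A-cue trials).

Level 2 is a paired *t* across subjects at every channel-time point, with
F = t². Family-wise error is controlled by the bootstrap maximum-statistic
procedure: each condition's maps are grand-mean centred across subjects at
every point (imposing the null), whole subjects are drawn with replacement
(paired maps move together), the maximum F over all points is recorded per
resample, and the critical value is the empirical (1 − α) quantile of the B
maxima. Defaults α = 0.01 and B = 2000; B < 100 is refused (the tail
quantile is unstable). Resamples in which a point has zero variance would
give F = ∞; such points are excluded and the resample contributes the
maximum of its finite F values (logged). Significance is strict inequality
(F > F_crit). Moderation analyses (contrast maps regressed on a mean-centred
per-subject score such as d'context) reuse the same max-statistic machinery,
imposing the null by removing the fitted intercept and slope and resampling
subjects from the residual maps.

Two properties of this procedure are worth knowing. First, it is
conservative: under the simulated global null the family-wise error rate at
α = 0.01 comes out between 0 and ~0.01 (the acceptance band is [0, 0.035]).
Second, the bootstrap-*t* tail is heavy at small sample sizes: with ~24
subjects the threshold over tens of thousands of correlated points lands
near F ≈ 55–70 even though an oracle null simulation puts the true 99%
max-F quantile near 40. In consequence an effect of group size d ≈ 1–1.5
(the realistic ERP range) is detectable at its spatiotemporal peak from
roughly 50 subjects — consistent with the analytic power result below — but
not from 24. The recovery validation therefore reports both sample sizes:
at 52 subjects the significance mask covers the injected support
essentially completely; at 24 subjects only the peak is recoverable, and
the 50%-coverage check in the acceptance suite documents this expected
failure rather than hiding it.

The paired-t power calculation uses the noncentral *t* distribution
(two-sided, df = n − 1, noncentrality d·√n). `paired_t_sample_size` returns
the smallest integer n whose power meets the target (51 for d = 0.5,
power = 0.80, α = 0.01); `solve_paired_t_n` returns the continuous root
(≈ 50.1 for the same inputs), the planning value conventional power tools
print and round.

## Decoding

Per time sample, a linear SVC (squared hinge, primal liblinear, C = 1) is
trained on the channel vector, with class weights N/(2·N_class) — inverse
frequency, so the 70/10 AX-heavy designs cannot be solved by always guessing
the majority. Cross-validation is 5-fold stratified, shuffled once per
subject and shared across training times so all cells of one GAT matrix are
comparable. Features are standardised with training-fold statistics at the
training time; the same affine transform is applied when the classifier is
scored at other times (train-time statistics travel with the classifier).
AUC is computed from the continuous decision values by the rank formula and
averaged across folds; a hard-prediction scorer is available for comparison
but graded AUC values require the decision-value reading. Group-level
significance is a two-sided one-sample *t* against 0.5 per cell with
Bonferroni correction over all tested cells; zero-variance cells are
non-significant unless every subject sits off chance at the same value
(flagged and logged). All trials enter decoding regardless of accuracy.

## Synthetic-data generator

The generator is the package's test bed: it produces data whose every
injected effect is known, so recovery, calibration and dissociation can be
measured rather than assumed.

**Evoked model.** Each condition effect is a component: a scalp topography
(Gaussian bump over the montage, max |weight| = 1) times a temporal kernel —
a half-cosine bump for transient components, a plateau with 15% cosine ramps
for sustained ones (real waveshapes are unknown; only the windows are
constrained). Defaults, all cue-locked seconds: B-vs-A transient
occipital-parietal negativity 0.18–0.25 s, sustained parietal positivity
0.40–0.75 s, late fronto-central negativity 1.10–1.45 s; probe-locked
(AY-vs-AX, windows shifted by the SOA) occipital-parietal negativity
0.18–0.25 s, fronto-central positivity 0.30–0.40 s, parietal positivity
0.45–0.75 s. Peak condition differences are 2.5 µV (cue) and 3 µV (probe).
Ground-truth masks mark (channel, time) points where a component's injected
difference exceeds half of its own maximum.

**Noise model.** Spatially correlated coloured noise plus sensor white
noise. The temporal spectrum is 1/f^1.5 with a cosine roll-off above 30 Hz,
emulating the band-limited (0.1–30 Hz filtered) signal that epoched EEG
statistics run on; spatial correlation decays as exp(−d/1.0) in unit-disc
montage distance (neighbouring channels r ≈ 0.7–0.85, as for
average-referenced scalp data). The background is scaled analytically so its
marginal standard deviation is exactly `background_sd` in expectation.
Defaults: background 5 µV, white 1.5 µV.

**Calibration of the variance split.** Two group-level observables pin the
defaults: peak group effect sizes of d ≈ 1–1.5 (paired t of ~7–11 at 52
subjects) and peak group-mean decoding AUC of ~0.6–0.7. The first constrains
amplitude relative to the *between-subject* spread, the second relative to
the *single-trial* noise. Jointly they imply a fairly clean single-trial
signal (≈5 µV noise against 2.5–3 µV peak effects) with large
between-subject amplitude heterogeneity: per-subject component amplitudes
are scaled by 1 + N(0, 0.55), floored at 0.1 — a population containing weak
and non-responders, as ERP cohorts do. An estimation-noise-dominated split
(e.g. 12 µV single-trial noise with 0.15 subject scatter) reproduces the d
values but caps decoding near AUC 0.57 and is therefore not used.

**Behaviour.** Correctness is Bernoulli per pair (defaults: AX 2%, AY 17%,
BX 4%, BY 3% errors) with a per-subject offset on the logit (SD 0.35). RTs
are lognormal (log-scale SD 0.2) with a per-subject additive offset
(SD 25 ms) on the subject's mean; the lognormal location is set so the
distribution *mean* — not the median — equals the target marginal (correct
AX 351 ms, AY 491 ms, BX 273 ms, BY 278 ms; incorrect AX 534, AY 385,
BX 592, BY 608 ms), because the emulated quantities are reported marginal
means and the ±15 ms fidelity check is on the mean. ITI and SOA are carried
as metadata; epochs are generated directly rather than cut from a
continuous record.

**What the generator does not emulate.** No forward-modelled head volumes,
no ocular/muscle artefacts, no trial-to-trial latency drift (component
jitter defaults to 0), no autocorrelation between successive trials, no
learning or fatigue effects, and Gaussian noise throughout. Passing tests
therefore demonstrate that the statistics behave correctly on data with the
stated covariance and effect structure — not that any particular real
dataset satisfies those assumptions.

## Behavioural indices

Rates are computed per pair over responded trials after the RT exclusion
(present RTs strictly below 100 ms or above 1000 ms are dropped; bounds are
inclusive, non-responses are kept). Rates of exactly 0 or 1 are replaced by
1/(2N) and 1 − 1/(2N) before the probit, so d'context and the A-cue bias are
always finite. The within-subject confidence interval removes each subject's
row mean (restoring the grand mean), rescales the per-condition variance by
J/(J−1) for J conditions, and uses the Student-t quantile at the requested
level — the subject-centring estimator with the small-sample correction
factor.

## Problem sizes and runtime

Validation runs use 32 channels at 128 Hz (mass-univariate) or 64 Hz
(decoding) against the original acquisition's 64 channels at 512 Hz;
statistics are resolution-agnostic and full-size generation is available
through the same interfaces. The standard validation battery: FWER over 200
null datasets of 16 subjects (16 ch × 64 samples, B = 500, ~30 s);
single-test threshold vs F(1,19) (B = 2000, instantaneous); recovery at 24
and 52 subjects (B = 2000, ~25 s / ~45 s); GAT dissociation over 16 subjects
(64 Hz, −0.1–1.05 s, ~45 s); behavioural marginals over 20/100 subjects
(~1 s). The complete acceptance script runs in under five minutes on one
core.

## Numerical conventions

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (pipeline stages use fixed spawn keys:
0 generator, 1 mass-univariate bootstrap, 2 moderation, 3 decoding), so any
stage can be re-run in isolation and reproduce the full run bitwise. Paired
*t* at zero-variance points reports signed infinity and is flagged; exact
threshold ties are not significant; bootstrap quantiles use the empirical
(linear-interpolation) quantile; standardisation guards divisors below
1e-12; the pseudo-inverse rank is recorded on every first-level fit.
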