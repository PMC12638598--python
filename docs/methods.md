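# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `pataka`, and what validation on synthetic data does and does
not establish.

## The analysis in one paragraph

A diadochokinesis (DDK) trial is a 10-second recording of a participant
repeating a plosive-initial syllable ("pa", "ta" or "ka") as fast as they
can.  From each admitted recording the package extracts 19 features
describing repetition timing (onset count/rate, inter-onset-interval
statistics), zone structure (syllable/pause durations and proportions),
voice onset time, and energy regularity.  The statistical question is not
which individual feature matters but whether *any* combination of features
improves estimation of three cognitive count scores — episodic-memory
errors, executive search strategy, working-memory errors — over a null model
of demographic/clinical covariates.  That is answered per (participant group
× outcome × DDK test) by exhaustive AICc subset selection over count GLMs,
with a collinearity constraint; a supplementary analysis compares paired ROC
curves of logistic models for HC-vs-SCI classification.

## Acoustic pipeline

**Screening.**  Recordings at exactly 8 kHz are excluded (consumer-hardware
captures at this rate proved unusable), as are recordings shorter than
`min_duration` (default 2 s — a 10-s protocol recording below this cannot
contain a usable trial) and recordings whose active-speech fraction is below
`utterance_floor` (default 2% of 10-ms frames above a noise-floor-relative
energy threshold).  Neither the length nor the utterance threshold has a
canonical value; both are configuration.  Unreadable containers raise
`IOError` and are counted separately from screening rejections.

**Internal rate.**  Admitted recordings are polyphase-resampled to 16 kHz so
all frame/hop parameters are uniform across the 8-48 kHz input range.

**Denoising** is spectral gating on a short-time spectrum (32-ms Hann
frames, 8-ms hop).  The per-band noise floor is the 20th percentile of
magnitude over a sliding 1.5-s window — evaluated on half-overlapping blocks
and interpolated, which tracks non-stationary ambient noise at O(N) cost — and
bins are attenuated toward a 0.08 gain floor through a sigmoid gate 6 dB
above the floor (3 dB transition), with a light 3×3 time-frequency smoothing
of the mask.  The operation is deterministic, preserves length and rate,
passes all-silent input through unchanged, and never increases silent-span
energy.

**Normalization** scales to unit peak amplitude; all features are
amplitude-scale invariant as a consequence.

**Onset detection** uses a spectral-flux envelope: the band-summed,
half-wave-rectified first difference of the log-magnitude STFT (46-ms
frames, 10-ms hop).  Frames whose analysis window straddles the signal edge
are dropped (the truncation discontinuity there splatters broadband leakage
into the flux).  Peaks are accepted above an adaptive threshold
(1.3 × [local 0.5-s median + 5% of the global maximum]) greedily in
descending strength with a 90-ms refractory period — above the fastest
plausible DDK rate (~11 syll/s).  Because a centred analysis window "sees"
an energy rise before its centre reaches it, the flux peak leads the
physical burst; a fixed +14 ms offset (calibrated on synthetic trains,
stable to ±3 ms across 2-7 syll/s and 20-40 dB SNR) converts peak times to
onset times.

**Segmentation** thresholds a smoothed short-time RMS track (12-ms window,
3-ms hop) with hysteresis: enter-speech at floor + 0.12·(peak − floor),
exit at floor + 0.06·(peak − floor), where floor/peak are the 15th/97th RMS
percentiles.  Gaps shorter than 30 ms are bridged; an isolated blip shorter
than 40 ms is merged forward across a gap of up to 150 ms (a lone plosive
burst re-joined to its vowel — without this, long-VOT syllables split and
VOT collapses to zero); remaining sub-40-ms blips are dropped.  Pauses are
defined only *between* repetitions: leading and trailing silence belongs to
neither zone, so speech% + pause% ≤ 100 with both percentages taken against
the full sample duration.

**VOT** is measured per speech interval as (voicing onset − interval
start).  Voicing is first localized by scanning 30-ms windows at 5-ms steps
for a normalized-autocorrelation peak ≥ 0.5 in the 70-400 Hz lag band, then
refined on an 8-ms RMS envelope (≈ one glottal period, so the track does
not ripple at f0): the onset is the first rise that stays above half the
vowel's steady level for ≥ 22 ms (outlasting a burst plus smoothing spread)
*and* passes the periodicity test at the rise point, minus a 5-ms attack
compensation (half the synthetic vowel's 10-ms amplitude attack).
Repetitions with no detected voicing, or with a measured gap ≥ 150 ms
(segmentation error, not a plosive VOT), are dropped but still counted in
`n_attempted`.

**Feature conventions.**  COV = SD/mean with the sample (n−1) SD
everywhere.  `decrement_on_ioi` is ln(IOI_last/IOI_first)/N_IOI using the
raw first and last detected intervals — positive means slowing; the log base
and ratio direction are a documented convention, since "a logarithmic ratio
of first and last IOIs normalized by IOI count" admits either sign.  Onset
strengths are normalized per recording (max = 1).  Features whose defining
set is empty or whose denominator is zero are NaN, including the
speech-to-pause ratio when total pause is zero (never infinity).

## Statistical layer

**Families.**  Executive strategy is modeled as Poisson; the two error
counts as negative binomial (NB2), whose dispersion α is estimated jointly
by maximum likelihood, to absorb their overdispersion.  When data are
equidispersed the NB dispersion MLE sits at the boundary α → 0 where Newton
steps fail; the fitter detects this and reports the Poisson supremum
log-likelihood with infinite dispersion (size θ = 1/α).

**AICc.**  AIC = 2k − 2logL; AICc = AIC + 2k(k+1)/(n−k−1), undefined for
n ≤ k+1.  k counts intercept, slopes, and the NB dispersion (matching the
likelihood-based parameter count of the glm.nb/MuMIn-style toolchain this
analysis mirrors; switchable in principle by adjusting `k`).

**Nagelkerke R².**  R²_CS = 1 − exp((2/n)(logL₀ − logL₁));
R²_N = R²_CS / (1 − exp((2/n)·logL₀)), reported ×100.  Reported values use
the intercept-only model as the reference L₀, so the null covariate block
itself gets a non-zero R²_N and ΔR²_N is the increment from features.

**Exhaustive selection.**  For one (group, outcome, test): rows missing the
outcome, any null covariate or any *candidate* feature are dropped once, so
every fit shares the same n and AICc values are comparable.  The null model
(age, sex, 5-level ordinal education, psychiatric flag, HADS anxiety and
depression — education enters as ordinal-coded numeric) is always included;
every feature subset containing no forbidden pair is fitted with the null
block, no interactions.  ΔAICc = AICc_null − AICc_best with "significant"
meaning strictly > 2; the candidate set contains the feature models that both
beat the null by > 2 and lie within 2 AICc of the best; appearance rates are
per-feature fractions of candidate-set membership (empty when not
significant).  Ties in AICc break toward the smaller subset, and results are
invariant to feature enumeration order.  A subset too large for the case
count is flagged unrankable rather than aborting the run.

**Forbidden pairs.**  Pearson correlations are computed on
pairwise-complete observations per test (pooled across groups by default;
per-group is configurable, since the exclusion rule's grouping is a genuine
design freedom).  A pair is barred iff |r| strictly exceeds 0.6 in *all
three* tests.  Absolute r is used — collinearity is sign-agnostic.  An
undefined correlation leaves the pair selectable (conservative) and is
logged.

**Paired ROC comparison.**  Per test, logistic models (null covariates vs
null + all 19 features) are fitted on the same complete cases; apparent
(in-sample) predicted probabilities are scored by Mann-Whitney AUC with
half-credit ties, and compared with the DeLong paired test: placement-value
covariance estimation, normal reference, two-sided p.  The implementation
reproduces pROC's `roc.test(..., method="delong", paired=TRUE)` to 8
decimals on a fixture (frozen in the test suite).  No forbidden-pair
filtering is applied here (all features enter; collinear fits draw a
warning, and only score rankings matter for ROC).  No cross-validation is
attempted — this is an apparent-fit comparison by design.

## Synthetic data: what it emulates, what it does not

**Audio.**  Each repetition is a 10-ms broadband burst, a silent gap, and a
vowel modeled as a 3-harmonic tone (f0 ~ 90-260 Hz across participants) with
a 10-ms raised-cosine attack — enough periodicity structure for an
unambiguous voicing onset without formant synthesis.  `vot` in the generator
is the burst-onset→voicing interval, i.e. exactly the quantity the VOT
features measure.  IOIs are Gaussian around a mean with a linear drift
(±drift/2 from first to last), so the decrement feature's sign is
controllable.  Background noise is Gaussian at a target SNR defined on the
active-speech span (silence-heavy recordings would otherwise distort SNR).
Repetitions that would overflow the duration are truncated; every event time
is recorded in the manifest; identical seeds give bit-identical output.

**Cohort.**  Covariates follow the target population's published summaries:
age ~ N(67, 7.3²) truncated at 50; 28% male; 5-level education with
probabilities (0.10, 0.08, 0.20, 0.23, 0.39); psychiatric-diagnosis
probability 0.15 (HC) / 0.30 (SCI); HADS anxiety and depression as clipped
negative-binomial small counts with group-shifted means (5.0/6.5 and
2.5/4.7).  Each participant carries latent timing parameters (cycle time
0.22 ± 0.025 s, jitter 11 ± 4 ms, drift, VOT 45 ± 10 ms, syllable fraction,
SNR 30 ± 4 dB), shifted by `sci_shift` latent SDs in the SCI group;
per-test manifests are drawn from these latents ("pa" slightly faster,
"ka" slightly slower), and **true features are computed by applying the
feature formulas to the exact manifest event times** — the same pure
functions the extractor uses on detected events.  Outcomes are drawn from
log-link GLMs whose linear predictor is the null covariate block (modest
default coefficients, intercepts matching the published outcome means of
4.1, 7.7 and 3.2) plus planted per-feature effects on z-scored
participant-level true features.  The executive score is generated as
1 + Poisson(exp(η)) to respect its floor of one (its minimum attainable
value); η is the log-mean of the excess.  The NB size parameter defaults to
1.2, chosen so simulated error-count variances match the published
mean/variance ratios.  Recordings go missing independently at 7% by default,
mirroring the ~6-9% per-test exclusion rates of the motivating study.

**Limitations.**  The synthetic vowel has no formant structure, no
coarticulation, no amplitude decline or fatigue; noise is stationary
Gaussian rather than household non-stationarity; repetition timing is
Gaussian rather than heavy-tailed.  Passing the validation grid therefore
shows the *implementation* recovers known timing structure under controlled
degradation — it does not certify accuracy on real dysarthric or
reverberant speech, and equivalence with the proprietary segmentation/VOT
method the feature definitions functionally re-implement cannot be
established without that system.

## Validation design and problem sizes

The acceptance suite checks, per run: exact hand-computed feature values
(1e−9); onset recall/precision ≥ 0.95 (50-ms matching tolerance), IOI-mean
error ≤ 5% and VOT error ≤ 5 ms over a 36-cell grid (rate 2-7/s × SNR
20-40 dB × jitter 0-20 ms); identity of the exhaustive-selection AICc
ranking and R²_N values with a direct scipy-optimized refit of all 32
subsets of 5 features at n = 300 (1e−6); a ≤ 10% false-positive rate of the
ΔAICc > 2 rule under a 1000-replicate null at n = 500 (theory:
P(χ²₁ > ≈4) ≈ 4.6%) and ≥ 80% power for a 0.3-per-SD effect at n = 800
(200 replicates); the forbidden-pair contract on a naturally collinear pair
(ioi_mean vs inverse_ioi_mean, |r| ≈ 0.99 in all three tests); the DeLong
test's level within [3%, 7.5%] under a 1000-replicate equal-true-AUC null
(two score vectors sharing a latent, independent noise — comparing nested
*in-sample* fits with noise features would instead measure apparent-fit
optimism, which is a property of in-sample evaluation, not of the test);
and the end-to-end 18 + 3-row report contract on a 200-participant
audio-path run with byte-identical rerun determinism (asserted at n = 40).
These sizes keep the full suite to a few minutes on one CPU while leaving
every Monte-Carlo margin wide against its threshold.

## Known limitations and degenerate inputs

- All-silent input: denoise is a fixed point; normalize raises.
- Fewer than 2 (or 3) onsets: IOI (or dispersion) features are NaN, never
  raised; an empty envelope yields an empty onset series.
- One continuous utterance: a single speech interval, zero pauses,
  pause-derived features NaN.
- The onset-lag and VOT attack-compensation constants are calibrated to the
  synthetic burst/vowel shapes; real plosives with slow bursts may need
  recalibration.
- In-sample AUCs are optimistic by construction; the paired comparison is
  of apparent fits, as in the supplementary design it mirrors.
- The study-shaped default of 19 features would mean 2¹⁹ subsets before
  pruning; the pipeline defaults to a 7-feature cross-section of the six
  quality groups (2⁷ subsets before forbidden-pair pruning) with the full
  set available behind `selection_features`/`max_features`.
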