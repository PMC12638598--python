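# pataka

Diadochokinetic (DDK) motor-speech analysis for cognitive-screening research:
extract acoustic performance features from rapid "pa"/"ta"/"ka" repetition
recordings, and test whether those features improve count-GLM estimation of
episodic-memory, executive-function and working-memory scores beyond
demographic and clinical covariates.

## Who this is for

Researchers studying speech as a digital biomarker of early cognitive
decline.  A DDK trial asks a participant to repeat a plosive-initial syllable
("pa-pa-pa…") as fast as possible for ten seconds; the timing and regularity
of the repetitions reflect motor-speech control, which in older adults
carries signal about cognition.  `pataka` implements the full analysis chain
for such trials, plus a synthetic-data layer so every stage can be validated
against known ground truth (useful because real clinical cohorts of this kind
are rarely shareable).

## What it computes

**19 motor-speech features per recording**, in six quality groups:

| group | features |
|---|---|
| onset | onset count, onset rate (count / total duration) |
| inter-onset interval | IOI mean, IOI SD, inverse min IOI, decrement on IOI = ln(IOI_last/IOI_first)/N_IOI, inverse-IOI mean, inverse-IOI COV |
| syllable | articulation rate (syllables / speech time), syllable duration mean & COV, speech %, speech-to-pause ratio |
| pause | pause mean, pause COV, pause % |
| voice onset | VOT mean, VOT COV (VOT = burst onset → voicing onset) |
| energy | COV of normalized onset strengths |

COV is SD/mean throughout, with the sample (n−1) SD.

**Model selection.** For each (group × outcome × DDK test) cell the package
fits a null count GLM — age, sex, education, psychiatric diagnosis, HADS
anxiety and depression, log link; Poisson for the executive-strategy score,
negative binomial (NB2, ML dispersion) for the memory error counts — and
every feature subset that contains no *forbidden pair* (features with
|Pearson r| > 0.6 in all three DDK tests are barred from co-occurring).
Models are ranked by AICc = 2k − 2logL + 2k(k+1)/(n−k−1); the feature set
"wins" when ΔAICc = AICc_null − AICc_best > 2.  Nagelkerke pseudo-R²
(in %, relative to the intercept-only model) quantifies variance explained,
and per-feature appearance rates summarize the candidate set (significant
models within 2 AICc of the best).

**Classification.** Per DDK test, logistic models with and without all 19
features are compared on apparent ROC curves with the paired DeLong test.

## Worked example

```python
from pataka import SyllableTrainSpec, synthesize_ddk_recording, extract_features
from pataka.preprocess import preprocess_recording

spec = SyllableTrainSpec(sample_rate=16000, duration=10.0, n_repetitions=40,
                         ioi_mean=0.25, ioi_sd=0.012, vot=0.040, snr_db=30, seed=1)
rec, manifest = synthesize_ddk_recording(spec)
features = extract_features(preprocess_recording(rec))
```

prints (see `examples/01_synthesize_and_extract.py`):

```
true repetitions: 38, true IOI mean: 0.2505 s, true VOT: 40.0 ms
  onset_count          = 38.0000
  onset_rate           = 3.8000
  ioi_mean             = 0.2505
  ioi_sd               = 0.0118
  vot_mean             = 0.0417
  speech_percent       = 48.1200
  articulation_rate    = 7.8969
```

The extractor recovers the onset count exactly, the IOI mean to 4 decimal
places, and the 40-ms VOT within 2 ms.  `examples/02_model_selection.py`
plants a 0.3-per-SD effect of IOI variability on episodic-memory errors in a
400-participant cohort and the selection run reports ΔAICc ≈ 20.8 with the
planted feature at a 100 % appearance rate; `examples/03_roc_comparison.py`
and `examples/04_full_pipeline.py` cover the classification comparison and
the complete 18-run study design (also available as `pataka run-all`).

## Layout

- `src/pataka/synth.py` — DDK audio generator + cohort simulator (ground truth)
- `src/pataka/preprocess.py` — WAV ingestion, screening, spectral-gating denoise
- `src/pataka/onsets.py` — spectral-flux onset detection, onset/IOI features
- `src/pataka/segments.py` — speech/pause segmentation, VOT, timing features
- `src/pataka/features.py` — feature table assembly, correlations, forbidden pairs
- `src/pataka/models.py` — count GLMs, AICc, Nagelkerke R², exhaustive selection
- `src/pataka/roc.py` — logistic scoring, AUC, paired DeLong comparison
- `src/pataka/pipeline.py`, `cli.py` — end-to-end orchestration and CLI

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
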