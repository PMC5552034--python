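# Methods

This note documents the models and operational definitions implemented in
`sstcoach`, the defaults and why they were chosen, what the synthetic
fixtures do and do not emulate, and the numerical corner cases.

## Visual features

### Landmark geometry

Input is a 66-point facial-landmark track with per-frame head pose (yaw,
pitch, roll in degrees).  The point groups follow the common
constrained-local-model layout (17 jaw, 10 eyebrow, 9 nose, 12 eye, 18 mouth
points).  Six geometric features are computed per frame:

| feature | definition (defaults) |
| --- | --- |
| outer_eyebrow_height | mean vertical distance, outer brow ends {17, 26} to outer eye corners {36, 45} |
| inner_eyebrow_height | inner brow ends {21, 22} to inner eye corners {39, 42} |
| outer_lip_height | outer upper-lip {50–52} to outer lower-lip {55–57} |
| inner_lip_height | inner upper-lip {60–62} to inner lower-lip {63–65} |
| eye_opening | upper lids {37, 38, 43, 44} to lower lids {40, 41, 46, 47} |
| lip_corner_distance | Euclidean distance between mouth corners {48, 54} |

All six are divided by the inter-ocular distance (distance between the
centroids of the two eye contours).  The normalization is not part of any
published recipe we follow; it is required so the representation is invariant
to recording distance and image resolution, and the tests assert exact
translation/scale invariance.  The feature→index mapping is a configuration
default (`sstcoach.config.DEFAULT_INDEX_MAP`, overridable via the `visual:`
section of a YAML file): the literature names these features but not their
indices, so the mapping is a documented choice, auditable and replaceable.

### Smile classifier and smiling ratio

A linear-kernel SVM (scikit-learn `SVC(kernel="linear")`, C = 1.0) is trained
on standardized features (training mean/sd) from happy and neutral exemplars.
Per frame, *smiling* requires a strictly positive decision value; an exact
zero classifies as neutral — smiling requires positive evidence.  The smiling
ratio is the fraction of frames labelled smiling, with **no temporal
smoothing**: the per-frame definition is the contract.  Frames with missing
(NaN) landmarks are excluded from both numerator and denominator, with a
logged count, because tracker dropouts are routine and silently counting them
either way would bias the ratio.

A constant training feature is an error by default (`on_constant_feature=
"drop"` zeroes its weight with a warning instead).  Constancy is detected by
exact range (`max − min == 0`), not by `sd == 0`, because the sample sd of a
constant column can round to ~1e−16.

### Head pose

`yaw_abs_mean` is the mean of |yaw| (any turn away from frontal counts,
regardless of side); `pitch_mean` is the signed mean (facing up and facing
down are distinct behaviors, so the sign is preserved; positive = down).
Units are degrees; the CSV reader converts radians when told
`angle_unit="rad"`.

## Prosodic features

The seven audio/linguistic features are named by the feedback design but
their internal definitions are this package's own, fixed in
`ProsodyConfig` and chosen to be standard and reproducible:

- **Framing**: 40 ms windows, 10 ms hop.
- **Silence**: a frame is silent below −35 dBFS RMS.  Silent runs of at least
  300 ms count as pauses; `pause_ratio` = total pause time / clip duration.
  A run of k frames spans (k−1)·hop + frame_length seconds (first-frame start
  to last-frame end), which recovers a scheduled silence to within one hop.
- **F0**: per-frame autocorrelation search in 75–500 Hz.  The frame is
  Hann-windowed and its autocorrelation divided by the window's own
  autocorrelation, which removes the linear taper bias of the raw estimator;
  among candidate peaks within 10% of the strongest, the smallest lag wins
  (suppressing octave-down errors); parabolic interpolation refines the lag.
  A frame is voiced when the normalized peak exceeds 0.5.  On steady tones the
  residual estimator noise is ~3×10⁻⁴ semitones; test tolerances are set an
  order of magnitude above that (0.05 semitones for `f0_variation`, 0.01 for
  `voice_quality`).
- **f0_variation**: sample sd (n−1) of voiced-frame F0 in semitones
  (12·log₂(F0/100 Hz); the reference cancels in the sd).
- **amplitude**: mean per-frame RMS in dBFS over speech frames.  Halving the
  waveform lowers it by exactly 20·log₁₀(2) ≈ 6.02 dB.
- **voice_quality**: mean |ΔF0|/F0 over consecutive voiced frame pairs — a
  jitter-like perturbation measure, 0 for a perfectly steady voice.

On an all-silent clip, F0 variation, amplitude, and voice quality are
**undefined and returned as `None`**, never as zeros: a zero would read as
"perfectly steady, very quiet speech", which is the opposite of "no speech".

Linguistic features operate on pre-tokenized transcripts (the target language
is Japanese; bundling a morphological analyzer is out of scope): words per
minute = 60·tokens/duration; long words = tokens with strictly more than six
characters (a literal reading of "over six"); fillers = exact lexicon matches
after case-folding, every occurrence counted.  The default lexicon is a small
Japanese filler set (eto, anou, maa, nanka, …), fully replaceable.

## Feedback engine

z-scores use the cohort sd with the n−1 denominator, so z-scoring each cohort
row against its own cohort yields exactly mean 0 / sd 1 per feature (a test
invariant).  A zero-sd feature is an error naming the feature — a degenerate
cohort must not silently produce infinite z.

The overall score is an identity-link Gaussian GLM — ordinary least squares —
of rated narrative skill (rescaled to 0–100) on four features: words per
minute, amplitude, long-word count, smiling ratio.  "Generalized linear
regression to a 0–100 score" admits several readings; the identity/Gaussian
one is the simplest consistent with a continuous bounded score, with clipping
to [0, 100] providing the range control.  The fit reports the leave-one-out
predicted-vs-true Pearson correlation (`loo_r`).  Because raw-scale and
standardized-design fits give identical predictions, both are exposed
(`standardize=`) and the mode used is recorded on the model.  No published
coefficient set exists; the shipped workflow fits the model on synthetic
cohort+rating data (or the user's own), and the method — not any specific
weight vector — is the deliverable.

Comment selection works on distances d_f = |z_f|: the **positive** comment
praises argmin d_f; the **improvement** comment targets the feature at the
median rank of d sorted ascending — not the farthest, because asking a
trainee to attack their single worst behavior first is counterproductive.
Conventions the policy needs but that were genuinely open:

- even feature count → the lower middle rank;
- distance ties → canonical feature-order position (stable, input-order
  independent);
- exactly two features → the median rank (0) coincides with the positive
  feature, so the improvement target bumps to rank 1, keeping the report's
  two comments distinct;
- signed features (e.g. pitch) are compared via |z| exactly like the others —
  the radar chart treats all axes uniformly.

Comment text is template-driven per (feature, direction-of-deviation), with
English and Japanese packs; the selection policy, not the wording, is the
contract.

Two feature presets exist: FULL (3 visual + 7 audio/linguistic) and ASD5
(pitch, words per minute, amplitude, long words, smiling ratio) — the reduced
set used when too many feedback axes would overwhelm the trainee.

## Session state machine

The five steps run as a pure transition table: instruction →(start)→
modeling →(user_start_roleplay)→ roleplay →(roleplay_timeout)→ feedback
→(assign_homework)→ homework →(finish)→ done, with feedback →(repeat)→
modeling loops (disable via `allow_repeats=False`) and a `feedback_viewed`
self-loop.  The role-play exits **only** on the timeout at the configured
duration (default 60 s).  `advance(state, event, config)` is a pure function;
rejected events raise with the list of allowed ones.  The avatar's nods are
fixed-interval log events (default every 8 s) — the original interaction
specifies nodding but no timing, and rendering is out of scope.  `run_roleplay`
is atomic: if the output sink fails, the state is unchanged and no artifact is
recorded, so a feedback report can exist only after a completed role-play
(enforced by `attach_report` and verified by exhaustive enumeration of all
event sequences to depth 8).

## Evaluation statistics

- Paired t on **pre − post** differences (df = n−1): improvement gives a
  negative t.  This sign convention is deliberate and prominent.
- Two-sample t is the pooled-variance Student's test (df = n₁+n₂−2).
- Both one- and two-tailed p-values are always reported; the caller picks the
  tail.  (For the bundled table, t(9) = −4.0 gives one-tailed 0.0016 and
  two-tailed 0.0031.)
- Cohen's d uses the pooled-sd-of-two-groups convention
  √((s₁²+s₂²)/2); the d-of-differences convention gives a different number
  and is not what this package computes.  d is invariant under common shifts
  and common positive rescaling of both groups.
- Rater agreement binarizes each rater's scores against that rater's own
  mean; values exactly at the mean count as "high" (a documented convention —
  some boundary must be chosen).
- Degenerate inputs (zero variance of differences, zero pooled sd, constant
  correlation input) raise rather than returning ±inf/NaN.

The bundled rating table (`sstcoach/data/asd_pre_post_ratings.csv`) holds the
ten participants' pre/post narrative-skill ratings on a 1–7 Likert scale with
ages and the three available follow-up scores; `load_rating_table` validates
scale bounds and id uniqueness.

## Synthetic fixtures

The generators are pure functions of (spec, seed) and return analytic ground
truth computed from the specification, never measured back from the output.

- **Face templates** are constructed schematic faces (raised/widened lip
  corners, parted lips, raised brows, slightly narrowed eyes for the happy
  face) — synthetic geometry, not derived from any face database.  Training
  clusters place class centers at the two templates' features with
  within-class noise sd = |center difference| / separation (default 3 sd,
  default counts 31 happy / 30 neutral).
- **Tracks** place smile episodes as contiguous blocks (default 30 frames) —
  more realistic than i.i.d. frame labels — totalling round(fraction · n)
  frames; yaw/pitch follow Gaussian random walks around configurable offsets;
  per-frame landmark jitter (default 0.4 px) emulates tracker noise.  The
  defaults emulate the one-minute role-play at 30 fps.
- **Audio** is a three-harmonic tone (amplitudes 1, ½, ¼) at a base F0
  (default 150 Hz) with optional per-10-ms F0 jitter and scheduled digital
  silences; the seed changes the starting phase and jitter draws but never
  the truth values.
- **Cohorts** draw each feature from a declared normal distribution with
  plausible magnitudes for one-minute narratives (e.g. smiling ratio
  0.40 ± 0.10, 120 ± 20 words/min, −25 ± 3 dBFS); **ratings** are a declared
  linear combination of the four score features plus Gaussian noise
  (default sd 5 on the 0–100 scale).

What the fixtures do **not** emulate: real facial appearance or tracker
failure modes beyond i.i.d. jitter and NaN dropouts; coarticulated speech
(formants, consonants, breaths — the surrogate is a harmonic tone, so the F0
tracker faces a much easier problem than real voice); natural language
(transcripts are token lists); and any population-specific behavior
distribution — no quantitative description of ASD-specific feature
distributions is available, so none is simulated.  Passing recovery tests
therefore demonstrates the pipeline's correctness on signals with known
truth, not field performance on real recordings.

## Problem sizes and numerical choices

The recovery suites run twenty 600-frame tracks (20 s at 30 fps) for the
smile pipeline and 8–10 s clips at 16 kHz for prosody — sizes at which every
recovery error observed is at least an order of magnitude under its
tolerance (smiling-ratio error ≤ 2/n frames against a ≤ 0.02 band; pause
ratio recovered exactly against a one-hop band).  OLS uses `numpy.linalg.lstsq`
(SVD); the test suite verifies it against an explicit normal-equations solve
to 1e−8.  Rank-deficient designs are rejected up front via an explicit rank
check.  Leave-one-out refits the model n times; n is small everywhere this
runs.

## Known limitations

- The smile classifier's accuracy is only ever demonstrated on self-consistent
  synthetic geometry; applying it to a real tracker's output requires
  retraining on real exemplars and possibly a different index map.
- The leave-one-out correlation of the score model on synthetic data
  (≈ 0.76 at the default signal/noise settings) characterizes the generator,
  not any human rating process.
- "Words over six letters" counts token characters; for Japanese this means
  whatever unit the upstream tokenizer emits, and morae/romanization
  distinctions are the caller's responsibility.
- The session machine models a single session; multi-week homework tracking
  is out of scope.
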