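# Methods

## The problem and the analysis unit

In background noise, speakers involuntarily and communicatively enhance
their speech — louder voice, higher pitch, larger mouth movements (the
Lombard effect). In face-to-face interaction the message is multimodal:
manual gestures carry meaning alongside speech. `lombardkit` implements an
analysis of whether, and how, noise modulates the *whole* multimodal
signal: speech acoustics, visual speech (face kinematics), and gesture
kinematics, and whether acoustic and kinematic enhancement trade off
against each other depending on modality.

The unit of analysis is the **communicative attempt**: a spoken utterance,
a gesture, or a multimodal (speech + gesture with temporal overlap) unit
separated by at least 200 ms from any other communicative behavior.
Annotation intervals are half-open `[onset, offset)` in milliseconds, so
abutting events share no time and the 200 ms rule is unambiguous:
consecutive behaviors belong to the same attempt iff their gap is < 200 ms
or they overlap. Only the first attempt of each round (one word, one noise
condition) is analyzed; later attempts reflect a strategy evolving under
addressee feedback. An attempt containing both speech and gesture with
zero overlap is a boundary case the annotation scheme does not define; it
is labeled by the kind with the larger total duration and flagged
`mixed_no_overlap` so reports can surface it.

## Features

Per attempt, nine features (speech features only where speech occurs,
gesture features only where gesture occurs):

| feature | definition | units |
|---|---|---|
| max intensity | max of windowed-RMS dB over the union of utterance intervals | dB re. full scale |
| max F0 | max autocorrelation pitch over voiced frames in utterance intervals | Hz |
| max mouth opening | max over frames of max pairwise distance among inner-mouth landmarks | m (reported mm) |
| mean lip movement | lower-lip path length / time covered by the attempt span | m/s (mm/s) |
| peak lip velocity | max smoothed lower-lip speed | m/s (mm/s) |
| peak velocity | max smoothed hand speed over hands involved in the gesture | m/s |
| max distance | max hand excursion from its position at gesture onset | m |
| vertical amplitude | highest 0–5 height band reached by either hand | ordinal |
| holdtime | total time all involved hands are below the stillness threshold | s |
| submovements | supra-threshold movement segments, splitting merged segments at prominent velocity peaks | count |

Height bands (per frame, from that frame's landmark heights): 0 below
torso middle; 1 torso middle to upper quarter; 2 within the upper quarter;
3 above the shoulders; 4 above mid-face; 5 above the head. Per-frame
references are the default (a switch is not provided because the
generator's bodies are static; with real data a per-frame reference also
absorbs posture drift).

Tunable kinematic constants, surfaced in every report: stillness threshold
0.15 m/s; minimum hold duration 0.1 s; velocity-peak prominence 0.05 m/s;
centered 3-frame moving-average smoothing, sized against single-frame
tracker jitter at ~30 Hz. `max_distance` measures from the gesture-onset
hand position; a body-referenced variant (distance from the torso center)
is available via `reference="body"`. Missing track frames are linearly
interpolated up to 3 consecutive frames; longer gaps split the computation
window. Tracks are assumed head-stabilized; an optional nose-bridge
subtraction exists for face tracks but is off by default.

Acoustics are computed from mono audio as windowed RMS energy (40 ms
Hanning frames, 10 ms steps) in dB re. digital full scale — the analysis
uses within-subject contrasts, so an SPL calibration offset cancels — and
autocorrelation pitch (75–500 Hz search, voicing threshold 0.45 on the
normalized autocorrelation peak, parabolic lag interpolation). Precomputed
contour CSVs are accepted on equal terms and agree with the audio path on
synthetic fixtures. Attempt maxima are taken strictly over annotated
utterance intervals so non-speech sound between utterances cannot leak in.

Aggregation across multiple gestures in one attempt: maxima for extremal
features (peak velocity, distance, amplitude), sums for additive ones
(holdtime, submovements), preserving the reading of submovements as the
amount of segmented visual information per attempt.

A note on counting: the submovement count is guaranteed non-increasing in
the prominence criterion. It is also non-increasing in the stillness
threshold for profiles that rise from rest when every interior peak is
counted, but not for arbitrary arrays — raising the threshold can split a
segment whose maximum sits on the segment edge into two counted segments.
The property tests state exactly this domain.

## Statistical models

One model per feature, fixed effect = noise condition (3 levels, treatment
coding, clear = reference), crossed random intercepts for participant and
item. Families: gaussian for the continuous features; Poisson (log link)
for submovement counts and gamma (log link) for holdtime — chosen by AIC
against the gaussian alternative on otherwise-identical fits, an
automatable surrogate for visual residual inspection, with residual
diagnostics emitted; cumulative-logit (proportional odds) for the ordinal
vertical amplitude, assessed on its coefficients.

All fits are maximum likelihood (never REML), so nested models compare by
likelihood ratio. Gaussian fits use the profiled deviance (exact ML; one
Cholesky per variance evaluation). Poisson, gamma, and cumulative-logit
fits use a Laplace approximation: Newton on the joint penalized
log-likelihood over fixed + random coefficients inside, Nelder–Mead over
log standard deviations (plus log shape for gamma) outside. For a CLMM
with a single random factor, adaptive Gauss–Hermite quadrature is
available (`nagq > 1`); with the study's crossed factors the Laplace
approximation (= one-node quadrature) is the estimator. Wald covariances
condition on the variance parameters, the usual mixed-model convention;
the parameter-recovery suite checks that the resulting 2-SE intervals
actually cover.

**Random slopes.** Condition slopes are *diagonal with one shared SD* per
grouping factor: the two non-reference condition dummies share a single
slope standard deviation, with no intercept–slope correlation. This keeps
the variance-parameter space small, makes the singularity fallback
deterministic, and matches the synthetic generator exactly. It is
deliberately more parsimonious than a full 3×3 slope covariance; with real
data the full structure would hit singularities more often and the ladder
would fall back earlier.

**The ladder** (deterministic; no randomness anywhere):

1. Null random structure: participant intercept always; the item intercept
   is kept iff it improves the null fit by likelihood ratio (α = 0.05).
2. Full model: condition fixed effect plus condition slopes for each
   retained grouping factor. On a singular fit the slope with the smaller
   variance is dropped (participant slope on an exact tie — the item
   structure is sparser); if still singular, intercepts only. A component
   is singular when its variance is below 1e-6 of the response variance
   (variance of `log(y + 0.5)` for the log-link families, 1 on the logit
   scale), or when forcing it to the boundary changes the deviance by less
   than 2e-3 — the boundary probe catches optimizer stalls above the floor.
   Whether a zero-variance truth is *detected* as singular is data-
   dependent (roughly the usual boundary probability), as in any ML fit.
3. The condition effect is tested against a null refit with the *same*
   random structure, so the reference distribution is a clean χ²(2). The
   comparison against the intercepts-only null — which mixes fixed- and
   random-structure differences and yields larger dfs — is also computed
   and logged, since ladders of this kind are often reported that way; it
   is not used for the calibrated decision. Interaction analyses test the
   model with modality, noise, and modality × noise terms against the
   noise-only null (df = 3 for the 3×2 design: a modality dummy plus two
   interaction terms) — the comparison ladders of this kind report — and
   additionally emit the stricter interaction-only comparison against the
   main-effects model (df = 2).
4. Pairwise condition contrasts come from estimated marginal means with
   random effects held at zero (population level), averaging over any
   other fixed factor; differences on the identity scale, ratios on log
   links; Tukey adjustment via the studentized range (residual df for
   gaussian, asymptotic otherwise).

Multicollinearity is screened before modeling: VIF_j = 1/(1−R²_j) from
regressing feature j on the others over complete cases, excluding features
with VIF > 3 (infinite for exact collinearity). Only multimodal attempts
have all nine features, so complete cases are the multimodal subset; the
screen is skipped with a trace entry when fewer than 5·(k+1) complete
cases exist. Outlier sensitivity refits every non-ordinal model after
removing responses above mean + 3 SD and reports whether the significance
pattern agrees. Holdtime values of exactly zero (a gesture without a
detectable hold) are left-censored at the frame resolution and shifted to
half a frame (1/60 s) before gamma fitting, with a trace entry.

## The synthetic generator

The generator's defaults are the study conditions: 58 producers × 20
items, the noise condition drawn uniformly per round, modality drawn per
round from the observed per-condition proportions (from the published
modality-usage counts), crossed participant/item random intercepts, and
condition shifts at the published point estimates where the study reports
them — intensity (0, +0.12, +0.29) dB, submovement log-rate (0, log 1.093,
log 1.142). Where the study reports no point estimate the defaults are
free parameters, not claims: holdtime multiplicative effects (1, 1.05,
1.10) with gamma shape 3 and a participant slope SD of 0.25 on the log
scale (the study found holdtime effects dominated by slope
heterogeneity); mouth-opening shifts (0, 0.4, 0.7) mm with a participant
slope SD of 0.8 mm; vertical-amplitude latent-logit effects (0, −0.07,
−0.12) (the study found no amplitude effect); F0 effects zero (the study
found none, attributing it to F0 saturation in loud speech). Variance
components (participant SD 2 dB for intensity, etc.) are likewise
documented defaults, since per-condition variance components are not
published. Per-participant slope heterogeneity is Gaussian with mean equal
to the fixed effect, drawn per condition dummy — some participants
positive, some negative, matching the reported individual differences.
`intensity_effect_scope="speech_only"` confines the intensity shift to
speech-only attempts, expressing the study's flexible-enhancement
configuration.

One caveat on modality frequency: the generator encodes the *marginal*
per-condition modality proportions, whose multimodal share is slightly
lower in 8-talker babble than in clear. A within-participant ordinal model
of multimodality on such data therefore tends toward a negative
8-talker coefficient, whereas the study reported a weak positive
conditional trend — marginal and conditional summaries of the same design
can differ, and the synthetic runs reflect the marginal truth they encode.

Two layers. `generate_latent_table` draws the per-round feature values
directly from this mixed-effects structure (fast; the surface for
parameter-recovery simulation). `generate_dataset` additionally renders
body tracks, face tracks, acoustic contours, and annotation tiers whose
*extracted* features equal the latent values, giving every extractor a
round-trip oracle:

- **Gestures** are minimum-jerk velocity pulses (speed shape
  `16 τ²(1−τ)²`, closed-form peak `1.875 L/T`). The first pulse reaches
  the apex (height set by the target amplitude band; the excursion is the
  target max distance, raised when the band requires a higher reach);
  further submovements traverse a small diamond around the apex whose
  turns are all 90°, so blended pulses keep a supra-threshold saddle and
  are counted by peak prominence. Blending aims each saddle at a level
  between the stillness threshold and the adjacent peaks using the angle
  between leg directions. Requested holds become explicit plateaus whose
  duration is shrunk by the closed-form sub-threshold tail time of the
  adjacent pulses (plus a smoothing compensation of 0.75 frame), so the
  *extracted* holdtime equals the target; holds too short to survive the
  extractor's smoothing (< min_hold + tails) are not renderable and the
  achieved value is recorded as the truth. The annotated gesture span runs
  from just before the first threshold crossing to just after the last
  (plus any end hold); the retraction back to rest falls outside the
  annotation, as an annotator excludes post-gesture recovery movement.
  The max-distance truth is evaluated on the continuous trajectory from
  the hand position at the annotated onset.
- **Lips** perform full open–close aperture cycles (`a sin²`), closed at
  every cycle boundary, with amplitudes solved so the total path equals
  the target and the first cycle at the full opening; the first cycle's
  duration is solved so the *extracted* (discretized, smoothed) peak
  velocity equals the target, using the closed-form discrete-time response
  of the extractor; cycles never get shorter than 8 frames, where that
  response model holds. When an utterance is too short for its path share,
  cycles are dropped or compressed and the achieved values are recorded.
- **Contours** place each utterance's intensity maximum exactly at the
  configured per-attempt value (second utterances 1.5 dB quieter), with F0
  declining from its onset maximum and absent outside utterances.

What rendering does *not* emulate: real tracker dropout and occlusion
(only small Gaussian jitter, 0.5 mm body / 0.02 mm face), head motion,
coarticulation (lips idle between cycles), reverberant audio, annotator
disagreement, or addressee behavior. Passing round-trip tests therefore
show the extractors invert this generative family — not that they are
robust to every artifact of real capture. Rendering accuracy, asserted in
the tests: acoustic maxima exact; amplitude bands and submovement counts
exact; max distance ±1 cm; peak velocity ±7%; mouth opening ±0.8 mm;
holdtime ±0.22 s (±2 frames per hold run); mean lip movement ±6 mm/s
(frame noise inflates path length on mostly-still multimodal spans).
About 20% of rounds get a second attempt and 30% of utterance sets a
second utterance, exercising the first-attempt filter and the
utterance-interval rule.

## Verification design

- **Oracles.** Closed forms (sinusoid peak `2πfa`, min-jerk peak
  `1.875 L/T`, dB ratio `20 log₁₀ 2`, VIF `1/(1−R²)`); brute-force scans
  (pairwise distances, transitive-closure segmentation, peak counting) on
  small fixtures; R `lme4` via `Rscript` as an independent mixed-model
  oracle (gaussian log-likelihood and coefficients to 1e-3; Poisson and
  gamma coefficients to 5e-3); statsmodels MixedLM/GLM/Logit/OrderedModel
  as fixed-effects reduction oracles.
- **Calibration.** Type-I error of the full selection + LRT ladder under a
  null truth, 500 simulated studies at 24 participants × 10 items (a size
  chosen to make 500 replicates cheap; calibration is a property of the
  procedure, not of n), must lie in [0.03, 0.07] at α = 0.05.
- **Recovery.** 100 replicates per family at the full 58 × 20 design with
  the generator at its default effects; each condition coefficient must
  fall within 2 estimated SEs of its truth in ≥ 90% of replicates, for
  gaussian, Poisson, gamma (with the participant slope in truth and
  model), and cumulative-logit fits.
- **Signature.** With acoustic enhancement confined to speech-only
  attempts and kinematic enhancement in all gesture-bearing attempts, the
  interaction analysis must find a significant noise × modality effect for
  intensity and none for submovements in ≥ 80% of 50 replicates.

## Known limitations

- Laplace (not quadrature) likelihoods for crossed-factor GLMMs; fixed
  effects agree with `lme4` to ~1e-2 on the intercept and ~5e-3 on
  contrasts at the study's size, but very sparse designs would degrade.
- Wald SEs condition on the variance parameters; no Kenward–Roger-style
  correction.
- The diagonal shared-SD slope structure cannot express intercept–slope
  correlation or per-condition slope variances.
- The proportional-odds assumption of the ordinal model is not tested.
- The acoustic dB scale is relative to digital full scale, not SPL.
- The generator renders one gesturing hand (the dominant hand); handedness
  metadata selects which hand the extractors emphasize, but bimanual
  coordination is not simulated.
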