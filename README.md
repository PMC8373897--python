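# lombardkit

Multimodal Lombard-effect analysis: when people communicate in background
noise, do they only speak louder, or do they also enhance their visible
signals — mouth movements and manual gestures — and does the acoustic
effort depend on whether a gesture is present?

`lombardkit` is a reusable pipeline for dyadic word-communication
experiments of this kind. It takes annotation tiers (ELAN EAF or CSV),
body and face keypoint tracks (Kinect-style, ~30 Hz), and audio or
precomputed intensity/F0 contours, and produces the full analysis:

- **Segmentation** of *communicative attempts* — speech, gesture, or
  multimodal units separated by ≥ 200 ms from any other communicative
  behavior — keeping only the first attempt per round.
- **Feature extraction**: per attempt, maximum speech intensity and F0
  (over annotated utterance intervals only); maximum mouth opening, mean
  lip movement, and peak lip velocity from facial landmarks; and peak
  velocity, maximum distance, ordinal vertical amplitude (0–5 height
  bands), holdtime, and submovement count from hand kinematics.
- **Inference**: for each feature, a generalized linear mixed model with
  noise condition as fixed effect and crossed random intercepts for
  participant and item — gaussian, Poisson (submovement counts), gamma
  (holdtimes), or cumulative-logit (ordinal amplitude) — with a
  deterministic random-slope selection ladder, likelihood-ratio tests,
  Tukey-adjusted marginal-means contrasts, noise × modality interaction
  analyses, a modality-frequency model, a VIF multicollinearity screen,
  and a mean + 3 SD outlier-sensitivity re-run.
- **A synthetic-study generator** that emulates the full design (58
  producers × 20 items, three noise conditions, random participant/item
  effects, per-participant slope heterogeneity) and renders tracks,
  contours, and tiers whose extracted features equal a known ground
  truth, so every stage has a parameter-recovery test surface.

The model at the core, for feature $y_{pic}$ of participant $p$, item $i$,
condition $c \in \{\text{clear}, \text{babble4}, \text{babble8}\}$:

$$g\!\left(\mathbb{E}\,y_{pic}\right) = \beta_0 + \beta_c + u_p + w_i
\;(+\, s_{pc}),\qquad u_p \sim \mathcal N(0, \sigma_u^2),\;
w_i \sim \mathcal N(0, \sigma_w^2),\; s_{pc} \sim \mathcal N(0, \sigma_s^2),$$

fit by maximum likelihood (profiled deviance for gaussian, Laplace
approximation otherwise), tested by $\chi^2$ likelihood ratio against a
structure-matched null. The mixed-model engine is implemented in the
package and validated against R `lme4` in the test suite.

## Worked example

```python
from lombardkit.inference import noise_effect_analysis
from lombardkit.synthetic import CONDITIONS, GeneratorConfig, generate_latent_table

table = generate_latent_table(GeneratorConfig(seed=1))  # 58 x 20 rounds
res = noise_effect_analysis(table, "max_intensity_db", "gaussian", list(CONDITIONS))
print(f"chi2({res.lrt.df}) = {res.lrt.chisq:.2f}, p = {res.lrt.p:.4f}")
print(res.contrasts.rows.round(4).to_string(index=False))
```

prints

```
chi2(2) = 21.20, p = 0.0000
         contrast  estimate  ratio     se   stat  p_adj
  babble4 - clear    0.1419    NaN 0.0698 2.0336 0.1053
  babble8 - clear    0.3293    NaN 0.0707 4.6584 0.0000
babble8 - babble4    0.1874    NaN 0.0733 2.5575 0.0291
```

— the generator's configured +0.29 dB intensity shift in 8-talker babble
is recovered at 0.33 ± 0.07 dB, significant against clear after Tukey
adjustment, with no reliable 4-talker shift, mirroring the structure of a
classic Lombard result. `examples/` contains one short script per
capability (generation, segmentation, extraction, model fitting, full
pipeline); `docs/methods.md` describes the models, the generator, and
every default.

From the shell:

```bash
lombardkit generate --seed 1 --participants 6 --items 8 --out data/
lombardkit run-all --config config.yaml --out report/
```

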