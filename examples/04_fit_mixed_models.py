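"""Fit the study's mixed models directly.

The inference ladder for one feature: pick the null random structure, try
condition random slopes (dropping them on singular fits), test the noise
effect by likelihood ratio, and report Tukey-adjusted pairwise contrasts
from estimated marginal means.
"""
from lombardkit.inference import noise_effect_analysis
from lombardkit.synthetic import CONDITIONS, GeneratorConfig, generate_latent_table

table = generate_latent_table(GeneratorConfig(seed=1))

res = noise_effect_analysis(table, "max_intensity_db", "gaussian", list(CONDITIONS))
print(f"speech intensity: chi2({res.lrt.df}) = {res.lrt.chisq:.2f}, p = {res.lrt.p:.4f}")
print(res.contrasts.rows.round(4).to_string(index=False))

res2 = noise_effect_analysis(table, "submovements", "poisson", list(CONDITIONS))
print(f"\nsubmovements: chi2({res2.lrt.df}) = {res2.lrt.chisq:.2f}, p = {res2.lrt.p:.4g}")
if res2.contrasts is not None:
    print(res2.contrasts.rows.round(4).to_string(index=False))
else:
    print("(no main effect at alpha = 0.05 in this replicate; "
          "contrasts are only formed for significant effects)")
# The babble8-clear intensity difference recovers the configured +0.29 dB
# shift; submovement contrasts, when formed, are rate ratios (the
# configured truth is 1.142x for 8-talker babble vs clear).
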