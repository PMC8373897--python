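"""Generate a small synthetic study and look at its ground truth.

The generator emulates a dyadic word-communication experiment: each
producer communicates items under randomly varying background-noise
conditions (clear, 4-talker babble, 8-talker babble), choosing speech,
gesture, or both per round. Every latent feature value is recorded, so
downstream extraction and inference can be checked against known truth.
"""
from lombardkit.synthetic import GeneratorConfig, generate_dataset, write_session

cfg = GeneratorConfig(n_participants=4, n_items=6, seed=7)
sessions, truth = generate_dataset(cfg)

print(f"{len(sessions)} sessions, {len(truth)} rounds")
print("\nModality mix:")
print(truth.groupby(["condition", "modality"]).size().unstack(fill_value=0))
print("\nGround-truth features (first rounds):")
cols = ["participant", "item", "condition", "modality",
        "max_intensity_db", "submovements", "holdtime_s"]
print(truth[cols].head(6).to_string(index=False))

paths = write_session(sessions[0], "scratch/example_session")
print("\nSession files written:", ", ".join(p.name for p in paths.values()))
# The intensity column is the per-attempt maximum in dB; submovements count
# distinct movement pulses; holdtime is stillness time within the gesture.
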