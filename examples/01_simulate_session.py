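"""Generate a synthetic DNMS session and inspect its structure.

A session is ~100 trials of a delayed non-match-to-sample task. Each
trial contributes a -2..+2 s perievent window around the sample lever
press, binned at 2 ms: CA3 spikes are inhomogeneous Bernoulli with
side-dependent rate bumps, CA1 spikes come from a known sparse
Laguerre-Volterra ground-truth model driven by the CA3 trains.
"""

from hippomimo import extract_perievent_patterns, generate_dnms_dataset, preset_spec

spec = preset_spec("easy", seed=0)
spec.n_trials = 20  # small, for a quick look
ds = generate_dnms_dataset(spec)

s = ds.spike_train_set
dt = spec.bin_width_s
print(f"{spec.n_ca3} CA3 + {spec.n_ca1} CA1 neurons, {spec.n_trials} trials")
print(f"total spikes: {len(s.spikes)}; events: {s.events['event_code'].value_counts().to_dict()}")
print(f"CA3 mean rate: {ds.session.inputs.mean() / dt:.1f} Hz, "
      f"CA1 mean rate: {ds.session.outputs.mean() / dt:.1f} Hz")

patterns = extract_perievent_patterns(s, "CA3", "sample")
p = patterns[0]
print(f"pattern matrix: {p.pattern.shape[0]} neurons x {p.pattern.shape[1]} bins "
      f"(window {p.window_s} s at {dt*1e3:.0f} ms); label={p.label} "
      f"({'left' if p.label else 'right'} sample)")
# Left trials boost the first three CA3 neurons around the lever press,
# right trials the next three — that asymmetry is what the decoder finds.
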