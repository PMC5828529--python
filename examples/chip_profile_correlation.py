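"""Correlate simulated binding profiles against class templates.

Builds one synthetic genome, simulates an axis-bound profile and a
transcription-coupled profile (plus their noise-free templates), conditions
every track (decile normalization -> median denoising -> 1 kb smoothing) and
prints the pairwise Pearson correlations. A high value against the axis
template and a low value against the RNA-pol-II-like template (or vice
versa) is the signature used to tell the two binding-site classes apart.
"""

import chipms


def conditioned(track):
    return chipms.smooth(chipms.denoise(chipms.decile_normalize(track)), window_bp=1000)


genome = chipms.simulate_genome(seed=5)


def sim(w_axis, w_txn, noise_sd):
    track, _ = chipms.simulate_chip_profile(
        genome, chipms.ChipSimConfig(w_axis=w_axis, w_txn=w_txn, noise_sd=noise_sd, seed=5)
    )
    return conditioned(track)


axis_template = sim(1.0, 0.0, 0.0)
polii_template = sim(0.0, 1.0, 0.0)
axis_track = sim(1.0, 0.0, 0.1)
txn_track = sim(0.0, 1.0, 0.1)

for label, a, b in [
    ("axis-bound track  vs axis template ", axis_track, axis_template),
    ("txn-coupled track vs pol II template", txn_track, polii_template),
    ("txn-coupled track vs axis template ", txn_track, axis_template),
]:
    r = chipms.correlate_profiles(a, b)
    print(f"{label}: Pearson r = {r.pearson_r:+.3f} over {r.n_probes} shared probes")

print(
    "\nEach track correlates strongly with its own class template and weakly"
    "\nwith the other class, mirroring how loss of the axis tether re-routes"
    "\nbinding toward highly transcribed genes."
)
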