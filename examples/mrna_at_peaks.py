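"""Compare mean mRNA level at the strongest peaks with the genome average.

Simulates a transcription-coupled profile and an axis-bound profile on the
same genome, attributes an mRNA level to every probe (gene bodies, single
promoters, divergent promoters averaged, convergent intergenic regions
unassigned) and contrasts the top-100-summit mean with the genome-wide mean.
"""

import numpy as np

import chipms

genome = chipms.simulate_genome(seed=5)


def summit_vs_genome(w_axis, w_txn, label):
    raw, _ = chipms.simulate_chip_profile(
        genome, chipms.ChipSimConfig(w_axis=w_axis, w_txn=w_txn, noise_sd=0.1, seed=5)
    )
    proc = chipms.smooth(chipms.denoise(chipms.decile_normalize(raw)), window_bp=2000)
    peaks = chipms.call_peaks(proc, threshold=float(np.median(proc.data["ratio"])) + 0.25)
    summits = [(p.chrom, p.summit_pos) for p in chipms.top_peaks(peaks, min(100, len(peaks)))]
    assignment = chipms.attribute_mrna(proc, genome)
    top, whole, excluded = chipms.mean_mrna_at_peaks(assignment, proc, summits)
    print(
        f"{label}: summit mean mRNA {top.mean:.2f} +- {top.sem:.2f} (n={top.n}) vs "
        f"genome {whole.mean:.2f} +- {whole.sem:.2f} (n={whole.n}); "
        f"{excluded['summit_unassigned']} summit probes unassigned"
    )


summit_vs_genome(0.0, 1.0, "transcription-coupled")
summit_vs_genome(1.0, 0.0, "axis-bound           ")
print(
    "\nOnly the transcription-coupled profile concentrates its strongest"
    "\npeaks on highly expressed genes; axis sites are placed independently"
    "\nof expression, so their summit mRNA matches the genome average."
)
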