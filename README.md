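# chipms

Tiling-array ChIP-chip signal processing and label-free AP-MS differential
enrichment, with seeded synthetic-data generators that carry ground truth
for every stage.

## The scientific problem

Some chromatin proteins occupy two distinct classes of binding sites. The
motivating case is a meiotic H3K4me3-reader that sits both on chromosome
**axis** attachment sites (through a DSB-machinery partner) and on **highly
transcribed genes** (through the H3K4 methyltransferase complex travelling
with RNA polymerase II). Distinguishing the two classes from genome-wide
binding data, and identifying the protein's partners from pull-down
proteomics, takes two complementary pipelines:

1. **ChIP-chip track analysis.** Probe-level IP/input ratios are
   decile-normalized (scaled so the genome-wide median ratio is 1),
   denoised with a 3-probe running median, and smoothed with a genomic
   sliding-window mean (1 kb or 2 kb). Peaks are maximal runs of probes
   above a threshold; each peak's **summit** is its maximum probe. Profiles
   are compared by Pearson correlation over shared probes
   (r = cov(x, y) / σ_x σ_y), summit signal is contrasted with the whole
   array (mean ± SEM, Tukey boxplot statistics), and each probe is assigned
   the mRNA level of its gene — probes in promoters take the downstream
   gene's level, probes in divergent promoters the mean of both flanking
   genes — to ask whether the strongest peaks sit on highly expressed genes.

2. **AP-MS differential enrichment.** A protein-group intensity table
   (3 bait vs 3 control replicates) is QC-filtered (no decoy/contaminant/
   only-by-site entries, ≥ 2 unique+razor peptides, ≥ 3 valid values in at
   least one condition), log2-transformed and median-centered per sample,
   missing values are imputed with each column's 2.5th percentile (a
   missing-not-at-random treatment), and each protein is tested with a
   **moderated t**: the pooled residual variance s² (d = n₁+n₂−2 df) is
   shrunk toward an empirical-Bayes prior (d₀, s₀²) moment-matched on
   log s² across proteins, giving s̃² = (d₀s₀² + d·s²)/(d₀ + d),
   t = Δmean / (s̃·√(1/n₁+1/n₂)), with p-values on d₀+d df and
   Benjamini–Hochberg FDR control. Significant interactors pass
   log2 FC > 7 **and** BH-FDR ≤ 1% (a permissive volcano gate,
   log2 FC > 3 and raw p < 10⁻⁴, is also provided).

Because real genome-scale datasets are large and external, the package
ships simulators with known ground truth: probe tracks as mixtures of an
axis component (Gaussian kernels at axis sites) and a transcription
component (signal proportional to gene mRNA level) plus noise, and
intensity matrices with planted interactors and intensity-dependent
missingness. Every downstream claim is tested against that truth.

## Worked example

```python
import chipms

genome = chipms.simulate_genome(seed=5)
track, truth = chipms.simulate_chip_profile(
    genome, chipms.ChipSimConfig(w_axis=1.0, w_txn=0.0, noise_sd=0.1, seed=5))
processed = chipms.smooth(chipms.denoise(chipms.decile_normalize(track)), window_bp=1000)
template, _ = chipms.simulate_chip_profile(
    genome, chipms.ChipSimConfig(w_axis=1.0, w_txn=0.0, noise_sd=0.0, seed=5))
r = chipms.correlate_profiles(processed, chipms.smooth(
    chipms.denoise(chipms.decile_normalize(template)), window_bp=1000))
print(r.pearson_r, r.n_probes)
```

Running `python examples/chip_profile_correlation.py` prints:

```
axis-bound track  vs axis template : Pearson r = +0.988 over 2068 shared probes
txn-coupled track vs pol II template: Pearson r = +0.996 over 2068 shared probes
txn-coupled track vs axis template : Pearson r = +0.056 over 2068 shared probes
```

The first two numbers say each simulated binding class is faithfully
recovered by its own template after conditioning; the third says the two
classes are uncorrelated with each other's templates, which is the signal
used to conclude that a protein's binding pattern switched class. The other
scripts in `examples/` walk through peak calling and summit recovery,
summit-vs-genome mRNA contrasts, pull-down enrichment (printing the
significant-interactor table with precision/recall against the planted
truth) and qPCR enrichment arithmetic.

A thin CLI mirrors the library: `chipms sim chip`, `chipms normalize`,
`chipms smooth --window-bp 1000`, `chipms callpeaks`, `chipms correlate`,
`chipms enrich`, `chipms run-demo` (see `chipms --help`).

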