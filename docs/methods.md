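# Methods

This note documents the models, conventions and numerical choices behind
`chipms`, and what the bundled simulators do and do not emulate.

## Coordinate and data conventions

All genomic coordinates are 1-based, fully-closed intervals; BED export
converts to 0-based half-open (a tested transform). Probes are represented
by their interval midpoint for every distance computation. Probe tracks are
per-chromosome ordered lists of non-overlapping intervals with finite
ratios; every conditioning step appends itself (with parameters) to an
append-only processing history that is embedded as `#` comments in written
files, so any track on disk records how it was produced.

## ChIP track simulator

The simulated ratio at probe midpoint p is

    ratio(p) = baseline
             + w_axis · Σ_s A_s · exp(−(p − pos_s)² / 2σ²)
             + w_txn · txn_scale · mrna(p)
             + ε

with baseline 1 (the value decile normalization targets), Gaussian axis
kernels of sd σ = 1 kb (peak widths comparable to 1-kb-smoothed tracks),
per-site amplitudes A_s log-normal around 1, and the transcription
component applying a gene's mRNA level to probes in its body and promoter
(same orientation rules as the analysis-side attribution, below).
ε is additive Gaussian on the ratio scale (a multiplicative log-normal
option exists behind `noise_model`). With `noise_sd=0` the track equals the
analytic mixture exactly; the test suite uses this as a closed-form oracle.

Probes tile each chromosome every 290 bp (60 bp features, ±10% jitter),
emulating a dense commercial tiling array. The probe layout is drawn from
an RNG stream independent of the noise stream, so a noisy track and its
noise-free template share every probe. Midpoints sit on the half-integer
lattice so stored intervals have exact midpoints.

Synthetic genomes pack non-overlapping genes (uniform 0.5–2.5 kb lengths,
0.2–0.8 kb gaps, random strands) with log-normal mRNA levels (median 1,
shape 1 — a heavy right tail like real expression data), place axis sites
quasi-regularly every 15–20 kb (the spacing of axis attachment regions in a
small fungal genome), and mark a configurable fraction of gene promoters as
DSB hotspots. The generators are seeded and byte-deterministic.

What the simulator does **not** emulate: sequence content, probe-specific
affinity biases, dye effects, copy-number variation, replication timing,
nucleosome structure, or spatially correlated noise. Passing recovery tests
therefore demonstrates correctness of the analysis logic under a clean
generative model, not robustness to every artifact of real arrays.

## Track conditioning

* **Decile normalization** — the published operation is named but not
  defined; here it scales the whole array by its genome-wide median
  (the 5th decile) so the median ratio is 1. It is idempotent and makes
  arrays comparable. A full quantile-to-reference mapping was considered
  and deliberately left out of the default path.
* **Denoising** — a k = 3 probe running median per chromosome; edge probes
  are copied unchanged by default (`edges="truncate"` uses the shorter
  neighborhood instead; both are tested against a brute-force oracle). A
  3-probe median removes single-probe spikes and preserves plateaus.
* **Smoothing** — an unweighted mean over all probes whose midpoints lie
  within ± window/2 of the focal midpoint, per chromosome, truncated at
  chromosome ends. Windows are genomic (bp), not probe counts: 1 kb for
  display-style tracks and profile correlation, 2 kb for summit-anchored
  analyses. The 2 kb choice for summit work matters: at 1 kb the smoothed
  top of a 1-kb-sd kernel is flat relative to residual probe noise at 10:1
  amplitude:noise, and summit positions wander 300–460 bp in roughly one
  kernel in ten; at 2 kb summits localize to about one probe spacing.

Results are reproducible to 1e-9 across runs on the same platform; no
operation crosses a chromosome boundary.

## Peak calling

Peaks are maximal runs of probes strictly above a threshold, after merging
runs separated by at most one below-threshold probe; runs with fewer than
two above-threshold probes are discarded. The summit is the probe of
maximum value (leftmost on ties), the score is the value at the summit,
and ranks are dense with ties broken by genomic position, so output is
bit-reproducible. The default threshold is the 0.99 genome-wide quantile of
the conditioned track — scale-free, and appropriate for real decile-
normalized arrays where peaks occupy a small fraction of probes. On dense
synthetic layouts (40 kernels on 0.8 Mb, ~20% of probes elevated) that
quantile lands above the smoothed kernel maxima, so recovery analyses use
an absolute threshold at baseline + amplitude/2 (half maximum) instead;
the caller accepts either form. A caveat worth knowing: with gap merging,
raising the threshold can *split* one merged peak into several, so peak
counts are monotone in the threshold only on unimodal profiles.

## Profile comparisons

Pearson correlation is computed over probes shared by exact
(chrom, start, end) key, on the linear conditioned-ratio scale (log2 scale
behind a flag); fewer than 3 shared probes or zero variance is an error,
not a NaN. Summit-anchored summaries map each summit to the probe
containing it (nearest probe with a warning otherwise) and report mean and
SEM (sample sd, n−1, over √n) for the summit set and the whole array.
Boxplot statistics follow the Tukey conventions: quartiles by linear
interpolation between order statistics (h = (n−1)q + 1), whiskers at the
most extreme point within 1.5 × IQR of the box (the factor is a parameter),
notch half-width 1.58 · IQR / √n.

mRNA attribution is purely orientation-based over whole intergenic
intervals, with no fixed promoter size: gene-body probes take their gene's
level; intergenic probes upstream of exactly one flanking gene take that
gene's level; probes between divergently transcribed genes take the
unweighted mean of both; probes between convergent genes (downstream of
both) stay unassigned and are excluded, with counts reported, from mRNA
summaries. qPCR enrichment is the ratio of percent-input values to a
negative-control locus, which maps to 1.0 exactly.

## Pull-down simulator and enrichment workflow

Each protein receives a base log2 abundance ~ N(25, 2) (the scale of
typical label-free LFQ runs) and per-cell replicate noise of sd 0.3
(a 20–25% CV). Planted interactors have their bait-condition cells raised
by their true log2 fold change; controls stay at base, so bait − ctrl
equals the planted effect when nothing is missing (a tested property).
Missingness is missing-not-at-random: P(missing) = logistic(α − β·x) per
cell with α = 17.5, β = 0.8, giving ~15% missing cells overall on a null
table and making low-intensity cells (including the controls of low-base
interactors) predominantly missing. The simulator also plants a small
fraction of decoy/contaminant/only-by-site and single-peptide rows so the
QC filters have work to do. It does not model peptide-level identification,
match-between-runs, shared peptides, or batch effects.

The workflow order is fixed and asserted via table history: filter →
log2 + median centering → 2.5-percentile imputation → moderated t → BH →
gate. Median centering shifts each column so its median equals the grand
median of the pre-shift column medians (differences between samples are
invariant to this target). The valid-values filter defaults to ≥ 3
non-missing values in *at least one* condition: a bait-specific interactor
is legitimately absent from controls, and the stricter both-conditions
reading would discard exactly the proteins the experiment exists to find
(it remains selectable).

The moderated t estimates its prior by moment matching on log s²:
with e_i = log s²_i − ψ(d/2) + log(d/2), the prior df solves
ψ′(d0/2) = var(e) − ψ′(d/2) (Newton on the trigamma inverse) and
s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)); the posterior variance is
(d0·s0² + d·s²)/(d0 + d) and p-values use d0 + d degrees of freedom. When
the observed spread of log-variances is no larger than chi-square sampling
alone, d0 = ∞ and every protein uses the common variance; if prior
estimation fails outright the code falls back to an ordinary pooled t with
a warning. The implementation agrees with Bioconductor limma's
lmFit + eBayes to ~1e-9 relative on a shared fixture (tested), and with a
step-by-step closed-form recomputation; an ordinary Welch t is available
behind a flag. BH adjustment is the standard step-up procedure.

Two significance gates are provided, reflecting two published conventions
that disagree: the stringent gate (log2 FC > 7 and BH-FDR ≤ 1%, the
default) and a permissive volcano gate (log2 FC > 3 and raw p < 10⁻⁴).
Neither is silently preferred; the gate used is recorded in the result
metadata.

### Behavior worth knowing at the detection boundary

Percentile imputation floors each column near its 2.5th percentile
(≈ 4 log2 units below the column mean at the default spread). Consequences,
all visible in the recovery tests: an interactor whose bait intensity is
below (floor + 7) cannot pass the stringent fold-change gate no matter how
real it is; an interactor losing one bait cell to dropout fails the
valid-values filter outright; and a single missing control cell imputed far
below its observed siblings inflates the residual variance enough that the
BH-adjusted p can exceed 1%. With nine planted interactors at log2 FC
exactly 8 — bait intensities then straddle the detection boundary — these
mechanisms together miss ~5% of interactors, so the "recall ≥ 8/9 with ≤ 1
false positive" property holds on most but not quite all seed sets (17 of
the fixed seeds 0–19; ~93% of seeds in expectation). This is a property of
the published gate under MNAR imputation, not of the implementation; the
type-I calibration of the test itself is nominal (raw p ≤ 0.05 for
5.0% ± 0.5% of null proteins, missingness disabled).

## Problem sizes and determinism

Default analyses run on 2 × 300 kb genomes (~2,000 probes, 150 genes,
~34 axis sites) and 1,500-protein tables; summit-recovery analyses use
2 × 400 kb with exactly 40 kernels. These sizes give every statistic a
stable value while keeping any test or script in seconds on one CPU. All
randomness flows from explicit integer seeds through `numpy` generators;
both end-to-end pipelines write SHA-256 manifests, and byte-identical
output for identical (config, seed) is itself a test.
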