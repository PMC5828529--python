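"""Comparative analyses of conditioned binding profiles.

Covers the downstream questions asked of tiling-array ChIP data once tracks
are normalized, denoised and smoothed: how two binding profiles correlate
genome-wide; how signal at peak summits compares with the whole array; how
mRNA levels at the strongest peaks compare with the genome; and the simple
arithmetic of ChIP-qPCR percent-input enrichment against a negative-control
locus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel, assign_mrna
from .track import ProbeTrack

__all__ = [
    "CorrelationResult",
    "SummarySignal",
    "correlate_profiles",
    "boxplot_stats",
    "summit_signal_summary",
    "attribute_mrna",
    "mean_mrna_at_peaks",
    "qpcr_enrichment",
]


@dataclass(frozen=True)
class CorrelationResult:
    label_a: str
    label_b: str
    n_probes: int
    pearson_r: float


@dataclass(frozen=True)
class SummarySignal:
    """Mean/SEM plus Tukey boxplot statistics for one group of values.

    SEM uses the sample standard deviation (n-1 denominator) over sqrt(n).
    Quartiles interpolate linearly between order statistics
    (h = (n-1)q + 1); whiskers extend to the most extreme data point within
    ``whisker_factor`` x IQR of the box; the notch half-width follows the
    1.58 x IQR / sqrt(n) convention.
    """

    group: str
    n: int
    mean: float
    sem: float
    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    notch: float


def correlate_profiles(a: ProbeTrack, b: ProbeTrack, log_scale: bool = False) -> CorrelationResult:
    """Pearson correlation of two tracks over their shared probes.

    Probes are matched by exact (chrom, start, end) key; the correlation is
    computed on the processed linear ratio scale unless ``log_scale``.
    """
    merged = a.data.merge(b.data, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"tracks share only {len(merged)} probes; need >= 3")
    x = merged["ratio_a"].to_numpy()
    y = merged["ratio_b"].to_numpy()
    if log_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-scale correlation requires positive ratios")
        x, y = np.log2(x), np.log2(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in one track")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(a.label or "a", b.label or "b", len(merged), r)


def boxplot_stats(values, group: str = "", whisker_factor: float = 1.5) -> SummarySignal:
    """Tukey boxplot statistics (plus mean/SEM) for a set of values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    in_lo = v[v >= q25 - whisker_factor * iqr]
    in_hi = v[v <= q75 + whisker_factor * iqr]
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return SummarySignal(
        group=group,
        n=int(v.size),
        mean=float(np.mean(v)),
        sem=sem,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_lo=float(in_lo.min()),
        whisker_hi=float(in_hi.max()),
        notch=float(1.58 * iqr / math.sqrt(v.size)),
    )


def _summit_probe_indices(track: ProbeTrack, summits) -> list[int]:
    """Map (chrom, position) summits to probe row indices.

    Prefers the probe whose interval contains the summit; falls back to the
    nearest probe midpoint (with a warning). Summits on chromosomes absent
    from the track are skipped with a warning.
    """
    idx_by_chrom = track.data.groupby("chrom", sort=False).indices
    starts = track.data["start"].to_numpy()
    ends = track.data["end"].to_numpy()
    mids = track.midpoints.to_numpy()
    out = []
    skipped = 0
    for chrom, pos in summits:
        idx = idx_by_chrom.get(chrom)
        if idx is None:
            skipped += 1
            continue
        j = np.searchsorted(starts[idx], pos, side="right") - 1
        if j >= 0 and pos <= ends[idx[j]]:
            out.append(int(idx[j]))
        else:
            warnings.warn(f"summit {chrom}:{pos} falls between probes; using nearest")
            out.append(int(idx[np.argmin(np.abs(mids[idx] - pos))]))
    if skipped:
        warnings.warn(f"skipped {skipped} summit(s) on chromosomes absent from track")
    return out


def summit_signal_summary(
    track: ProbeTrack, summits, n: int | None = None
) -> tuple[SummarySignal, SummarySignal]:
    """Signal at summit probes vs the entire array.

    ``summits`` is an iterable of (chrom, position); only the first ``n`` are
    used when given. Returns (summit summary, whole-array summary).
    """
    summits = list(summits)
    if n is not None:
        summits = summits[:n]
    rows = _summit_probe_indices(track, summits)
    if not rows:
        raise ValueError("no summit maps to any probe of the track")
    v = track.data["ratio"].to_numpy()
    label = f"top-{len(rows)} summits"
    return boxplot_stats(v[rows], group=label), boxplot_stats(v, group="whole array")


def attribute_mrna(track: ProbeTrack, genome: GenomeModel) -> pd.DataFrame:
    """Assign an mRNA level and class to every probe of a track.

    Returns a DataFrame aligned with ``track.data`` carrying ``mrna``
    (NaN when unassigned) and ``klass`` in {gene_body, promoter_single,
    promoter_divergent, unassigned}. Probes in convergent intergenic regions
    (downstream of both neighbours) stay unassigned.
    """
    mids = track.midpoints.to_numpy()
    levels = np.full(track.n_probes, np.nan)
    classes = np.full(track.n_probes, "unassigned", dtype=object)
    for chrom, idx in track.data.groupby("chrom", sort=False).indices.items():
        lv, cl = assign_mrna(chrom, mids[idx], genome.genes)
        levels[idx] = lv
        classes[idx] = cl
    return pd.DataFrame({"mrna": levels, "klass": classes}, index=track.data.index)


def mean_mrna_at_peaks(
    assignment: pd.DataFrame, track: ProbeTrack, summits, n: int = 100
) -> tuple[SummarySignal, SummarySignal, dict]:
    """Mean mRNA at the strongest peak summits vs the whole genome.

    ``assignment`` must come from :func:`attribute_mrna` on the same track.
    Unassigned probes are excluded from both groups; the returned dict
    reports how many were excluded from each.
    """
    if len(assignment) != track.n_probes:
        raise ValueError("assignment and track disagree on probe count")
    summits = list(summits)[:n]
    rows = _summit_probe_indices(track, summits)
    if not rows:
        raise ValueError("no summit maps to any probe of the track")
    mrna = assignment["mrna"].to_numpy()
    summit_vals = mrna[rows]
    summit_vals = summit_vals[~np.isnan(summit_vals)]
    if summit_vals.size == 0:
        raise ValueError("all summit probes are unassigned; cannot summarize")
    genome_vals = mrna[~np.isnan(mrna)]
    excluded = {
        "summit_unassigned": int(len(rows) - summit_vals.size),
        "genome_unassigned": int(len(mrna) - genome_vals.size),
    }
    return (
        boxplot_stats(summit_vals, group=f"top-{len(rows)} summits"),
        boxplot_stats(genome_vals, group="whole genome"),
        excluded,
    )


def qpcr_enrichment(percent_input: dict[str, float], control_site: str) -> dict[str, float]:
    """Normalize ChIP-qPCR percent-input values to a negative-control locus.

    ``enrichment(site) = %input(site) / %input(control)``; the control site
    itself maps to exactly 1.0.
    """
    if control_site not in percent_input:
        raise ValueError(f"control site {control_site!r} not among measured sites")
    ctrl = percent_input[control_site]
    if ctrl <= 0:
        raise ValueError("control-site percent input must be > 0")
    return {site: v / ctrl for site, v in percent_input.items()}
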