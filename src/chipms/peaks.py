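"""Peak calling on conditioned probe tracks.

A peak is a maximal run of probes strictly above a threshold (genome-wide
quantile by default, or an absolute value), after merging runs separated by
at most ``max_gap_probes`` below-threshold probes; runs with fewer than
``min_probes`` above-threshold probes are discarded. The summit is the probe
of maximum value (leftmost on ties), the score is the track value at the
summit, and peaks are ranked 1..n by descending score with genomic position
breaking ties. Peaks never span chromosome boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .track import ProbeTrack

__all__ = ["Peak", "call_peaks", "top_peaks", "write_peaks_bed", "write_summits_bed"]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 1-based closed
    end: int
    summit_pos: int  # midpoint of the summit probe
    score: float
    rank: int = 0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit_pos <= self.end):
            raise ValueError("summit must lie within the peak interval")


def call_peaks(
    track: ProbeTrack,
    quantile: float | None = 0.99,
    threshold: float | None = None,
    max_gap_probes: int = 1,
    min_probes: int = 2,
    require_processed: bool = True,
) -> list[Peak]:
    """Call peaks on a conditioned track.

    Exactly one of ``quantile`` (genome-wide quantile of the track, default
    0.99) and ``threshold`` (absolute value) sets the calling threshold; an
    explicit ``threshold`` wins.  ``require_processed`` asserts that the
    track's history includes a smoothing step, since calling on raw probe
    ratios is almost never intended; pass False to override.
    """
    if track.n_probes == 0:
        return []
    if require_processed and not any(h.startswith("smooth") for h in track.history):
        raise ValueError(
            "track history has no smoothing step; condition the track first "
            "or pass require_processed=False"
        )
    values = track.data["ratio"].to_numpy()
    if threshold is None:
        if quantile is None or not (0 < quantile < 1):
            raise ValueError("quantile must be in (0, 1)")
        threshold = float(np.quantile(values, quantile))
    if max_gap_probes < 0 or min_probes < 1:
        raise ValueError("max_gap_probes must be >= 0 and min_probes >= 1")

    starts_all = track.data["start"].to_numpy()
    ends_all = track.data["end"].to_numpy()
    mids_all = ((starts_all + ends_all) / 2).astype(int)

    peaks: list[Peak] = []
    for chrom, idx in track.data.groupby("chrom", sort=False).indices.items():
        v = values[idx]
        above = np.flatnonzero(v > threshold)
        if above.size == 0:
            continue
        # group above-threshold probes into runs, merging across short gaps
        runs: list[list[int]] = [[above[0]]]
        for i in above[1:]:
            if i - runs[-1][-1] - 1 <= max_gap_probes:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) < min_probes:
                continue
            run_arr = np.array(run)
            summit_local = run_arr[int(np.argmax(v[run_arr]))]  # argmax -> leftmost tie
            gi = idx[run_arr]
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(starts_all[gi[0]]),
                    end=int(ends_all[gi[-1]]),
                    summit_pos=int(mids_all[idx[summit_local]]),
                    score=float(v[summit_local]),
                )
            )

    chrom_order = {c: i for i, c in enumerate(track.chromosomes())}
    peaks.sort(key=lambda p: (-p.score, chrom_order[p.chrom], p.start))
    return [
        Peak(p.chrom, p.start, p.end, p.summit_pos, p.score, rank=i + 1)
        for i, p in enumerate(peaks)
    ]


def top_peaks(peaks: list[Peak], n: int = 100) -> list[Peak]:
    """First ``n`` peaks by rank (score descending, position on ties)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if n > len(peaks):
        warnings.warn(f"requested top {n} of {len(peaks)} peaks; returning all")
    ranks = [p.rank for p in peaks]
    if ranks != sorted(ranks):
        raise ValueError("peaks must be rank-sorted; use call_peaks output")
    return peaks[:n]


def write_peaks_bed(peaks: list[Peak], path) -> None:
    """Write peaks as BED (0-based half-open; score = summit value)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\tpeak{p.rank}\t{p.score:.6g}\n")


def write_summits_bed(peaks: list[Peak], path) -> None:
    """Write summit positions as 1-bp BED features."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.summit_pos - 1}\t{p.summit_pos}\tsummit{p.rank}\t{p.score:.6g}\n"
            )
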