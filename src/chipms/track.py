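"""Probe-level ChIP ratio tracks and their signal conditioning.

A :class:`ProbeTrack` holds one two-color tiling-array sample: per
chromosome, an ordered list of non-overlapping probes, each an interval with
an IP/input ratio.  The three conditioning steps applied to raw ratios before
any comparison are:

1. ``decile_normalize`` — scale the whole array so the genome-wide median
   ratio is 1 (the 5th decile), making arrays comparable;
2. ``denoise`` — a k-probe running-median filter that removes single-probe
   spikes while preserving plateaus;
3. ``smooth`` — an unweighted mean over a genomic window (1 kb or 2 kb by
   convention) centred on each probe midpoint.

Every step appends itself to the track's processing history, which is
embedded as ``#`` comments when the track is written out.

Internally coordinates are 1-based closed; bedGraph I/O converts to/from the
0-based half-open convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProbeTrack",
    "read_track",
    "write_track",
    "decile_normalize",
    "denoise",
    "smooth",
]

TRACK_COLUMNS = ["chrom", "start", "end", "ratio"]


@dataclass
class ProbeTrack:
    data: pd.DataFrame  # columns chrom, start (1-based), end (closed), ratio
    label: str = ""
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if list(df.columns) != TRACK_COLUMNS:
            raise ValueError(f"track must have columns {TRACK_COLUMNS}")
        if not np.isfinite(df["ratio"]).all():
            raise ValueError("probe ratios must be finite")
        if (df["start"] > df["end"]).any():
            raise ValueError("probe start must be <= end")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (np.diff(starts) < 0).any():
                bad = int(np.flatnonzero(np.diff(starts) < 0)[0])
                raise ValueError(f"unsorted probes on {chrom!r} near row {sub.index[bad + 1]}")
            if (starts[1:] <= ends[:-1]).any():
                bad = int(np.flatnonzero(starts[1:] <= ends[:-1])[0])
                raise ValueError(f"overlapping probes on {chrom!r} near row {sub.index[bad + 1]}")

    @property
    def midpoints(self) -> pd.Series:
        return (self.data["start"] + self.data["end"]) / 2.0

    @property
    def n_probes(self) -> int:
        return len(self.data)

    def with_ratios(self, ratios: np.ndarray, step: str) -> "ProbeTrack":
        """Return a copy with new ratios and ``step`` appended to history."""
        df = self.data.copy()
        df["ratio"] = np.asarray(ratios, dtype=float)
        return ProbeTrack(data=df, label=self.label, history=[*self.history, step])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))


def read_track(path, format: str | None = None, label: str | None = None) -> ProbeTrack:
    """Read a track from bedGraph or 4-column TSV.

    ``format`` defaults from the file extension (.bedgraph/.bg vs anything
    else -> tsv). bedGraph intervals (0-based half-open) are converted to the
    internal 1-based closed convention. ``#``-prefixed ``history:`` comments
    written by :func:`write_track` are restored into the track's history.
    """
    path = str(path)
    if format is None:
        format = "bedgraph" if path.endswith((".bedgraph", ".bg")) else "tsv"
    if format not in ("bedgraph", "tsv"):
        raise ValueError(f"unknown track format {format!r}")
    history: list[str] = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("track"):
                continue
            if line.startswith("#"):
                stripped = line.lstrip("# ")
                if stripped.startswith("history:"):
                    history.append(stripped[len("history:"):].strip())
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, ratio = parts[:4]
            try:
                start_i, end_i, ratio_f = int(start), int(end), float(ratio)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if format == "bedgraph":
                start_i += 1  # 0-based half-open -> 1-based closed
            rows.append((chrom, start_i, end_i, ratio_f))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    try:
        return ProbeTrack(data=df, label=label or "", history=history)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_track(track: ProbeTrack, path, format: str | None = None, precision: int = 6) -> None:
    """Write a track as bedGraph or TSV, embedding processing history."""
    path = str(path)
    if format is None:
        format = "bedgraph" if path.endswith((".bedgraph", ".bg")) else "tsv"
    with open(path, "w") as fh:
        if track.label:
            fh.write(f"# label: {track.label}\n")
        for step in track.history:
            fh.write(f"# history: {step}\n")
        for row in track.data.itertuples(index=False):
            start = row.start - 1 if format == "bedgraph" else row.start
            fh.write(f"{row.chrom}\t{start}\t{row.end}\t{row.ratio:.{precision}f}\n")


def decile_normalize(track: ProbeTrack) -> ProbeTrack:
    """Scale the whole array by its genome-wide median so the median is 1.

    A single multiplicative constant is applied to every probe; the operation
    is idempotent and invariant to positive rescaling of the input.
    """
    if track.n_probes == 0:
        raise ValueError("cannot normalize an empty track")
    med = float(np.median(track.data["ratio"]))
    if med == 0:
        raise ValueError("median ratio is zero; decile normalization undefined")
    return track.with_ratios(track.data["ratio"].to_numpy() / med, "decile_normalize(median=1)")


def denoise(track: ProbeTrack, k: int = 3, edges: str = "copy") -> ProbeTrack:
    """k-probe running-median filter, applied per chromosome.

    ``edges='copy'`` (default) leaves the first and last (k-1)/2 probes of
    each chromosome unchanged; ``edges='truncate'`` takes the median of the
    available (shorter) neighborhood instead.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("median-filter window k must be odd and >= 1")
    if edges not in ("copy", "truncate"):
        raise ValueError("edges must be 'copy' or 'truncate'")
    out = np.empty(track.n_probes)
    half = k // 2
    values = track.data["ratio"].to_numpy()
    for _, idx in track.data.groupby("chrom", sort=False).indices.items():
        v = values[idx]
        filtered = (
            pd.Series(v).rolling(k, center=True, min_periods=1).median().to_numpy()
        )
        if edges == "copy" and len(v) > 2 * half:
            filtered[:half] = v[:half]
            filtered[-half:] = v[-half:]
        elif edges == "copy":
            filtered = v.copy()
        out[idx] = filtered
    return track.with_ratios(out, f"denoise(k={k}, edges={edges})")


def smooth(track: ProbeTrack, window_bp: float = 1000) -> ProbeTrack:
    """Genomic sliding-window mean over probe midpoints, per chromosome.

    Each probe's value becomes the unweighted mean of all probes on the same
    chromosome whose midpoint lies within ± ``window_bp``/2 of the focal
    midpoint (inclusive); the window is truncated at chromosome ends. A
    window smaller than the probe spacing leaves the track unchanged.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    half = window_bp / 2.0
    values = track.data["ratio"].to_numpy()
    mids_all = track.midpoints.to_numpy()
    out = np.empty(track.n_probes)
    for chrom, idx in track.data.groupby("chrom", sort=False).indices.items():
        if len(idx) == 0:
            warnings.warn(f"empty chromosome {chrom!r}: passthrough")
            continue
        m = mids_all[idx]
        v = values[idx]
        cs = np.concatenate([[0.0], np.cumsum(v)])
        lo = np.searchsorted(m, m - half, side="left")
        hi = np.searchsorted(m, m + half, side="right")
        out[idx] = (cs[hi] - cs[lo]) / (hi - lo)
    return track.with_ratios(out, f"smooth(window_bp={window_bp:g})")
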