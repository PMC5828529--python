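"""Optional rendering of tracks, volcano plots and boxplots (SVG/PNG)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .profiles import SummarySignal
from .proteomics import EnrichmentResult
from .track import ProbeTrack

__all__ = ["plot_track", "plot_volcano", "plot_box_summaries"]


def plot_track(track: ProbeTrack, path, chrom: str | None = None) -> None:
    """Plot the smoothed ratio profile of one chromosome."""
    chrom = chrom or track.chromosomes()[0]
    sub = track.data[track.data["chrom"] == chrom]
    fig, ax = plt.subplots(figsize=(10, 2.5))
    ax.plot((sub["start"] + sub["end"]) / 2 / 1000, sub["ratio"], lw=0.7)
    ax.set_xlabel(f"{chrom} position (kb)")
    ax.set_ylabel("ChIP ratio")
    ax.set_title(track.label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_volcano(result: EnrichmentResult, path) -> None:
    """log2 fold change vs -log10 p, significant interactors highlighted."""
    rows = result.rows
    with np.errstate(divide="ignore"):
        neglog = -np.log10(rows["p"].to_numpy())
    neglog = np.clip(neglog, 0, 320)
    sig = rows["significant"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(rows["log2_fc"][~sig], neglog[~sig], s=6, c="0.6", label="background")
    ax.scatter(rows["log2_fc"][sig], neglog[sig], s=14, c="crimson", label="significant")
    ax.set_xlabel("log2 fold change (bait - ctrl)")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"gate: {result.gate} {result.params.get('fc_cutoff_log2', '')}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_box_summaries(summaries: list[SummarySignal], path, ylabel: str = "signal") -> None:
    """Render precomputed boxplot statistics (no raw data needed)."""
    fig, ax = plt.subplots(figsize=(1.2 * len(summaries) + 1, 4))
    stats = [
        {
            "med": s.median,
            "q1": s.q25,
            "q3": s.q75,
            "whislo": s.whisker_lo,
            "whishi": s.whisker_hi,
            "label": s.group,
        }
        for s in summaries
    ]
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
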