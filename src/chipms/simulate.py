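"""Seeded simulators for ChIP probe tracks and pull-down intensity tables.

Two binding-site classes drive the ChIP simulator, mirroring the biology of
a protein that occupies both chromosome-axis attachment sites and highly
transcribed genes:

* an *axis* component — Gaussian kernels of width ``kernel_sd`` centred on
  the genome's axis sites, scaled by each site's amplitude;
* a *transcription* component — signal proportional to the mRNA level of the
  gene covering (or, by the promoter rules, assigned to) each probe.

The simulated ratio at probe midpoint ``p`` is::

    ratio(p) = baseline
             + w_axis * sum_s A_s * exp(-(p - pos_s)^2 / (2 * kernel_sd^2))
             + w_txn  * txn_scale * mrna(p)
             + noise

With ``noise_sd=0`` the track is the exact deterministic mixture, which the
test suite exploits as a closed-form oracle. Setting ``w_txn=0`` produces an
axis-only profile (a "transcription-independent" binding pattern); setting
``w_axis=0`` produces a transcription-coupled, RNA-pol-II-like profile.

The pull-down simulator emulates a label-free AP-MS experiment: a
proteins x samples log2-intensity matrix with bait and control replicates,
planted interactors whose bait intensities are elevated by a known log2 fold
change, and intensity-dependent (MNAR) missingness following
``P(missing) = logistic(alpha - beta * log2 intensity)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .genome import GenomeModel, assign_mrna
from .track import ProbeTrack

__all__ = [
    "ChipSimConfig",
    "ProteomicsSimConfig",
    "SimTruth",
    "simulate_chip_profile",
    "simulate_interactome_table",
]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    planted_summits: pd.DataFrame = None  # chrom, position, amplitude
    planted_interactors: pd.DataFrame = None  # protein_id, log2_fc

    def to_tsv(self, path) -> None:
        frames = []
        if self.planted_summits is not None:
            df = self.planted_summits.copy()
            df.insert(0, "kind", "summit")
            frames.append(df)
        if self.planted_interactors is not None:
            df = self.planted_interactors.copy()
            df.insert(0, "kind", "interactor")
            frames.append(df)
        pd.concat(frames, axis=0).to_csv(path, sep="\t", index=False)


@dataclass
class ChipSimConfig:
    probe_spacing: float = 290.0  # Agilent 44K-like density
    probe_length: int = 60
    jitter_frac: float = 0.1
    kernel_sd: float = 1000.0
    w_axis: float = 1.0
    w_txn: float = 0.0
    txn_scale: float = 0.5
    noise_sd: float = 0.1
    noise_model: str = "additive"  # or "multiplicative" (log-normal)
    baseline: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("w_axis", "w_txn", "txn_scale", "noise_sd", "kernel_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        if self.noise_model not in ("additive", "multiplicative"):
            raise ValueError("noise_model must be 'additive' or 'multiplicative'")


def _probe_grid(length: int, cfg: ChipSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Midpoints of a jittered probe grid covering one chromosome.

    Midpoints sit on the half-integer lattice so that an even-length closed
    interval [start, start + L - 1] has its exact midpoint at the returned
    value; the analytic mixture and the stored track then agree exactly.
    """
    nominal = np.arange(cfg.probe_spacing / 2, length, cfg.probe_spacing)
    jitter = rng.uniform(-0.5, 0.5, size=nominal.size) * cfg.jitter_frac * cfg.probe_spacing
    mids = np.floor(nominal + jitter) + 0.5
    half = cfg.probe_length / 2
    return mids[(mids - half >= 0) & (mids + half <= length)]


def expected_chip_signal(genome: GenomeModel, cfg: ChipSimConfig, chrom: str, mids: np.ndarray) -> np.ndarray:
    """Noise-free mixture value at the given midpoints (the analytic model)."""
    signal = np.full(mids.shape, cfg.baseline, dtype=float)
    if cfg.w_axis > 0 and not genome.axis_sites.empty:
        sites = genome.axis_sites[genome.axis_sites["chrom"] == chrom]
        for pos, amp in zip(sites["position"], sites["amplitude"]):
            signal += cfg.w_axis * amp * np.exp(-((mids - pos) ** 2) / (2 * cfg.kernel_sd**2))
    if cfg.w_txn > 0:
        levels, _ = assign_mrna(chrom, mids, genome.genes)
        signal += cfg.w_txn * cfg.txn_scale * np.nan_to_num(levels)
    return signal


def simulate_chip_profile(genome: GenomeModel, cfg: ChipSimConfig) -> tuple[ProbeTrack, SimTruth]:
    """Simulate a probe-level ChIP ratio track over the genome.

    Returns the track (sorted, non-overlapping probes; one probe roughly per
    ``probe_spacing``) and a :class:`SimTruth` whose planted summits are the
    genome's axis sites.
    """
    cfg.validate()
    genome.validate()
    # independent child streams: the probe layout must depend only on the
    # seed, never on whether noise is drawn, so that noisy tracks and their
    # noise-free templates share every probe
    rng_grid, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    rows = []
    for chrom, length in genome.chromosomes:
        mids = _probe_grid(length, cfg, rng_grid)
        signal = expected_chip_signal(genome, cfg, chrom, mids)
        if cfg.noise_sd > 0:
            eps = rng_noise.normal(0.0, cfg.noise_sd, size=mids.size)
            if cfg.noise_model == "additive":
                signal = signal + eps
            else:
                signal = signal * np.exp(eps)
        starts = (mids - cfg.probe_length / 2 + 0.5).astype(int)  # 1-based closed
        ends = (starts + cfg.probe_length - 1).astype(int)
        for s, e, r in zip(starts, ends, signal):
            rows.append((chrom, int(s), int(e), float(r)))
    track = ProbeTrack(
        data=pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio"]),
        label=f"sim(w_axis={cfg.w_axis:g}, w_txn={cfg.w_txn:g}, noise={cfg.noise_sd:g}, seed={cfg.seed})",
        history=[f"simulate_chip_profile(seed={cfg.seed})"],
    )
    truth = SimTruth(planted_summits=genome.axis_sites.copy())
    return track, truth


@dataclass
class ProteomicsSimConfig:
    n_proteins: int = 1500
    n_bait: int = 3  # three biological replicates per condition
    n_ctrl: int = 3
    interactors: list[tuple[str, float]] = field(default_factory=list)  # (protein_id, true log2FC)
    base_mean: float = 25.0  # log2-intensity scale of a typical LFQ run
    base_sd: float = 2.0
    rep_sd: float = 0.3
    missing_alpha: float = 17.5
    missing_beta: float = 0.8
    missing_enabled: bool = True
    decoy_fraction: float = 0.02  # reverse / contaminant / only-by-site each
    single_peptide_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_bait < 2 or self.n_ctrl < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        ids = {pid for pid, _ in self.interactors}
        if len(ids) != len(self.interactors):
            raise ValueError("duplicate interactor ids")
        for pid, _ in self.interactors:
            if not self._valid_id(pid):
                raise ValueError(f"interactor id {pid!r} outside protein id range")

    def _valid_id(self, pid: str) -> bool:
        return pid in set(self.protein_ids())

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_proteins + 1)]


def default_interactors(n: int = 9, log2_fc: float = 8.0, start: int = 1) -> list[tuple[str, float]]:
    """Convenience set of planted interactors (ids P0001.. by default)."""
    return [(f"P{i:04d}", log2_fc) for i in range(start, start + n)]


def simulate_interactome_table(cfg: ProteomicsSimConfig):
    """Simulate a protein-group intensity table for a bait-vs-control pull-down.

    Each protein has a log-normal base abundance; bait-condition cells of
    planted interactors are shifted up by their true log2 fold change; MNAR
    missingness is then applied cell-wise.  Returns an
    :class:`~chipms.proteomics.IntensityTable` and the matching truth.
    """
    from .proteomics import IntensityTable  # local import to avoid a cycle

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ids = cfg.protein_ids()
    n = cfg.n_proteins
    fc_map = dict(cfg.interactors)

    base = rng.normal(cfg.base_mean, cfg.base_sd, size=n)
    samples = [f"bait_{i+1}" for i in range(cfg.n_bait)] + [
        f"ctrl_{i+1}" for i in range(cfg.n_ctrl)
    ]
    conditions = pd.Series(
        ["bait"] * cfg.n_bait + ["ctrl"] * cfg.n_ctrl, index=samples, name="condition"
    )
    log2 = base[:, None] + rng.normal(0.0, cfg.rep_sd, size=(n, len(samples)))
    fc = np.array([fc_map.get(pid, 0.0) for pid in ids])
    log2[:, : cfg.n_bait] += fc[:, None]

    if cfg.missing_enabled:
        p_missing = expit(cfg.missing_alpha - cfg.missing_beta * log2)
        missing = rng.random(log2.shape) < p_missing
    else:
        missing = np.zeros(log2.shape, dtype=bool)

    intensities = np.power(2.0, log2)
    intensities[missing] = np.nan

    flags = pd.DataFrame(
        {
            "protein_id": ids,
            "is_reverse": rng.random(n) < cfg.decoy_fraction,
            "is_contaminant": rng.random(n) < cfg.decoy_fraction,
            "only_by_site": rng.random(n) < cfg.decoy_fraction,
            "unique_razor_peptides": np.where(
                rng.random(n) < cfg.single_peptide_fraction, 1, 2 + rng.poisson(5, size=n)
            ),
        }
    )
    # planted interactors are always clean, well-identified entries
    planted = flags["protein_id"].isin(fc_map)
    flags.loc[planted, ["is_reverse", "is_contaminant", "only_by_site"]] = False
    flags.loc[planted, "unique_razor_peptides"] = np.maximum(
        flags.loc[planted, "unique_razor_peptides"], 2
    )

    table = IntensityTable(
        proteins=flags,
        intensities=pd.DataFrame(intensities, index=ids, columns=samples),
        conditions=conditions,
    )
    truth = SimTruth(
        planted_interactors=pd.DataFrame(cfg.interactors, columns=["protein_id", "log2_fc"])
    )
    return table, truth
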