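"""Synthetic genome models: chromosomes, genes, axis sites and DSB hotspots.

The genome model is the ground truth against which every downstream stage
(track conditioning, peak calling, profile comparison) is tested. It emulates
the coordinate conventions of a small budding-yeast-like genome: a handful of
chromosomes a few hundred kb long, densely packed non-overlapping genes, axis
attachment sites spaced quasi-regularly every 15-20 kb, and DSB hotspots at a
subset of gene promoters.

Coordinates are 1-based, fully closed intervals throughout the package; BED
export converts to the 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "GenomeModel",
    "simulate_genome",
    "assign_mrna",
    "write_genes_gff3",
    "write_sites_bed",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "mrna_level"]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mrna_level: float


@dataclass
class GenomeModel:
    """Chromosomes, genes (with expression levels), axis sites and hotspots.

    ``chromosomes``: list of (name, length bp).
    ``genes``: DataFrame with columns gene_id, chrom, start, end, strand,
    mrna_level; sorted and non-overlapping per chromosome.
    ``axis_sites``: DataFrame chrom, position, amplitude.
    ``hotspots``: DataFrame chrom, position.
    """

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame
    axis_sites: pd.DataFrame
    hotspots: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        lengths = self.chrom_lengths
        g = self.genes
        if list(g.columns) != GENE_COLUMNS:
            raise ValueError(f"gene table must have columns {GENE_COLUMNS}")
        if not g.empty:
            if not g["strand"].isin(["+", "-"]).all():
                raise ValueError("gene strand must be '+' or '-'")
            if not np.isfinite(g["mrna_level"]).all() or (g["mrna_level"] < 0).any():
                raise ValueError("mrna_level must be finite and non-negative")
            for chrom, sub in g.groupby("chrom", sort=False):
                if chrom not in lengths:
                    raise ValueError(f"gene on unknown chromosome {chrom!r}")
                s = sub.sort_values("start")
                if (s["start"] < 1).any() or (s["end"] > lengths[chrom]).any():
                    raise ValueError(f"gene outside chromosome {chrom!r}")
                if (s["start"] > s["end"]).any():
                    raise ValueError("gene start must be <= end")
                if (s["start"].values[1:] <= s["end"].values[:-1]).any():
                    raise ValueError(f"overlapping genes on {chrom!r}")
        for name, df in (("axis site", self.axis_sites), ("hotspot", self.hotspots)):
            for _, row in df.iterrows():
                length = lengths.get(row["chrom"])
                if length is None or not (1 <= row["position"] <= length):
                    raise ValueError(f"{name} outside its chromosome: {dict(row)}")
        if not self.axis_sites.empty and (self.axis_sites["amplitude"] <= 0).any():
            raise ValueError("axis site amplitudes must be > 0")


def simulate_genome(
    chromosomes: list[tuple[str, int]] | None = None,
    n_genes: int = 150,
    axis_spacing: tuple[float, float] = (15_000, 20_000),
    n_axis_sites: int | None = None,
    hotspot_fraction: float = 0.2,
    gene_length: tuple[float, float] = (500, 2_500),
    gene_gap: tuple[float, float] = (200, 800),
    mrna_sigma: float = 1.0,
    axis_amplitude_sigma: float = 0.25,
    seed: int = 0,
) -> GenomeModel:
    """Draw a seeded synthetic genome.

    Genes are packed left to right with uniform lengths and intergenic gaps,
    random strands, and log-normal mRNA levels (median 1, shape
    ``mrna_sigma``).  Axis sites are laid down quasi-regularly with spacing
    drawn uniformly from ``axis_spacing`` and log-normal amplitudes around 1.
    ``n_axis_sites=0`` disables axis sites entirely; a positive value caps the
    spacing-driven count.  Hotspots mark the promoters of a random
    ``hotspot_fraction`` of genes.

    Raises ``ValueError`` when the requested gene count cannot be packed into
    the genome at the minimum length+gap.
    """
    if chromosomes is None:
        chromosomes = [("chr1", 300_000), ("chr2", 300_000)]
    rng = np.random.default_rng(seed)
    total = sum(length for _, length in chromosomes)
    min_footprint = gene_length[0] + gene_gap[0]
    if n_genes * min_footprint > total:
        raise ValueError(
            f"cannot pack {n_genes} genes (min footprint {min_footprint} bp) "
            f"into {total} bp of genome"
        )

    # apportion genes to chromosomes by length (largest remainder)
    quotas = {}
    assigned = 0
    fracs = []
    for name, length in chromosomes:
        exact = n_genes * length / total
        quotas[name] = int(exact)
        assigned += int(exact)
        fracs.append((exact - int(exact), name))
    for _, name in sorted(fracs, reverse=True)[: n_genes - assigned]:
        quotas[name] += 1

    records = []
    idx = 0
    for name, length in chromosomes:
        pos = 1
        placed = 0
        while placed < quotas[name]:
            pos += int(rng.uniform(*gene_gap))
            glen = int(rng.uniform(*gene_length))
            if pos + glen - 1 > length:
                raise ValueError(
                    f"ran out of space on {name} after {placed} of "
                    f"{quotas[name]} genes; reduce n_genes"
                )
            idx += 1
            records.append(
                (
                    f"g{idx:04d}",
                    name,
                    pos,
                    pos + glen - 1,
                    "+" if rng.random() < 0.5 else "-",
                    float(rng.lognormal(0.0, mrna_sigma)),
                )
            )
            pos += glen
            placed += 1
    genes = pd.DataFrame(records, columns=GENE_COLUMNS)

    axis_records = []
    if n_axis_sites != 0:
        for name, length in chromosomes:
            pos = rng.uniform(*axis_spacing) / 2
            while pos < length:
                axis_records.append(
                    (name, int(pos), float(rng.lognormal(0.0, axis_amplitude_sigma)))
                )
                pos += rng.uniform(*axis_spacing)
        if n_axis_sites is not None:
            axis_records = axis_records[:n_axis_sites]
    axis_sites = pd.DataFrame(axis_records, columns=["chrom", "position", "amplitude"])

    hot_records = []
    if hotspot_fraction > 0 and not genes.empty:
        n_hot = int(round(hotspot_fraction * len(genes)))
        chosen = rng.choice(len(genes), size=n_hot, replace=False)
        lengths = dict(chromosomes)
        for i in sorted(chosen):
            row = genes.iloc[i]
            pos = row["start"] - 100 if row["strand"] == "+" else row["end"] + 100
            pos = int(np.clip(pos, 1, lengths[row["chrom"]]))
            hot_records.append((row["chrom"], pos))
    hotspots = pd.DataFrame(hot_records, columns=["chrom", "position"])

    return GenomeModel(
        chromosomes=list(chromosomes),
        genes=genes,
        axis_sites=axis_sites,
        hotspots=hotspots,
        meta={"seed": seed, "n_genes": n_genes},
    )


def assign_mrna(chrom: str, midpoints: np.ndarray, genes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Assign an mRNA level to each probe midpoint on one chromosome.

    Returns ``(levels, classes)`` where ``levels`` is float (NaN when
    unassigned) and ``classes`` is one of ``gene_body``, ``promoter_single``,
    ``promoter_divergent``, ``unassigned``.

    Rules (orientation-based, no fixed promoter size):

    * midpoint inside a gene body -> that gene's level;
    * intergenic, upstream (5') of exactly one flanking gene -> that gene's
      level (the probe sits in its promoter);
    * intergenic between two genes transcribed away from each other
      (divergent, ``<- ->``) -> the unweighted mean of both levels;
    * intergenic between two genes transcribed toward each other
      (convergent, ``-> <-``) -> unassigned (downstream of both).
    """
    sub = genes[genes["chrom"] == chrom].sort_values("start")
    n = len(midpoints)
    levels = np.full(n, np.nan)
    classes = np.full(n, "unassigned", dtype=object)
    if sub.empty:
        return levels, classes
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    strands = sub["strand"].to_numpy()
    mrna = sub["mrna_level"].to_numpy()

    # index of last gene starting at or before the midpoint
    left = np.searchsorted(starts, midpoints, side="right") - 1
    for i, m in enumerate(midpoints):
        li = left[i]
        if li >= 0 and m <= ends[li]:
            levels[i] = mrna[li]
            classes[i] = "gene_body"
            continue
        # intergenic: li is the gene to the left (or -1), li+1 to the right
        ri = li + 1
        left_promoter = li >= 0 and strands[li] == "-"  # '-' gene: promoter on its right
        right_promoter = ri < len(starts) and strands[ri] == "+"
        if left_promoter and right_promoter:
            levels[i] = 0.5 * (mrna[li] + mrna[ri])
            classes[i] = "promoter_divergent"
        elif left_promoter:
            levels[i] = mrna[li]
            classes[i] = "promoter_single"
        elif right_promoter:
            levels[i] = mrna[ri]
            classes[i] = "promoter_single"
    return levels, classes


def write_genes_gff3(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for _, g in genome.genes.iterrows():
            attrs = f"ID={g.gene_id};mrna_level={g.mrna_level:.6g}"
            fh.write(
                f"{g.chrom}\tchipms\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_sites_bed(sites: pd.DataFrame, path, name_prefix: str = "site") -> None:
    """Write point features (chrom, position[, amplitude]) as 1-bp BED."""
    with open(path, "w") as fh:
        for i, row in enumerate(sites.itertuples(index=False), start=1):
            score = getattr(row, "amplitude", 0.0)
            fh.write(
                f"{row.chrom}\t{row.position - 1}\t{row.position}\t"
                f"{name_prefix}{i}\t{score:.6g}\n"
            )
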