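"""Miniature genome models for simulated aCGH cohorts.

A :class:`GenomeModel` describes the assay design: chromosomes with
centromere positions, gene intervals, and the oligonucleotide probes that
tile each gene.  The default genome is a deliberately small stand-in for a
60K CGH array — 8 chromosomes, ~100 genes each, 2–12 probes per gene — so
that every downstream stage (probe averaging, calling, clustering) runs in
seconds while still exercising the gene-size sweep from >=2 up to >=10
probes per gene.

All coordinates are 0-based, half-open, matching BED conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: Chromosomes carrying the recurrent arm events this package models
#: (8q/20q gains, 5q/21q losses, plus arms used by the lineage archetypes).
DEFAULT_CHROM_NAMES: tuple[str, ...] = (
    "chr5", "chr7", "chr8", "chr13", "chr17", "chr18", "chr20", "chr21",
)

_GENE_BP_PER_PROBE = 10_000
_GENE_GAP = 5_000
_PROBE_LENGTH = 60  # 60-mer oligonucleotides
_CENTROMERE_FRACTION = 0.4

# Probe-count distribution for the default genome: skewed toward small
# genes, spanning 2..12 so the >=2 ... >=10 sweep is exercisable.
_DEFAULT_PROBE_COUNTS = np.arange(2, 13)
_DEFAULT_PROBE_WEIGHTS = np.array(
    [0.24, 0.16, 0.14, 0.12, 0.10, 0.08, 0.06, 0.04, 0.03, 0.02, 0.01]
)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    probe_count: int


@dataclass(frozen=True)
class Probe:
    probe_id: str
    chrom: str
    position: int
    gene_id: str | None  # None for intergenic probes


@dataclass
class GenomeModel:
    """Chromosomes, gene intervals and probe positions of one array design."""

    chromosomes: list[Chromosome]
    genes: list[Gene]
    probes: list[Probe]
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._gene_index = {g.gene_id: i for i, g in enumerate(self.genes)}
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        chrom = {c.name: c for c in self.chromosomes}
        for g in self.genes:
            if g.chrom not in chrom:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= chrom[g.chrom].length):
                raise ValueError(f"gene {g.gene_id} interval outside chromosome")
        seen_pos: set[tuple[str, int]] = set()
        per_gene = {g.gene_id: 0 for g in self.genes}
        for p in self.probes:
            key = (p.chrom, p.position)
            if key in seen_pos:
                raise ValueError(f"duplicate probe position {key}")
            seen_pos.add(key)
            if p.gene_id is not None:
                g = self.genes[self._gene_index[p.gene_id]]
                if not (g.start <= p.position < g.end):
                    raise ValueError(
                        f"probe {p.probe_id} outside its gene {p.gene_id}"
                    )
                per_gene[p.gene_id] += 1
        for g in self.genes:
            if per_gene[g.gene_id] != g.probe_count:
                raise ValueError(
                    f"gene {g.gene_id}: probe_count={g.probe_count} but "
                    f"{per_gene[g.gene_id]} probe records point to it"
                )

    # -- arms ----------------------------------------------------------
    def arm_of(self, chrom: str, position: float) -> str:
        """Arm name ("chr8q" style) for a genomic position (midpoint rule)."""
        for c in self.chromosomes:
            if c.name == chrom:
                return f"{chrom}p" if position < c.centromere else f"{chrom}q"
        raise KeyError(f"unknown chromosome: {chrom}")

    def gene_arm(self, gene: Gene) -> str:
        return self.arm_of(gene.chrom, (gene.start + gene.end) / 2)

    def arm_names(self) -> list[str]:
        return [f"{c.name}{a}" for c in self.chromosomes for a in ("p", "q")]

    def genes_on_arm(self, arm: str) -> np.ndarray:
        """Indices (into ``self.genes``) of genes whose midpoint lies on *arm*."""
        if arm not in self.arm_names():
            raise KeyError(f"unknown arm: {arm}")
        return np.array(
            [i for i, g in enumerate(self.genes) if self.gene_arm(g) == arm],
            dtype=int,
        )

    def gene_index(self, gene_id: str) -> int:
        return self._gene_index[gene_id]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    # -- tabular views -------------------------------------------------
    def genes_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": "+",
                "probe_count": [g.probe_count for g in self.genes],
            }
        )

    def probes_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in self.probes],
                "chrom": [p.chrom for p in self.probes],
                "start": [p.position for p in self.probes],
                "end": [p.position + _PROBE_LENGTH for p in self.probes],
                "gene_id": [p.gene_id for p in self.probes],
            }
        )

    def arms_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.name for c in self.chromosomes],
                "centromere": [c.centromere for c in self.chromosomes],
                "length": [c.length for c in self.chromosomes],
            }
        )


def build_genome(
    n_chromosomes: int = 8,
    genes_per_chromosome: int = 100,
    probe_count_distribution: int
    | Sequence[int]
    | Callable[[np.random.Generator, int], np.ndarray]
    | None = None,
    seed: int = 0,
    chrom_names: Sequence[str] | None = None,
) -> GenomeModel:
    """Construct a deterministic miniature genome.

    Parameters
    ----------
    probe_count_distribution
        How many probes each gene gets: an ``int`` (every gene identical), a
        sequence of candidate counts (sampled uniformly), a callable
        ``f(rng, n) -> int array``, or ``None`` for the default skewed
        2..12 distribution.
    seed
        Seeds gene-size draws; fixed seed gives an identical genome.

    Gene length is proportional to probe count (larger genes carry more
    probes, the premise of the gene-size sweep); genes are laid end to end
    and the centromere sits at 40% of each chromosome's final length.
    """
    if n_chromosomes < 1:
        raise ValueError(f"n_chromosomes must be >=1, got {n_chromosomes}")
    if genes_per_chromosome < 1:
        raise ValueError(
            f"genes_per_chromosome must be >=1, got {genes_per_chromosome}"
        )
    if chrom_names is None:
        if n_chromosomes <= len(DEFAULT_CHROM_NAMES):
            chrom_names = DEFAULT_CHROM_NAMES[:n_chromosomes]
        else:
            chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    elif len(chrom_names) != n_chromosomes:
        raise ValueError("chrom_names length must equal n_chromosomes")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chromosomes: list[Chromosome] = []
    genes: list[Gene] = []
    probes: list[Probe] = []

    for cname in chrom_names:
        counts = _draw_probe_counts(
            probe_count_distribution, rng, genes_per_chromosome
        )
        pos = _GENE_GAP
        for gi, pc in enumerate(counts):
            glen = int(pc) * _GENE_BP_PER_PROBE
            gene_id = f"{cname}_g{gi:03d}"
            genes.append(Gene(gene_id, cname, pos, pos + glen, int(pc)))
            for pj in range(int(pc)):
                ppos = pos + (pj + 1) * glen // (int(pc) + 1)
                probes.append(Probe(f"{gene_id}_p{pj}", cname, ppos, gene_id))
            pos += glen + _GENE_GAP
        length = pos + _GENE_GAP
        chromosomes.append(
            Chromosome(cname, length, int(length * _CENTROMERE_FRACTION))
        )
    return GenomeModel(chromosomes, genes, probes)


def _draw_probe_counts(dist, rng: np.random.Generator, n: int) -> np.ndarray:
    if dist is None:
        counts = rng.choice(_DEFAULT_PROBE_COUNTS, size=n, p=_DEFAULT_PROBE_WEIGHTS)
    elif isinstance(dist, int):
        counts = np.full(n, dist, dtype=int)
    elif callable(dist):
        counts = np.asarray(dist(rng, n), dtype=int)
    else:
        counts = rng.choice(np.asarray(list(dist), dtype=int), size=n)
    if counts.min() < 1:
        raise ValueError("probe counts must be >=1")
    return counts
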