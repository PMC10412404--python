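"""Mutation backgrounds: the null against which observed mutations are judged.

The driver statistics compare each gene's observed EA distribution and burden
with what random mutagenesis of the same reference genome would produce. The
default background enumerates *every* possible coding SNV (each coding
position x 3 alternate bases, once per containing gene) — the deterministic
limit of random mutation simulation, exact and cheap for bacterial genomes.
A sampled mode (uniform random SNVs over the genome) and a custom mode (a
user-supplied mutation file, parsed exactly like observed data) are provided
for parity with app-style workflows and for empirical null sets.

Per-gene EA pools hold the background missense EA values; the genome-wide
pool is their union. ``scope`` selects which one a gene's KS/sum null uses
(per-gene controls each gene's own EA spectrum and is the default).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ea import EAScoreTable
from .reference import ReferenceGenome
from .variants import (MISSENSE, NONSENSE, IngestReport, ProteinEffect,
                       VariantRecord, _effect_for_gene, annotate, dedupe,
                       effects_from_substitutions, read_gd,
                       read_substitutions, read_vcf)

_BASES = "ACGT"


@dataclass
class BackgroundSet:
    """Background EA pools and mutational-opportunity counts per gene."""

    mode: str  # exhaustive | sampled | custom
    pools: dict[str, np.ndarray]  # per-gene missense EA multisets
    opportunities: dict[str, int]  # possible coding SNVs per gene (3 x cds nt)
    n_enumerated: int  # SNV-gene pairs annotated to build the set
    seed: int | None = None
    _genome_pool: np.ndarray | None = field(default=None, repr=False)

    @property
    def genome_pool(self) -> np.ndarray:
        if self._genome_pool is None:
            parts = [p for p in self.pools.values() if p.size]
            self._genome_pool = (np.concatenate(parts) if parts
                                 else np.array([], dtype=float))
        return self._genome_pool

    def pool(self, gene: str, scope: str = "per_gene") -> np.ndarray:
        if scope == "genome_wide":
            return self.genome_pool
        return self.pools.get(gene, np.array([], dtype=float))

    @property
    def total_pool_size(self) -> int:
        return int(sum(p.size for p in self.pools.values()))


def enumerate_coding_snvs(genome: ReferenceGenome,
                          ea_table: EAScoreTable | None
                          ) -> list[ProteinEffect]:
    """Annotate every coding position x 3 alternate bases, per containing gene.

    Returns one effect per (SNV, gene) pair — a position shared by two
    overlapping genes appears once for each, matching how observed variants
    are annotated (consistent numerator and denominator).
    """
    effects: list[ProteinEffect] = []
    for gene in sorted(genome.genes, key=lambda g: g.locus_tag):
        seq = genome.contigs[gene.contig]
        for pos in range(gene.start, gene.end + 1):
            ref = seq[pos - 1]
            for alt in _BASES:
                if alt == ref:
                    continue
                v = VariantRecord(gene.contig, pos, ref, alt, strain="")
                effects.append(_effect_for_gene(genome, gene, v, ea_table))
    return effects


def _pools_from_effects(effects: Iterable[ProteinEffect],
                        genome: ReferenceGenome, *,
                        stop_gain_score: float | None = None
                        ) -> dict[str, np.ndarray]:
    raw: dict[str, list[float]] = {g.locus_tag: [] for g in genome.genes}
    for e in effects:
        if e.effect == MISSENSE and e.ea is not None:
            raw[e.gene].append(e.ea)
        elif e.effect == NONSENSE and stop_gain_score is not None:
            raw[e.gene].append(stop_gain_score)
    return {g: np.sort(np.array(v, dtype=float)) for g, v in raw.items()}


def _opportunities(genome: ReferenceGenome) -> dict[str, int]:
    return {g.locus_tag: 3 * g.cds_length for g in genome.genes}


def enumerate_background(genome: ReferenceGenome, ea_table: EAScoreTable, *,
                         stop_gain_score: float | None = None,
                         snv_catalog: Sequence[ProteinEffect] | None = None
                         ) -> BackgroundSet:
    """Exhaustive background: all possible coding SNVs, deterministically.

    Enumerates 3 SNVs per coding nucleotide (3 x coding_length_total SNV-gene
    pairs in total) and pools the EA of every reachable, scored missense per
    gene. Pass a precomputed ``snv_catalog`` to reuse the enumeration.
    """
    effects = (list(snv_catalog) if snv_catalog is not None
               else enumerate_coding_snvs(genome, ea_table))
    return BackgroundSet(
        mode="exhaustive",
        pools=_pools_from_effects(effects, genome,
                                  stop_gain_score=stop_gain_score),
        opportunities=_opportunities(genome),
        n_enumerated=len(effects))


def sample_background(genome: ReferenceGenome, ea_table: EAScoreTable,
                      n_mutations: int, seed: int, *,
                      stop_gain_score: float | None = None) -> BackgroundSet:
    """Sampled background: n uniform random SNVs over the whole genome.

    Positions are drawn uniformly over (genomic position x 3 alternate bases)
    with replacement — no transition/transversion bias — then annotated like
    observed data; intergenic draws contribute nothing to the pools.
    Deterministic under ``seed``.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    rng = np.random.default_rng(seed)
    contigs = sorted(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contigs])
    total = lengths.sum()
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    flat = rng.integers(0, total, size=n_mutations)
    alt_idx = rng.integers(0, 3, size=n_mutations)
    effects: list[ProteinEffect] = []
    n_annotated = 0
    for f, ai in zip(flat, alt_idx):
        ci = int(np.searchsorted(offsets, f, side="right") - 1)
        contig = contigs[ci]
        pos = int(f - offsets[ci]) + 1
        ref = genome.base_at(contig, pos)
        alt = [b for b in _BASES if b != ref][ai] if ref in _BASES else None
        if alt is None:
            continue
        v = VariantRecord(contig, pos, ref, alt, strain="")
        genes = genome.genes_at(contig, pos)
        for gene in genes:
            effects.append(_effect_for_gene(genome, gene, v, ea_table))
        n_annotated += 1
    return BackgroundSet(
        mode="sampled",
        pools=_pools_from_effects(effects, genome,
                                  stop_gain_score=stop_gain_score),
        opportunities=_opportunities(genome),
        n_enumerated=n_annotated, seed=seed)


def load_custom_background(path: str | Path, fmt: str,
                           genome: ReferenceGenome, ea_table: EAScoreTable, *,
                           strain: str = "background",
                           stop_gain_score: float | None = None
                           ) -> BackgroundSet:
    """Custom background from a user mutation file (vcf | gd | substitutions).

    The file is parsed and annotated exactly like observed data. An empty
    usable background (no scored missense anywhere) is a hard error: the
    statistics are undefined against it.
    """
    report = IngestReport()
    if fmt == "vcf":
        effects = annotate(read_vcf(path, strain, report=report), genome,
                           ea_table)
    elif fmt == "gd":
        effects = annotate(read_gd(path, strain, genome, report=report),
                           genome, ea_table)
    elif fmt == "substitutions":
        effects = effects_from_substitutions(
            read_substitutions(path, default_strain=strain, report=report),
            genome, ea_table)
    else:
        raise ValueError(f"unknown background format {fmt!r}")
    pools = _pools_from_effects(effects, genome,
                                stop_gain_score=stop_gain_score)
    bg = BackgroundSet(mode="custom", pools=pools,
                       opportunities=_opportunities(genome),
                       n_enumerated=len(effects))
    if bg.genome_pool.size == 0:
        raise ValueError(
            f"custom background {path} yields no usable (scored missense) "
            "mutations; statistics are undefined")
    return bg
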