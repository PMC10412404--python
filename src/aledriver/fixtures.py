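"""Deterministic synthetic fixtures: genome, EA table, evolved-strain mutations.

Everything the pipeline consumes can be generated here from one seed: a toy
bacterial genome (random codon usage, valid start/stop, both strands, short
intergenic spacers) written as GenBank, a synthetic EA table covering every
reachable missense, and per-strain mutation sets written in all three input
dialects (VCF, GenomeDiff, substitution list) so format-equivalence is
testable end to end.

The mutation model mirrors an adaptive-laboratory-evolution design: several
replicate strains each carry a number of neutral mutations drawn uniformly
over all possible coding SNVs, while designated driver genes receive extra
mutations whose EA is biased toward the top of that gene's spectrum.
``ea_bias`` in [-1, 1] is the probability that an extra mutation is drawn
from the gene's top EA quartile (negative values use the bottom quartile —
a low-impact, high-count decoy), 0 means uniform, 1.0 means every extra
comes from the top quartile.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .background import enumerate_coding_snvs
from .ea import EAScoreTable, synth_ea_table, write_ea_table
from .reference import (GeneModel, ReferenceGenome, reverse_complement,
                        translate_codon)
from .variants import MISSENSE, ProteinEffect

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS)


@dataclass(frozen=True)
class DriverSpec:
    """One seeded driver gene: how many extra mutations, with what EA bias."""

    locus_tag: str
    n_extra: int
    ea_bias: float  # [-1, 1]; see module docstring

    def __post_init__(self):
        if not -1.0 <= self.ea_bias <= 1.0:
            raise ValueError("ea_bias must lie in [-1, 1]")
        if self.n_extra < 0:
            raise ValueError("n_extra must be >= 0")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic ALE experiment."""

    n_genes: int = 50
    gene_length_range: tuple[int, int] = (300, 900)  # nt, multiples of 3
    n_strains: int = 5
    neutral_per_strain: int = 20
    drivers: list[DriverSpec] = field(default_factory=list)
    seed: int = 0
    intergenic_range: tuple[int, int] = (20, 60)
    minus_strand_fraction: float = 0.5
    contig: str = "chr1"

    def __post_init__(self):
        if self.n_genes < 1 or self.n_strains < 0 or self.neutral_per_strain < 0:
            raise ValueError("counts must be non-negative (n_genes >= 1)")


@dataclass
class FixtureSet:
    """In-memory objects plus the file paths one fixture run produced."""

    genome: ReferenceGenome
    ea_table: EAScoreTable
    effects: list[ProteinEffect]  # simulated observed effects, all strains
    truth: list[DriverSpec]
    genbank: Path | None = None
    ea_path: Path | None = None
    vcf_paths: dict[str, Path] = field(default_factory=dict)
    gd_paths: dict[str, Path] = field(default_factory=dict)
    substitutions_path: Path | None = None
    truth_path: Path | None = None


def _locus_tag(i: int) -> str:
    return f"ALE_{i + 1:04d}"


def build_genome(spec: FixtureSpec,
                 rng: np.random.Generator) -> ReferenceGenome:
    """Random toy genome: ATG ... sense codons ... TAA, spacers between genes."""
    lo, hi = spec.gene_length_range
    pieces: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0

    def spacer() -> str:
        n = int(rng.integers(spec.intergenic_range[0],
                             spec.intergenic_range[1] + 1))
        return "".join(rng.choice(list("ACGT"), size=n))

    for i in range(spec.n_genes):
        gap = spacer()
        pieces.append(gap)
        cursor += len(gap)
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
        cds = "ATG" + "".join(body) + "TAA"
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        genomic = cds if strand == "+" else reverse_complement(cds)
        start = cursor + 1
        end = cursor + len(cds)
        pieces.append(genomic)
        cursor = end
        prot = "".join(translate_codon(cds[j:j + 3])
                       for j in range(0, len(cds) - 3, 3))
        genes.append(GeneModel(locus_tag=_locus_tag(i), gene_name=f"g{i + 1:03d}",
                               contig=spec.contig, start=start, end=end,
                               strand=strand, protein_seq=prot))
    pieces.append(spacer())
    return ReferenceGenome({spec.contig: "".join(pieces)}, genes)


def _driver_extras(catalog: Sequence[ProteinEffect], driver: DriverSpec,
                   rng: np.random.Generator) -> list[ProteinEffect]:
    rows = [e for e in catalog
            if e.gene == driver.locus_tag and e.effect == MISSENSE
            and e.ea is not None]
    if not rows:
        raise ValueError(f"driver gene {driver.locus_tag} has no scored "
                         "missense to draw from")
    eas = np.array([e.ea for e in rows])
    if driver.ea_bias >= 0:
        cut = np.quantile(eas, 0.75)
        biased = [e for e in rows if e.ea >= cut]
    else:
        cut = np.quantile(eas, 0.25)
        biased = [e for e in rows if e.ea <= cut]
    out = []
    for _ in range(driver.n_extra):
        src = biased if rng.random() < abs(driver.ea_bias) else rows
        out.append(src[int(rng.integers(0, len(src)))])
    return out


def simulate_mutations(genome: ReferenceGenome, spec: FixtureSpec,
                       rng: np.random.Generator,
                       catalog: Sequence[ProteinEffect]
                       ) -> list[ProteinEffect]:
    """Draw the observed mutation set for every strain.

    Neutral mutations are uniform over the coding-SNV catalog; driver extras
    follow each driver's EA bias and land in random strains. Within a strain,
    draws are unique at the amino-acid-substitution level so the same set is
    representable losslessly in VCF, GD and substitution-list form.
    """
    strains = [f"s{i + 1}" for i in range(spec.n_strains)]
    if spec.drivers and not strains:
        strains = ["s1"]
    for d in spec.drivers:
        genome.gene(d.locus_tag)  # raises if a driver gene is absent
    taken: dict[str, set] = {s: set() for s in strains}
    out: list[ProteinEffect] = []

    def place(effect: ProteinEffect, strain: str) -> bool:
        key = (effect.gene, effect.codon_index, effect.ref_aa, effect.alt_aa)
        if key in taken[strain]:
            return False
        taken[strain].add(key)
        out.append(dataclasses.replace(effect, strain=strain))
        return True

    for strain in strains:
        placed = 0
        while placed < spec.neutral_per_strain:
            e = catalog[int(rng.integers(0, len(catalog)))]
            if place(e, strain):
                placed += 1
    for driver in spec.drivers:
        for e in _driver_extras(catalog, driver, rng):
            for _ in range(100):  # resample the strain on collision
                strain = strains[int(rng.integers(0, len(strains)))]
                if place(e, strain):
                    break
    return out


def write_genbank(genome: ReferenceGenome, path: str | Path) -> None:
    """Write the genome as a GenBank flat file (round-trips via the loader)."""
    records = []
    for contig, seq in genome.contigs.items():
        rec = SeqRecord(Seq(seq), id=contig, name=contig[:16],
                        description="synthetic fixture genome",
                        annotations={"molecule_type": "DNA",
                                     "topology": "circular"})
        for g in sorted(genome.genes, key=lambda g: g.start):
            if g.contig != contig:
                continue
            loc = FeatureLocation(g.start - 1, g.end,
                                  strand=1 if g.strand == "+" else -1)
            feat = SeqFeature(loc, type="CDS", qualifiers={
                "locus_tag": [g.locus_tag], "gene": [g.gene_name],
                "transl_table": ["11"]})
            rec.features.append(feat)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def write_vcf(effects: Sequence[ProteinEffect], genome: ReferenceGenome,
              path: str | Path) -> None:
    """Minimal single-sample VCF 4.2 with the effects' genomic coordinates."""
    rows = sorted({(e.contig, e.pos, e.ref, e.alt) for e in effects},
                  key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in sorted(genome.contigs):
            fh.write(f"##contig=<ID={contig},length="
                     f"{len(genome.contigs[contig])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt in rows:
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_gd(effects: Sequence[ProteinEffect], path: str | Path) -> None:
    """Minimal breseq GenomeDiff with one SNP entry per effect."""
    rows = sorted({(e.contig, e.pos, e.alt) for e in effects},
                  key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("#=GENOME_DIFF\t1.0\n")
        for i, (contig, pos, alt) in enumerate(rows, 1):
            fh.write(f"SNP\t{i}\t.\t{contig}\t{pos}\t{alt}\n")


def write_substitutions(effects: Sequence[ProteinEffect],
                        path: str | Path) -> None:
    """Substitution-list dialect: locus_tag, refAA+pos+altAA, strain."""
    rows = sorted({(e.strain, e.gene, e.codon_index, e.ref_aa, e.alt_aa)
                   for e in effects if e.gene})
    with open(path, "w") as fh:
        fh.write("#gene\tsubstitution\tstrain\n")
        for strain, gene, ci, ref_aa, alt_aa in rows:
            fh.write(f"{gene}\t{ref_aa}{ci}{alt_aa}\t{strain}\n")


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureSet:
    """Generate and write a complete fixture set; byte-deterministic per seed.

    Emits genome.gb, ea_table.tsv, per-strain {strain}.vcf and {strain}.gd,
    a pooled substitutions.tsv, and truth.tsv listing the seeded drivers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.seed)
    rng_genome, rng_mut = (np.random.default_rng(s) for s in root.spawn(2))
    genome = build_genome(spec, rng_genome)
    ea_table = synth_ea_table(genome, spec.seed)
    catalog = enumerate_coding_snvs(genome, ea_table)
    effects = simulate_mutations(genome, spec, rng_mut, catalog)

    fx = FixtureSet(genome=genome, ea_table=ea_table, effects=effects,
                    truth=list(spec.drivers))
    fx.genbank = outdir / "genome.gb"
    write_genbank(genome, fx.genbank)
    fx.ea_path = outdir / "ea_table.tsv"
    write_ea_table(ea_table, genome, fx.ea_path)
    for strain in sorted({e.strain for e in effects}):
        sub = [e for e in effects if e.strain == strain]
        fx.vcf_paths[strain] = outdir / f"{strain}.vcf"
        write_vcf(sub, genome, fx.vcf_paths[strain])
        fx.gd_paths[strain] = outdir / f"{strain}.gd"
        write_gd(sub, fx.gd_paths[strain])
    fx.substitutions_path = outdir / "substitutions.tsv"
    write_substitutions(effects, fx.substitutions_path)
    fx.truth_path = outdir / "truth.tsv"
    with open(fx.truth_path, "w") as fh:
        fh.write("#locus_tag\tn_extra\tea_bias\n")
        for d in spec.drivers:
            fh.write(f"{d.locus_tag}\t{d.n_extra}\t{d.ea_bias}\n")
    return fx


def write_synthetic_pdb(protein_length: int, path: str | Path, *,
                        chain_id: str = "A") -> None:
    """Synthetic single-chain CA-only PDB (idealized helix), numbered from 1.

    A geometric stand-in for a predicted structure, sufficient for testing
    B-factor projection and round-trips; it is not a real protein model.
    """
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("synthetic")
    sb.init_model(0)
    sb.init_chain(chain_id)
    sb.init_seg("    ")
    for i in range(1, protein_length + 1):
        sb.init_residue("ALA", " ", i, " ")
        t = i * 100.0 * np.pi / 180.0
        coord = np.array([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i],
                         dtype=float)
        sb.init_atom("CA", coord, 0.0, 1.0, " ", " CA ", i, "C")
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))
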