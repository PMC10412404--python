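"""Annotated bacterial reference genomes.

Loads a GenBank flat file (or GFF3 + FASTA) into a light-weight genome model —
contig sequences plus one :class:`GeneModel` per usable CDS — and provides the
codon-level coordinate arithmetic needed to map genomic SNVs onto protein
substitutions. Coordinates are 1-based inclusive throughout, matching GenBank
and VCF conventions.

Only simple prokaryotic CDS features are supported: single-interval locations,
length divisible by 3, no internal stop codons. Features violating these rules
(pseudogenes, compound joins) are skipped and counted in the load report, since
per-residue impact scores are undefined for broken reading frames.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STOP = "*"
UNTRANSLATABLE = "X"

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_MAP: dict[str, str] = dict(_TABLE11.forward_table)
_CODON_MAP.update({c: STOP for c in _TABLE11.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon with the bacterial (table 11) genetic code.

    Returns the one-letter amino acid, ``"*"`` for a stop codon, or ``"X"``
    when the codon contains an ambiguous base and cannot be translated.
    Internal GTG/TTG translate as Val/Leu (initiation is not special-cased).
    """
    codon = codon.upper()
    try:
        return _CODON_MAP[codon]
    except KeyError:
        return UNTRANSLATABLE


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene: the unit at which drivers are ranked."""

    locus_tag: str
    gene_name: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    protein_seq: str  # literal table-11 translation, stop excluded

    @property
    def cds_length(self) -> int:
        return self.end - self.start + 1

    @property
    def protein_length(self) -> int:
        return len(self.protein_seq)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class LoadReport:
    """Counts of CDS features accepted/skipped while loading a genome."""

    n_cds_seen: int = 0
    n_loaded: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str, detail: str = "") -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1
        logger.info("skipping CDS (%s)%s", reason, f": {detail}" if detail else "")


class ReferenceGenome:
    """Contig sequences plus the usable CDS annotation, with position lookup."""

    def __init__(self, contigs: dict[str, str], genes: list[GeneModel],
                 report: LoadReport | None = None):
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
        self.contigs = {k: v.upper() for k, v in contigs.items()}
        self.genes = list(genes)
        self.report = report or LoadReport()
        self._by_tag = {g.locus_tag: g for g in self.genes}
        self._by_name: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            if g.gene_name:
                self._by_name.setdefault(g.gene_name, []).append(g)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            if not (1 <= g.start <= g.end <= len(self.contigs[g.contig])):
                raise ValueError(f"gene {g.locus_tag} outside contig {g.contig}")
            self._trees.setdefault(g.contig, IntervalTree()).addi(
                g.start, g.end + 1, g)

    @property
    def coding_length_total(self) -> int:
        return sum(g.cds_length for g in self.genes)

    def gene(self, locus_tag: str) -> GeneModel:
        return self._by_tag[locus_tag]

    def resolve_gene(self, name: str) -> GeneModel:
        """Resolve by locus tag first, then by unique gene name."""
        if name in self._by_tag:
            return self._by_tag[name]
        hits = self._by_name.get(name, [])
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise KeyError(f"unknown gene {name!r}")
        raise KeyError(f"gene name {name!r} is ambiguous: "
                       + ",".join(g.locus_tag for g in hits))

    def genes_at(self, contig: str, pos: int) -> list[GeneModel]:
        """All genes whose CDS contains the 1-based position (may overlap)."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: g.locus_tag)

    def base_at(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos - 1]

    def cds_sequence(self, gene: GeneModel) -> str:
        """The CDS nucleotide sequence on the coding strand."""
        raw = self.contigs[gene.contig][gene.start - 1:gene.end]
        return raw if gene.strand == "+" else reverse_complement(raw)

    def codon_at(self, locus_tag: str, genomic_pos: int) -> tuple[int, int, str]:
        """Locate a genomic position within a gene's reading frame.

        Returns ``(codon_index, offset_in_codon, codon)`` where codon_index is
        1-based (1 = start codon), offset_in_codon is 0..2 on the coding
        strand, and codon is the 3-nt codon oriented to the coding strand.
        """
        gene = self._by_tag[locus_tag]
        if not gene.contains(genomic_pos):
            raise ValueError(
                f"position {genomic_pos} outside gene {locus_tag} "
                f"({gene.start}-{gene.end})")
        if gene.strand == "+":
            off = genomic_pos - gene.start
        else:
            off = gene.end - genomic_pos
        codon_index, offset = divmod(off, 3)
        codon_index += 1
        if gene.strand == "+":
            s = gene.start - 1 + 3 * (codon_index - 1)
            codon = self.contigs[gene.contig][s:s + 3]
        else:
            e = gene.end - 3 * (codon_index - 1)
            codon = reverse_complement(self.contigs[gene.contig][e - 3:e])
        return codon_index, offset, codon


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _build_gene(contig_id: str, seq: str, locus_tag: str, gene_name: str,
                start: int, end: int, strand: str,
                report: LoadReport) -> GeneModel | None:
    length = end - start + 1
    if length % 3 != 0:
        report.skip("length_not_multiple_of_3", locus_tag)
        return None
    cds = seq[start - 1:end]
    if strand == "-":
        cds = reverse_complement(cds)
    aas = [translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3)]
    if UNTRANSLATABLE in aas:
        report.skip("ambiguous_bases", locus_tag)
        return None
    if aas[-1] != STOP:
        report.skip("missing_stop_codon", locus_tag)
        return None
    if STOP in aas[:-1]:
        report.skip("internal_stop_codon", locus_tag)
        return None
    return GeneModel(locus_tag=locus_tag, gene_name=gene_name, contig=contig_id,
                     start=start, end=end, strand=strand,
                     protein_seq="".join(aas[:-1]))


def load_genbank(path: str | Path) -> ReferenceGenome:
    """Load an annotated genome from a GenBank flat file.

    Every CDS feature with a locus_tag, a simple (non-join) location and an
    intact reading frame becomes a :class:`GeneModel`; everything else is
    skipped and tallied in the genome's load report. Raises ``ValueError``
    when no usable CDS is found.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    report = LoadReport()
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "genbank"))
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    for rec in records:
        seq = str(rec.seq).upper()
        contigs[rec.id] = seq
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            report.n_cds_seen += 1
            tags = feat.qualifiers.get("locus_tag")
            if not tags:
                report.skip("missing_locus_tag")
                continue
            if len(feat.location.parts) != 1:
                report.skip("compound_location", tags[0])
                continue
            start = int(feat.location.start) + 1  # biopython is 0-based
            end = int(feat.location.end)
            strand = "+" if feat.location.strand != -1 else "-"
            name = feat.qualifiers.get("gene", [""])[0]
            gene = _build_gene(rec.id, seq, tags[0], name, start, end, strand,
                               report)
            if gene is not None:
                genes.append(gene)
                report.n_loaded += 1
    if not genes:
        raise ValueError(f"no usable CDS features in {path}")
    return ReferenceGenome(contigs, genes, report)


def load_gff3_fasta(gff_path: str | Path, fasta_path: str | Path) -> ReferenceGenome:
    """Load a genome from GFF3 annotation plus a FASTA sequence file.

    Same post-conditions as :func:`load_genbank`; GenBank is the reference
    dialect. CDS features need a ``locus_tag`` attribute (falling back to
    ``ID``); multi-segment CDS (same ID on several lines) are skipped.
    """
    import gffutils

    with _open_text(fasta_path) as fh:
        contigs = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(fh, "fasta")}
    if not contigs:
        raise ValueError(f"no sequences in {fasta_path}")
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    report = LoadReport()
    genes: list[GeneModel] = []
    cds_by_key: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        key = (feat.attributes.get("locus_tag") or feat.attributes.get("ID")
               or [None])[0]
        report.n_cds_seen += 1
        if key is None:
            report.skip("missing_locus_tag")
            continue
        cds_by_key.setdefault(key, []).append(feat)
    for tag, feats in sorted(cds_by_key.items()):
        if len(feats) != 1:
            report.skip("compound_location", tag)
            continue
        feat = feats[0]
        if feat.seqid not in contigs:
            report.skip("unknown_contig", tag)
            continue
        name = (feat.attributes.get("gene") or [""])[0]
        strand = "-" if feat.strand == "-" else "+"
        gene = _build_gene(feat.seqid, contigs[feat.seqid], tag, name,
                           feat.start, feat.end, strand, report)
        if gene is not None:
            genes.append(gene)
            report.n_loaded += 1
    if not genes:
        raise ValueError(f"no usable CDS features in {gff_path}")
    return ReferenceGenome(contigs, genes, report)
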