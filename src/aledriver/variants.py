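"""Variant ingestion and protein-effect annotation.

Three input routes deliver evolved-strain mutations: VCF (via pysam), breseq
GenomeDiff (GD) text, and plain amino-acid substitution lists. All three feed
a unified stream — genomic routes as :class:`VariantRecord` which
:func:`annotate` projects onto protein substitutions, the substitution route
directly as :class:`ProteinEffect` via :func:`effects_from_substitutions`.

Variants from replicate strains are pooled; recurrence of the same mutation
across strains is kept (it is frequency signal), while duplicate rows within
one strain are collapsed. Only single-nucleotide substitutions are consumed;
everything else is counted and skipped.
"""
from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .reference import STOP, GeneModel, ReferenceGenome, translate_codon

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_AA = set("ACDEFGHIKLMNPQRSTVWY") | {STOP}
_SUB_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")

# effect classes
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NONSENSE = "nonsense"
STOP_LOSS = "stop-loss"
START_LOSS = "start-loss"
INTERGENIC = "intergenic"

NONSYNONYMOUS = frozenset({MISSENSE, NONSENSE, STOP_LOSS, START_LOSS})


@dataclass(frozen=True)
class VariantRecord:
    """One genomic SNV from one evolved strain."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    strain: str


@dataclass(frozen=True)
class SubstitutionRecord:
    """One amino-acid substitution as uploaded directly (e.g. ``recA A123V``)."""

    gene: str
    ref_aa: str
    pos: int  # 1-based residue index
    alt_aa: str
    strain: str

    @property
    def sub(self) -> str:
        return f"{self.ref_aa}{self.pos}{self.alt_aa}"


@dataclass(frozen=True)
class ProteinEffect:
    """Annotated consequence of one SNV (or substitution) in one gene."""

    gene: str  # locus_tag; "" for intergenic
    codon_index: int  # 1-based; 0 for intergenic
    ref_aa: str
    alt_aa: str
    effect: str
    strain: str
    ea: float | None = None
    contig: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""

    @property
    def substitution(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass
class IngestReport:
    """accepted + skipped(by reason) = total data lines, per input file."""

    total: int = 0
    accepted: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str, detail: str = "") -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1
        if detail:
            logger.info("skipped (%s): %s", reason, detail)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES


def read_vcf(path: str | Path, strain: str, *, pass_only: bool = True,
             split_multiallelic: bool = False,
             report: IngestReport | None = None) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF 4.x file (plain or bgzipped).

    Indels, MNVs, symbolic alleles and (unless ``split_multiallelic``)
    multi-allelic rows are skipped and counted. Rows whose FILTER is neither
    PASS nor '.' are skipped by default.
    """
    report = report if report is not None else IngestReport()
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            report.total += 1
            filters = list(rec.filter.keys())
            if pass_only and filters and filters != ["PASS"]:
                report.skip("non_pass_filter", f"{rec.chrom}:{rec.pos}")
                continue
            alts = rec.alts or ()
            if not alts:
                report.skip("no_alt_allele", f"{rec.chrom}:{rec.pos}")
                continue
            if len(alts) > 1:
                if split_multiallelic and all(_is_snv(rec.ref, a) for a in alts):
                    for a in alts:
                        out.append(VariantRecord(rec.chrom, rec.pos, rec.ref,
                                                 a, strain))
                    report.accepted += 1
                else:
                    report.skip("multiallelic", f"{rec.chrom}:{rec.pos}")
                continue
            if not _is_snv(rec.ref, alts[0]):
                report.skip("not_snv", f"{rec.chrom}:{rec.pos}")
                continue
            out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alts[0],
                                     strain))
            report.accepted += 1
    return out


def _open_text(path: str | Path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def read_gd(path: str | Path, strain: str, genome: ReferenceGenome, *,
            report: IngestReport | None = None) -> list[VariantRecord]:
    """Read SNP mutation entries from a breseq GenomeDiff file.

    GD SNP lines carry (type, id, parent-ids, seq-id, position, new base); the
    reference base comes from the genome. All other mutation and evidence
    entry types (INS, DEL, MOB, AMP, CON, SUB, RA, MC, JC, UN, ...) are
    skipped and counted.
    """
    report = report if report is not None else IngestReport()
    out: list[VariantRecord] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.total += 1
            fields = line.split("\t")
            if fields[0] != "SNP":
                report.skip(f"entry_type_{fields[0]}")
                continue
            if len(fields) < 6:
                report.skip("malformed_snp_line", line)
                continue
            contig, pos_s, new = fields[3], fields[4], fields[5].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                report.skip("malformed_snp_line", line)
                continue
            if contig not in genome.contigs:
                report.skip("unknown_contig", contig)
                continue
            if not (1 <= pos <= len(genome.contigs[contig])):
                report.skip("position_out_of_range", f"{contig}:{pos}")
                continue
            if new not in _BASES:
                report.skip("ambiguous_new_base", new)
                continue
            ref = genome.base_at(contig, pos)
            if ref == new:
                report.skip("new_base_equals_reference", f"{contig}:{pos}")
                continue
            out.append(VariantRecord(contig, pos, ref, new, strain))
            report.accepted += 1
    return out


def read_substitutions(path: str | Path, *, default_strain: str = "sample",
                       report: IngestReport | None = None
                       ) -> list[SubstitutionRecord]:
    """Read a tab-delimited amino-acid substitution list.

    Columns: gene, substitution (refAA+position+altAA, ``*`` = stop), optional
    strain. Lines starting with '#' are comments; malformed lines are rejected
    with their line number in the report.
    """
    report = report if report is not None else IngestReport()
    out: list[SubstitutionRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.total += 1
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                report.skip("wrong_column_count", f"line {lineno}")
                continue
            gene, sub = fields[0].strip(), fields[1].strip()
            strain = fields[2].strip() if len(fields) == 3 else default_strain
            m = _SUB_RE.match(sub)
            if not m or m.group(1) not in _AA or m.group(3) not in _AA \
                    or int(m.group(2)) < 1:
                report.skip("malformed_substitution", f"line {lineno}: {sub!r}")
                continue
            out.append(SubstitutionRecord(gene, m.group(1), int(m.group(2)),
                                          m.group(3), strain))
            report.accepted += 1
    return out


def dedupe(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Collapse duplicate identical rows within one strain, keeping order."""
    seen: set[VariantRecord] = set()
    out = []
    for v in variants:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def classify(codon_index: int, ref_aa: str, alt_aa: str) -> str:
    """Effect class from the literal reading-frame translation."""
    if ref_aa == alt_aa:
        return SYNONYMOUS
    if alt_aa == STOP:
        return NONSENSE
    if ref_aa == STOP:
        return STOP_LOSS
    if codon_index == 1:
        return START_LOSS
    return MISSENSE


def _effect_for_gene(genome: ReferenceGenome, gene: GeneModel,
                     v: VariantRecord, ea_table) -> ProteinEffect:
    ci, offset, codon = genome.codon_at(gene.locus_tag, v.pos)
    alt_base = v.alt if gene.strand == "+" else _COMP[v.alt]
    alt_codon = codon[:offset] + alt_base + codon[offset + 1:]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    effect = classify(ci, ref_aa, alt_aa)
    ea = None
    if effect == MISSENSE and ea_table is not None:
        ea = ea_table.get(gene.locus_tag, ci, alt_aa)
    return ProteinEffect(gene=gene.locus_tag, codon_index=ci, ref_aa=ref_aa,
                         alt_aa=alt_aa, effect=effect, strain=v.strain, ea=ea,
                         contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt)


def annotate(variants: Iterable[VariantRecord], genome: ReferenceGenome,
             ea_table=None, *, report: IngestReport | None = None
             ) -> list[ProteinEffect]:
    """Map genomic SNVs onto protein substitutions.

    A variant inside one or more CDS yields one effect per containing gene
    (driver statistics are per-gene, so overlapping genes each see it);
    intergenic variants yield a single intergenic effect kept for accounting.
    Variants whose ref base disagrees with the genome, and duplicate rows
    within one strain, are rejected/collapsed with counts.
    """
    report = report if report is not None else IngestReport()
    effects: list[ProteinEffect] = []
    for v in dedupe(variants):
        report.total += 1
        if v.contig not in genome.contigs:
            report.skip("unknown_contig", v.contig)
            continue
        if not (1 <= v.pos <= len(genome.contigs[v.contig])):
            report.skip("position_out_of_range", f"{v.contig}:{v.pos}")
            continue
        if v.ref == v.alt or v.ref not in _BASES or v.alt not in _BASES:
            report.skip("invalid_alleles", f"{v.contig}:{v.pos}")
            continue
        if genome.base_at(v.contig, v.pos) != v.ref:
            report.skip("ref_mismatch", f"{v.contig}:{v.pos}")
            continue
        genes = genome.genes_at(v.contig, v.pos)
        if not genes:
            effects.append(ProteinEffect(gene="", codon_index=0, ref_aa="",
                                         alt_aa="", effect=INTERGENIC,
                                         strain=v.strain, contig=v.contig,
                                         pos=v.pos, ref=v.ref, alt=v.alt))
            report.accepted += 1
            continue
        for gene in genes:
            effects.append(_effect_for_gene(genome, gene, v, ea_table))
        report.accepted += 1
    return effects


def effects_from_substitutions(subs: Iterable[SubstitutionRecord],
                               genome: ReferenceGenome, ea_table=None, *,
                               report: IngestReport | None = None
                               ) -> list[ProteinEffect]:
    """Build protein effects directly from an amino-acid substitution list.

    Genes resolve by locus tag first, then by unique gene name (ambiguous
    names raise). The reference residue is validated against the gene's
    protein sequence (position ``protein_length + 1`` addresses the stop
    codon); mismatches are rejected with a count.
    """
    report = report if report is not None else IngestReport()
    effects: list[ProteinEffect] = []
    seen: set[tuple[str, str, str]] = set()
    for s in subs:
        report.total += 1
        gene = genome.resolve_gene(s.gene)  # raises on unknown/ambiguous
        if s.pos <= gene.protein_length:
            expected = gene.protein_seq[s.pos - 1]
        elif s.pos == gene.protein_length + 1:
            expected = STOP
        else:
            report.skip("position_beyond_protein", f"{s.gene} {s.sub}")
            continue
        if s.ref_aa != expected:
            report.skip("ref_residue_mismatch",
                        f"{s.gene} {s.sub} (reference has {expected})")
            continue
        key = (s.strain, gene.locus_tag, s.sub)
        if key in seen:
            continue
        seen.add(key)
        effect = classify(s.pos, s.ref_aa, s.alt_aa)
        ea = None
        if effect == MISSENSE and ea_table is not None:
            ea = ea_table.get(gene.locus_tag, s.pos, s.alt_aa)
        effects.append(ProteinEffect(gene=gene.locus_tag, codon_index=s.pos,
                                     ref_aa=s.ref_aa, alt_aa=s.alt_aa,
                                     effect=effect, strain=s.strain, ea=ea))
        report.accepted += 1
    return effects
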