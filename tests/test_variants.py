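"""Variant parsing (VCF/GD/substitutions) and protein-effect annotation."""
import dataclasses

import pytest

import aledriver as ad
from aledriver.reference import reverse_complement, GeneModel, ReferenceGenome
from aledriver.variants import (MISSENSE, NONSENSE, START_LOSS, STOP_LOSS,
                                SYNONYMOUS, INTERGENIC, IngestReport,
                                VariantRecord)


def _write_vcf(path, rows):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=toy,length=49>\n")
        fh.write('##FILTER=<ID=lowqual,Description="low quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


class TestReadVcf:
    def test_snv_rows_map_directly(self, tmp_path):
        path = tmp_path / "a.vcf"
        _write_vcf(path, [("toy", 14, ".", "C", "A", ".", "PASS", ".")])
        rep = IngestReport()
        out = ad.read_vcf(path, "s1", report=rep)
        assert out == [VariantRecord("toy", 14, "C", "A", "s1")]
        assert rep.accepted == rep.total == 1

    def test_indels_filtered_and_counted(self, tmp_path):
        path = tmp_path / "b.vcf"
        _write_vcf(path, [
            ("toy", 10, ".", "AT", "A", ".", "PASS", "."),
            ("toy", 14, ".", "C", "A", ".", "lowqual", "."),
            ("toy", 15, ".", "T", "C", ".", ".", "."),
        ])
        rep = IngestReport()
        out = ad.read_vcf(path, "s1", report=rep)
        assert [v.pos for v in out] == [15]
        assert rep.skipped == {"not_snv": 1, "non_pass_filter": 1}
        assert rep.accepted + rep.n_skipped == rep.total == 3

    def test_multiallelic_split_flag(self, tmp_path):
        path = tmp_path / "c.vcf"
        _write_vcf(path, [("toy", 14, ".", "C", "A,G", ".", "PASS", ".")])
        assert ad.read_vcf(path, "s1") == []
        out = ad.read_vcf(path, "s1", split_multiallelic=True)
        assert sorted(v.alt for v in out) == ["A", "G"]

    def test_keep_filtered_flag(self, tmp_path):
        path = tmp_path / "d.vcf"
        _write_vcf(path, [("toy", 14, ".", "C", "A", ".", "lowqual", ".")])
        assert len(ad.read_vcf(path, "s1", pass_only=False)) == 1


class TestReadGd:
    def test_snp_entries_take_ref_from_genome(self, tmp_path, toy_genome):
        path = tmp_path / "a.gd"
        path.write_text("#=GENOME_DIFF\t1.0\n"
                        "SNP\t1\t23\ttoy\t14\tA\n"
                        "DEL\t2\t24\ttoy\t20\t1\n"
                        "RA\t3\t.\ttoy\t14\t0\tC\tA\n")
        rep = IngestReport()
        out = ad.read_gd(path, "s1", toy_genome, report=rep)
        assert out == [VariantRecord("toy", 14, "C", "A", "s1")]
        assert rep.skipped == {"entry_type_DEL": 1, "entry_type_RA": 1}

    def test_out_of_range_position_rejected(self, tmp_path, toy_genome):
        path = tmp_path / "b.gd"
        path.write_text("SNP\t1\t.\ttoy\t99999\tA\n")
        rep = IngestReport()
        assert ad.read_gd(path, "s1", toy_genome, report=rep) == []
        assert rep.skipped == {"position_out_of_range": 1}


class TestReadSubstitutions:
    def test_parse_and_stop_notation(self, tmp_path):
        path = tmp_path / "subs.tsv"
        path.write_text("# comment\n"
                        "recA\tA123V\ts1\n"
                        "ftsZ\tQ47*\n"
                        "geneX\t123AV\ts1\n")
        rep = IngestReport()
        out = ad.read_substitutions(path, report=rep)
        assert [(s.gene, s.sub) for s in out] == [("recA", "A123V"),
                                                  ("ftsZ", "Q47*")]
        assert out[1].alt_aa == "*"
        assert rep.skipped == {"malformed_substitution": 1}
        assert rep.accepted + rep.n_skipped == rep.total == 3


class TestAnnotate:
    """gf1 (+, 10-24) codons: ATG(10-12) GCT(13-15) CAA(16-18) GGT(19-21) TAA."""

    def _one(self, genome, pos, ref, alt, **kw):
        return ad.annotate([VariantRecord("toy", pos, ref, alt, "s1")],
                           genome, **kw)

    def test_missense(self, toy_genome):
        (e,) = self._one(toy_genome, 14, "C", "A")  # GCT -> GAT
        assert (e.effect, e.substitution) == (MISSENSE, "A2D")

    def test_nonsense(self, toy_genome):
        (e,) = self._one(toy_genome, 16, "C", "T")  # CAA -> TAA
        assert (e.effect, e.ref_aa, e.alt_aa) == (NONSENSE, "Q", "*")

    def test_synonymous_third_position(self, toy_genome):
        (e,) = self._one(toy_genome, 15, "T", "C")  # GCT -> GCC
        assert e.effect == SYNONYMOUS

    def test_start_loss(self, toy_genome):
        (e,) = self._one(toy_genome, 10, "A", "G")  # ATG -> GTG
        assert (e.effect, e.codon_index) == (START_LOSS, 1)

    def test_stop_loss(self, toy_genome):
        (e,) = self._one(toy_genome, 22, "T", "C")  # TAA -> CAA
        assert (e.effect, e.ref_aa) == (STOP_LOSS, "*")

    def test_minus_strand_alt_is_complemented(self, toy_genome):
        # gr1 codon 2 = TTT (genomic 40-42 reverse complement AAA)
        (e,) = self._one(toy_genome, 41, "A", "G")
        assert e.gene == "gr1"
        assert (e.codon_index, e.ref_aa) == (2, "F")
        assert e.effect == MISSENSE

    def test_intergenic_kept_for_accounting(self, toy_genome):
        (e,) = self._one(toy_genome, 5, "A", "C")
        assert e.effect == INTERGENIC and e.gene == ""

    def test_ref_mismatch_rejected_with_count(self, toy_genome):
        rep = IngestReport()
        out = self._one(toy_genome, 14, "G", "A", report=rep)
        assert out == [] and rep.skipped == {"ref_mismatch": 1}

    def test_duplicates_within_strain_collapse(self, toy_genome):
        v = VariantRecord("toy", 14, "C", "A", "s1")
        assert len(ad.annotate([v, v], toy_genome)) == 1
        v2 = dataclasses.replace(v, strain="s2")
        assert len(ad.annotate([v, v2], toy_genome)) == 2


def test_strand_symmetry_under_reverse_complement(toy_genome):
    """Mirroring genome and variant leaves the protein effect unchanged."""
    seq = toy_genome.contigs["toy"]
    length = len(seq)
    mirrored = ReferenceGenome(
        {"toy": reverse_complement(seq)},
        [GeneModel(g.locus_tag, g.gene_name, "toy",
                   length - g.end + 1, length - g.start + 1,
                   "-" if g.strand == "+" else "+", g.protein_seq)
         for g in toy_genome.genes])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for gene in toy_genome.genes:
        for pos in range(gene.start, gene.end + 1):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                (e1,) = ad.annotate(
                    [VariantRecord("toy", pos, ref, alt, "s")], toy_genome)
                (e2,) = ad.annotate(
                    [VariantRecord("toy", length - pos + 1, comp[ref],
                                   comp[alt], "s")], mirrored)
                assert (e1.gene, e1.codon_index, e1.ref_aa, e1.alt_aa,
                        e1.effect) == (e2.gene, e2.codon_index, e2.ref_aa,
                                       e2.alt_aa, e2.effect)


def test_substitution_route_matches_genomic_route(small_bundle):
    """The same mutations via substitution list give the same effect keys."""
    fx = small_bundle["fixture"]
    genome, table = small_bundle["genome"], small_bundle["table"]
    subs = ad.read_substitutions(fx.substitutions_path)
    via_subs = ad.effects_from_substitutions(subs, genome, table)
    key = lambda e: (e.strain, e.gene, e.codon_index, e.ref_aa, e.alt_aa,
                     e.effect, e.ea)
    via_vcf = []
    for strain, path in fx.vcf_paths.items():
        via_vcf += ad.annotate(ad.read_vcf(path, strain), genome, table)
    assert sorted(map(key, via_subs)) == sorted(map(key, via_vcf))


def test_substitution_ref_residue_validated(toy_genome):
    rep = IngestReport()
    out = ad.effects_from_substitutions(
        [ad.SubstitutionRecord("gf1", "W", 2, "V", "s1")], toy_genome,
        report=rep)
    assert out == [] and rep.skipped == {"ref_residue_mismatch": 1}


def test_ambiguous_gene_name_is_error():
    cds = "ATGGCTTAA"
    seq = cds + "T" + cds
    genes = [GeneModel("t1", "dup", "c", 1, 9, "+", "MA"),
             GeneModel("t2", "dup", "c", 11, 19, "+", "MA")]
    genome = ReferenceGenome({"c": seq}, genes)
    with pytest.raises(KeyError, match="ambiguous"):
        ad.effects_from_substitutions(
            [ad.SubstitutionRecord("dup", "A", 2, "V", "s")], genome)
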