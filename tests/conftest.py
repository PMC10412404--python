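import numpy as np
import pytest

import aledriver as ad
from aledriver.reference import GeneModel, ReferenceGenome, translate_codon


def _protein(cds: str) -> str:
    return "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds) - 3, 3))


@pytest.fixture(scope="session")
def toy_genome() -> ReferenceGenome:
    """Hand-indexed two-gene genome for exact coordinate assertions.

    Layout (1-based):
      1-9    intergenic ACGTACGTA
      10-24  gf1, + strand: ATG GCT CAA GGT TAA  (M A Q G *)
      25-30  intergenic TTTTTT
      31-45  gr1, - strand: CDS = ATG TTT GAT TAA + one sense codon
    """
    fwd_cds = "ATGGCTCAAGGTTAA"
    rev_cds = "ATGTTTGATCCGTAA"  # M F D P *
    rc = rev_cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seq = "ACGTACGTA" + fwd_cds + "TTTTTT" + rc + "GGGG"
    genes = [
        GeneModel("gf1", "alpha", "toy", 10, 24, "+", _protein(fwd_cds)),
        GeneModel("gr1", "beta", "toy", 31, 45, "-", _protein(rev_cds)),
    ]
    return ReferenceGenome({"toy": seq}, genes)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A 12-gene synthetic experiment with one high-EA driver, on disk."""
    spec = ad.FixtureSpec(
        n_genes=12, gene_length_range=(150, 450), n_strains=3,
        neutral_per_strain=8,
        drivers=[ad.DriverSpec("ALE_0005", 6, 1.0)], seed=11)
    return ad.make_fixture(spec, tmp_path_factory.mktemp("fx"))


@pytest.fixture(scope="session")
def small_bundle(small_fixture):
    """Reloaded-from-disk genome/EA plus exhaustive background and catalog."""
    genome = ad.load_genbank(small_fixture.genbank)
    table, rejected = ad.load_ea_table(small_fixture.ea_path, genome)
    assert not rejected
    catalog = ad.enumerate_coding_snvs(genome, table)
    bg = ad.enumerate_background(genome, table, snv_catalog=catalog)
    return {"genome": genome, "table": table, "catalog": catalog, "bg": bg,
            "fixture": small_fixture}


@pytest.fixture(scope="session")
def study_bundle():
    """The 50-gene study-scale genome used by the statistical checks.

    Built in memory once per session: genome (~30 kb coding), full synthetic
    EA table, coding-SNV catalog and exhaustive background.
    """
    spec = ad.FixtureSpec(seed=101)
    root = np.random.SeedSequence(spec.seed)
    rng_genome, _ = (np.random.default_rng(s) for s in root.spawn(2))
    genome = ad.build_genome(spec, rng_genome)
    table = ad.synth_ea_table(genome, spec.seed)
    catalog = ad.enumerate_coding_snvs(genome, table)
    bg = ad.enumerate_background(genome, table, snv_catalog=catalog)
    return {"spec": spec, "genome": genome, "table": table,
            "catalog": catalog, "bg": bg}
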