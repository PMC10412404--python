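"""Project mutational burden onto a protein structure for PyMOL viewing.

Builds the per-residue sumEA and unique-mutation-count tracks of one gene
from annotated effects, writes them into the B-factor column of a (synthetic)
single-chain PDB, and emits the PyMOL command script that applies the
blue-white-red spectrum. Residues without data get B = -1.00 and are grey.
"""
import tempfile
from pathlib import Path

import numpy as np

import aledriver as ad

spec = ad.FixtureSpec(n_genes=10, n_strains=4, neutral_per_strain=10,
                      drivers=[ad.DriverSpec("ALE_0003", 8, 1.0)], seed=4)

with tempfile.TemporaryDirectory() as tmp:
    fx = ad.make_fixture(spec, tmp)
    genome = ad.load_genbank(fx.genbank)
    table, _ = ad.load_ea_table(fx.ea_path, genome)
    effects = []
    for strain, path in fx.vcf_paths.items():
        effects += ad.annotate(ad.read_vcf(path, strain), genome, table)

gene = genome.gene("ALE_0003")
sum_track, uniq_track = ad.residue_tracks_from_effects(effects, gene)

workdir = Path(tempfile.mkdtemp())
pdb = workdir / "model.pdb"
ad.write_synthetic_pdb(gene.protein_length, pdb)
ad.write_colored_pdb(pdb, sum_track, workdir / "colored.pdb",
                     workdir / "coloring.pml")

hit = np.flatnonzero(sum_track.values) + 1
print(f"{gene.locus_tag}: {gene.protein_length} residues, "
      f"{int(uniq_track.values.sum())} distinct substitutions at "
      f"{hit.size} residues")
print(f"mutated residues (1-based): {hit.tolist()}")
print(f"sumEA at those residues: "
      f"{np.round(sum_track.values[hit - 1], 1).tolist()}")
print(f"\nPyMOL script ({workdir / 'coloring.pml'}):")
print((workdir / "coloring.pml").read_text())
print("Open the .pml in PyMOL to see high-burden residues in red; "
      "the same values sit in the PDB B-factor column.")
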