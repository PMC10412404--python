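"""Quick EA search: the score of one substitution, straight from the table.

EA (Evolutionary Action) scores the expected functional impact of a missense
substitution on a 0-100 scale; the lookup distinguishes a genuinely missing
score from a query whose reference residue contradicts the protein sequence.
"""
import tempfile

import aledriver as ad

with tempfile.TemporaryDirectory() as tmp:
    fx = ad.make_fixture(ad.FixtureSpec(n_genes=5, seed=2), tmp)
    genome = ad.load_genbank(fx.genbank)
    table, _ = ad.load_ea_table(fx.ea_path, genome)

gene = "ALE_0001"
(pos, alt), _ = sorted(table.scores[gene].items())[0]
ref = genome.gene(gene).protein_seq[pos - 1]

print(f"known substitution   {gene} {ref}{pos}{alt} ->",
      f"{ad.lookup_ea(table, genome, gene, f'{ref}{pos}{alt}'):.2f}")

unseen_alt = next(a for a in "WYH" if a not in (ref, alt)
                  and table.get(gene, pos, a) is None)
print(f"absent substitution  {gene} {ref}{pos}{unseen_alt} ->",
      ad.lookup_ea(table, genome, gene, f"{ref}{pos}{unseen_alt}"),
      "(a sentinel, never 0)")

wrong_ref = "W" if ref != "W" else "Y"
print(f"wrong reference      {gene} {wrong_ref}{pos}{alt} ->",
      ad.lookup_ea(table, genome, gene, f"{wrong_ref}{pos}{alt}"))

print(f"stop-gain, EA=100 policy  {gene} {ref}{pos}* ->",
      ad.lookup_ea(table, genome, gene, f"{ref}{pos}*",
                   stop_gain_score=100.0))
print("\nEA is defined for missense only; nonsense substitutions return the "
      "configured stop-gain score (here 100: maximally disruptive).")
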