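# aledriver

Driver-gene detection for adaptive laboratory evolution (ALE) experiments in
bacteria, based on Evolutionary Action (EA) mutation-impact scores.

## The problem

In any bacterial population evolved under selective pressure — serial passage
under antibiotic, heat, a new carbon source — the sequenced clones carry a mix
of mutations: a few in genes that *drive* the adapted phenotype, and many
neutral passengers. The classical way to find drivers is mutational frequency:
rank genes by mutation count relative to gene length. That ignores what the
mutations *do*. A gene hit five times by near-neutral substitutions is less
interesting than a gene hit three times at functionally critical residues.

`aledriver` supplements frequency with the **Evolutionary Action (EA)** score,
a 0–100 measure of the predicted functional impact of a missense substitution
(higher = more disruptive), consumed here as a precomputed per-protein table.
Each gene's observed mutation-impact profile is compared against a **mutation
background** — by default the exhaustive set of all possible coding SNVs of
the reference genome — with three one-sided gene-level statistics:

- **EA_KS** — the one-sided two-sample Kolmogorov–Smirnov statistic
  D⁺ = supₓ [F_bg(x) − F_obs(x)] between the background EA distribution and
  the gene's observed missense EA distribution; large D⁺ means the gene's
  mutations are shifted toward high impact. p = exp(−2 D⁺² mn/(m+n)).
- **EA_sum** — the gene's total observed EA, tested against a Monte-Carlo
  null of equally many draws from the background pool;
  p = (1 + #{null sums ≥ observed}) / (1 + n_mc).
- **frequency** — the burden baseline: upper-tail exact binomial
  p = P(X ≥ n_g), X ~ Binomial(N_total, L_g / L_coding_total).

p-values are Benjamini–Hochberg corrected per method; genes ranked highly by
several methods (Venn consensus) are the strongest candidates. Per-residue
mutational burden (sumEA, distinct-substitution counts) and ET/pLDDT tracks
can be projected onto protein structures for PyMOL inspection.

## Inputs

- annotated reference genome: GenBank flat file (or GFF3 + FASTA);
- evolved-strain variants: VCF, breseq GenomeDiff (GD), or a tab-delimited
  amino-acid-substitution list (`gene<TAB>A123V[<TAB>strain]`);
- EA score table: `locus_tag<TAB>position<TAB>refAA<TAB>altAA<TAB>EA`;
  optional per-residue ET / pLDDT tracks;
- optional custom mutation background (any of the three variant formats);
- optional single-chain PDB per protein for structure coloring.

A deterministic fixture generator (`make_fixture`) emulates all of these, so
the whole pipeline runs and is tested without any downloads.

## Worked example

`python examples/01_end_to_end_driver_ranking.py` builds a 50-gene synthetic
genome, seeds three driver genes with 10 extra top-EA-quartile mutations each
plus one decoy gene with 10 extra *bottom*-quartile mutations, pools variants
from 5 strains (20 neutral mutations each), and ranks:

```
Top 6 genes by EA_sum:
locus_tag  n_mut   sum_ea  ks_stat     q_ks    q_sum       q_freq  rank_ks  rank_sum  rank_freq
 ALE_0007     14 926.5574 0.603035 0.001036 0.001850 6.194249e-05        3         1          2
 ALE_0033     10 759.3812 0.749843 0.000519 0.001850 5.771907e-03        1         2          4
 ALE_0019     13 916.3881 0.614977 0.001036 0.004933 6.571886e-07        2         3          1

The decoy gene (many low-impact mutations):
 ALE_0044     10 161.7049 0.010417 0.998882    1.0 0.002941       35        37          3
```

The three seeded drivers occupy EA_sum ranks 1–3 (and EA_KS ranks 1–3) with
q < 0.005. The decoy — just as many extra mutations, but low-impact — is rank
3 by frequency yet rank 37 by EA_sum: impact-weighting, not raw count, is
what separates drivers from mutational noise. Other examples cover the quick
EA lookup, the Venn consensus + STRING query export, and structure coloring.

The same pipeline is scriptable from the shell:

```bash
aledriver --seed 7 fixture --out fx --driver ALE_0007:10:1.0
aledriver annotate --genbank fx/genome.gb --ea fx/ea_table.tsv \
    --vcf fx/s1.vcf --vcf fx/s2.vcf --out effects.tsv
aledriver --seed 7 rank --genbank fx/genome.gb --ea fx/ea_table.tsv \
    --effects effects.tsv --background-mode exhaustive --out results.tsv
aledriver venn --results results.tsv --top 20 --out overlap.json
```

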