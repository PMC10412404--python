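# Methods

## Model and procedure

`aledriver` asks, gene by gene, whether the mutations observed in evolved
bacterial strains look like random mutagenesis of the reference genome or
like selection for functional change. The unit of analysis is the CDS
(locus tag); the observed data are pooled single-nucleotide variants from
all replicate strains, annotated to protein substitutions on the coding
strand with the bacterial genetic code (translation table 11). Missense
substitutions carry an Evolutionary Action (EA) score in [0, 100]
(higher = more disruptive), read from a user-supplied table — EA is consumed,
never computed here.

### Mutation background

The null model is a mutation background: the EA spectrum that random SNVs in
the same genome would produce.

- **Exhaustive (default).** Every coding position × 3 alternate bases is
  annotated, once per containing gene, giving exactly
  3 × Σ cds_length SNV–gene pairs. Each gene's background pool is the
  multiset of EA values of its reachable, scored missense changes. This is
  the deterministic, exact n→∞ limit of random mutation simulation and is
  cheap at bacterial scale (~14M SNVs for an *E. coli*-sized genome; ~90k
  for the test genomes here).
- **Sampled.** n SNVs drawn uniformly over (genomic position × 3 alternates)
  with replacement, annotated identically; kept for API parity and very
  large genomes. Default n = 100,000 (arbitrary; the exhaustive mode is
  preferred). Uniform spectrum — no transition/transversion bias.
- **Custom.** A user mutation file (VCF/GD/substitutions) parsed exactly
  like observed data. An empty usable background is a hard error.

Background scope is **per-gene** by default: each gene's observed EA
distribution is compared with its own possible-mutation spectrum, which
controls for gene-specific codon composition. A genome-wide pooled scope is
available (`background_scope="genome_wide"`).

### Gene-level tests (all one-sided)

Drivers are defined as accumulating *more* impactful mutations, so high-EA
shifts and high counts are the only alternatives of interest.

- **EA_KS.** D⁺ = supₓ [F_bg(x) − F_obs(x)], computed over all pooled data
  points (the sup of a difference of right-continuous step functions is
  attained there). p = exp(−2 D⁺² mn/(m+n)), the asymptotic one-sided
  formula, floored at machine precision. At the small per-gene counts
  typical of ALE data this formula is an upper bound on the exact p
  (conservative, never anti-conservative) — confirmed empirically by the
  null-calibration test, where its rejection rate at α = 0.05 is ≈ 0.012.
- **EA_sum.** sumEA = Σ observed EA; the null resamples n_mc pseudo-genes of
  the same mutation count from the background pool (with replacement) and
  uses the add-one empirical p = (1 + #{null ≥ obs})/(1 + n_mc), which
  cannot be 0 and is exact-conservative under exchangeability. Conditioning
  on the observed count deliberately separates impact signal from frequency
  signal, keeping EA_sum complementary to the frequency method (this is
  what makes the decoy-gene separation possible). An unconditional variant
  (count redrawn ~ Binomial(N, L_g/L_tot) first) is flag-switchable.
- **Frequency.** Exact binomial upper tail, X ~ Binomial(N_total,
  cds_length / coding_length_total), p = P(X ≥ n_gene). The count policy
  defaults to nonsynonymous (missense, nonsense, start-loss, stop-loss);
  synonymous counting is a flag.

Benjamini–Hochberg correction runs per method over the genes that method
actually tested (EA tests: ≥ min_mut scored missense and a non-empty pool;
frequency: ≥ min_mut mutations); untested genes get p = 1, q = NaN, and
still receive a rank. Ranks order by ascending p, ties broken by descending
sumEA (EA methods) or descending count (frequency), then locus tag —
deterministic by construction.

### Consensus and structure projection

The three top-N lists (default N = 20) are partitioned into the 7 disjoint
Venn regions; the consensus set is genes in ≥ 2 lists. The STRING
protein–protein-interaction enrichment call is deliberately not made
(network dependency, server-version drift); the exact query payload is
exported instead. Per-residue tracks — sumEA, distinct-substitution counts,
plus user-supplied ET and pLDDT — are written into the B-factor column of a
single-chain PDB together with a PyMOL command script (blue-white-red
spectrum over the track range). A command script rather than a binary
session file: diffable, testable, replays to the same visual state.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_mc` | 10,000 | Monte-Carlo replicates of the EA_sum null; p resolution 1/(1+n_mc) |
| `min_mut` | 1 | minimum scored missense for the EA tests |
| `background_scope` | per_gene | which pool the EA nulls draw from |
| `per_strain_recurrence` | True | the same substitution counts once per strain carrying it (recurrence across replicates is frequency signal); False collapses to once overall |
| `stop_gain_score` | None | None: nonsense excluded from EA statistics (EA is defined for missense); e.g. 100.0 includes them as maximally disruptive |
| `count_synonymous` | False | frequency counts are nonsynonymous-only by default |
| top-N for consensus | 20 | length of each method's list entering the Venn overlap |

Effect identity is the amino-acid substitution (gene, position, ref, alt
residue): a change reached by two different nucleotide routes counts once.
Missense without an EA entry stays in frequency counts but is dropped
(reported, never imputed) from EA statistics. Tables whose values all lie in
[0, 1] are auto-rescaled to 0–100 with a warning. Start-codon handling:
proteins store the literal table-11 translation (a GTG start reads V), and
any nonsynonymous change in codon 1 is classified start-loss — this keeps
the genomic and substitution-list routes classifying identically.

Determinism: one top-level seed derives every stream; each gene's
Monte-Carlo null is keyed by (seed, crc32(locus_tag)), so results are
independent of input order and delivery format — the format-equivalence
test requires byte-identical result tables from VCF, GenomeDiff and
substitution-list input.

## Synthetic data

The fixture generator emulates an ALE experiment end to end: a random-codon
genome (valid start/stop, no internal stops, both strands, short intergenic
spacers), an EA table with one Beta(2,2)-distributed score (scaled to 0–100)
per missense substitution reachable by a single nucleotide change, and
per-strain mutation sets — neutral mutations uniform over all coding SNVs,
plus driver genes receiving extra mutations biased toward their top EA
quartile. `ea_bias` ∈ [−1, 1] is the probability of drawing from the top
(positive) or bottom (negative) quartile; bias 1.0 draws exclusively from
the top quartile, and negative bias builds the low-impact/high-count decoy
used to show what frequency ranking alone gets wrong.

Study-scale defaults, used by the statistical tests and the acceptance
script: 50 genes of 300–900 nt (~30 kb coding), 5 strains × 20 neutral
mutations, drivers with 10 extras at bias ±1.0; null calibration uses 1,000
replicates of 100 background-drawn mutations, driver recovery 100
replicates. These sizes give ≥ 36,000 gene-tests for calibration and stable
recovery estimates while the whole suite runs in well under a minute.

What the generator does **not** emulate: mutational spectrum bias
(transition/transversion, context effects, hotspots), indels and structural
variants, linkage between mutations within a clone, shared ancestry among
replicate lineages, and real EA score distributions (which are
protein-specific and often bimodal rather than Beta). Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under a uniform, independent mutation model — not that the method's power on
real ALE data matches the synthetic recovery rates.

## Numerical choices and degenerate inputs

- KS p-values are floored at the smallest positive normal double; empirical
  p-values use the +1/+1 estimator, so no p is ever 0.
- EA pools are sorted arrays; D⁺ is evaluated by `searchsorted` on the
  union of points — ties across and within samples are handled exactly
  (verified against a brute-force double loop to 1e−12).
- Genes with zero scored missense: sumEA = 0, EA p = 1, excluded from EA
  BH; zero-mutation genes get p_freq = 1 (P(X ≥ 0)).
- Sampled-background convergence is assessed on 20-bin EA histograms
  (total variation < 0.05 at n = 10⁵ on a small genome); unbinned empirical
  TV cannot reach that threshold for near-continuous pools at any practical
  n, so the binned comparison is the meaningful one.
- CDS features that are unusable for per-residue scoring (compound joins,
  length not divisible by 3, internal stops, ambiguous bases) are skipped
  with per-reason counts; a genome with zero usable CDS is a hard error.
- B-factors are clamped to [0, 999.99] (PDB fixed format); undefined
  residues are written as −1.00 and colored grey — distinguishable from a
  true 0.

## Design choices where the design was open

- Variants in overlapping genes are annotated once per containing gene
  (driver statistics are per-gene); the same duplication rule is applied to
  the background, keeping numerator and denominator consistent.
- Recurrent identical substitutions count once per strain by default
  (recurrence across independent replicates is evidence), configurable.
- VCF FILTER policy: PASS/'.' only by default, flag to keep all.
- The structure-coloring sumEA pools each distinct substitution once by
  default (matching unique-mutation semantics and the cross-module
  conservation identity with GeneResult sumEA); per-occurrence pooling is a
  flag.

## Known limitations

Single-nucleotide substitutions only (no indel/SV consequences); prokaryotic
gene models only (no splicing, no compound locations); EA/ET tables must be
supplied (no alignment-based computation); the binomial frequency model
assumes a uniform mutation rate per coding nucleotide; multi-chain
structures are not mapped. The one-sided design means genes under selection
for *loss* of high-impact mutations (purifying shifts toward low EA) are
invisible by construction.
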