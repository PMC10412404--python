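"""End-to-end driver ranking on a synthetic lab-evolution experiment.

Generates a 50-gene bacterial genome with three seeded driver genes (extra
mutations drawn from the top EA quartile) and one low-impact decoy gene with
just as many extra mutations, then runs the full pipeline: annotate variants,
build the exhaustive mutation background, and rank genes by EA_KS, EA_sum and
frequency.
"""
import tempfile

import aledriver as ad

DRIVERS = ["ALE_0007", "ALE_0019", "ALE_0033"]
DECOY = "ALE_0044"

spec = ad.FixtureSpec(
    n_genes=50, n_strains=5, neutral_per_strain=20,
    drivers=[ad.DriverSpec(t, 10, 1.0) for t in DRIVERS]
    + [ad.DriverSpec(DECOY, 10, -1.0)],
    seed=7)

with tempfile.TemporaryDirectory() as tmp:
    fx = ad.make_fixture(spec, tmp)
    genome = ad.load_genbank(fx.genbank)
    table, _ = ad.load_ea_table(fx.ea_path, genome)

    effects = []
    for strain, path in fx.vcf_paths.items():
        effects += ad.annotate(ad.read_vcf(path, strain), genome, table)

background = ad.enumerate_background(genome, table)
results = ad.rank_drivers(genome, effects, background,
                          ad.RankingConfig(seed=7))

cols = ["locus_tag", "n_mut", "sum_ea", "ks_stat", "q_ks", "q_sum", "q_freq",
        "rank_ks", "rank_sum", "rank_freq"]
print("Top 6 genes by EA_sum:")
print(results.sort_values("rank_sum").head(6)[cols].to_string(index=False))
print()
print("The decoy gene (many low-impact mutations):")
print(results[results.locus_tag == DECOY][cols].to_string(index=False))
print()
print(f"Seeded drivers {DRIVERS} carry extra top-quartile-EA mutations, so "
      "both EA statistics put them at the head of the ranking (small q, "
      "rank <= 3).")
print(f"The decoy {DECOY} has just as many extra mutations but low EA: "
      "frequency ranks it as a top driver, while EA_sum does not — "
      "impact-weighting is what separates drivers from mutation counts.")
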