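"""Per-gene driver statistics: EA_KS, EA_sum and the frequency baseline.

The premise: genes driving adaptation accumulate mutations that are both more
frequent and more functionally impactful than random mutagenesis predicts.
Three one-sided gene-level tests operationalize this against a mutation
background (see :mod:`aledriver.background`):

* **EA_KS** — one-sided two-sample Kolmogorov-Smirnov statistic
  ``D+ = sup_x [F_bg(x) - F_obs(x)]`` between the background EA distribution
  and the gene's observed missense EA distribution; D+ > 0 means the observed
  EAs sit above the background (more impactful). p from the asymptotic
  one-sided formula ``exp(-2 D+^2 mn/(m+n))``, a conservative bound at small
  samples.
* **EA_sum** — the gene's total observed EA versus a Monte-Carlo null of
  equally many draws (with replacement) from the background pool, with the
  add-one empirical p ``(1 + #{null sums >= obs}) / (1 + n_mc)``.
  Conditioning on the observed count separates impact signal from frequency
  signal; an unconditional mode (count drawn binomially first) is available.
* **frequency** — the classical burden baseline: upper-tail exact binomial
  p for the gene's mutation count given opportunity
  ``cds_length / coding_length_total``.

p-values are Benjamini-Hochberg adjusted per method; genes are ranked by
ascending p with deterministic tie-breaking. All randomness derives from one
seed; each gene's Monte-Carlo stream is keyed by its locus tag so results do
not depend on input order or delivery format.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .background import BackgroundSet
from .reference import ReferenceGenome
from .variants import (INTERGENIC, MISSENSE, NONSENSE, NONSYNONYMOUS,
                       SYNONYMOUS, ProteinEffect)

_P_FLOOR = float(np.finfo(float).tiny)

METHODS = ("ks", "sum", "freq")


@dataclass
class RankingConfig:
    """Knobs for the gene-ranking pipeline.

    n_mc
        Monte-Carlo replicates for the EA_sum null (>= 100).
    min_mut
        minimum scored missense per gene for the EA tests; genes below it
        get p = 1 and are excluded from BH correction.
    background_scope
        'per_gene' (each gene's own background EA spectrum, default) or
        'genome_wide'.
    count_synonymous
        include synonymous changes in frequency counts (default: counts are
        nonsynonymous only).
    per_strain_recurrence
        count the same substitution once per strain carrying it (default) or
        once overall.
    stop_gain_score
        include nonsense mutations in EA statistics at this score (e.g. 100);
        None (default) excludes them from EA statistics entirely.
    conditional_sum_null
        resample EA_sum nulls at the observed per-gene count (default); if
        False, the null also redraws the count ~ Binomial(N, L_g/L_tot).
    """

    n_mc: int = 10_000
    min_mut: int = 1
    seed: int = 0
    background_scope: str = "per_gene"
    count_synonymous: bool = False
    per_strain_recurrence: bool = True
    stop_gain_score: float | None = None
    conditional_sum_null: bool = True

    def __post_init__(self):
        if self.n_mc < 100:
            raise ValueError("n_mc must be >= 100")
        if self.min_mut < 1:
            raise ValueError("min_mut must be >= 1")
        if self.background_scope not in ("per_gene", "genome_wide"):
            raise ValueError(f"unknown scope {self.background_scope!r}")


def gene_rng(seed: int, locus_tag: str) -> np.random.Generator:
    """Deterministic per-gene RNG independent of gene processing order."""
    key = zlib.crc32(locus_tag.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def ea_ks(obs: np.ndarray, bg: np.ndarray) -> tuple[float, float]:
    """One-sided two-sample KS test for observed EAs shifted to HIGH values.

    ``D+ = sup_x [F_bg(x) - F_obs(x)]`` evaluated over all pooled data points
    (the sup of a difference of right-continuous step functions is attained
    there). p = exp(-2 D+^2 mn/(m+n)), floored at machine precision.
    """
    obs = np.asarray(obs, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if obs.size == 0 or bg.size == 0:
        raise ValueError("ea_ks requires non-empty observed and background")
    pts = np.unique(np.concatenate([obs, bg]))
    f_bg = np.searchsorted(np.sort(bg), pts, side="right") / bg.size
    f_obs = np.searchsorted(np.sort(obs), pts, side="right") / obs.size
    d_plus = float(max(0.0, np.max(f_bg - f_obs)))
    m, n = bg.size, obs.size
    p = float(np.exp(-2.0 * d_plus ** 2 * m * n / (m + n)))
    return d_plus, min(1.0, max(p, _P_FLOOR))


def ea_sum_test(obs: np.ndarray, bg: np.ndarray, n_mc: int,
                rng: np.random.Generator) -> tuple[float, float]:
    """EA_sum: observed total EA versus a Monte-Carlo resampling null.

    Draws ``n_mc`` pseudo-genes of the same mutation count from the
    background pool (with replacement), sums each, and reports the add-one
    empirical upper-tail p — never exactly 0, conservative by construction.
    """
    obs = np.asarray(obs, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if obs.size == 0:
        raise ValueError("ea_sum_test requires at least one observed EA")
    if bg.size == 0:
        raise ValueError("ea_sum_test requires a non-empty background pool")
    sum_ea = float(obs.sum())
    idx = rng.integers(0, bg.size, size=(n_mc, obs.size))
    null_sums = bg[idx].sum(axis=1)
    p = (1.0 + np.count_nonzero(null_sums >= sum_ea)) / (1.0 + n_mc)
    return sum_ea, float(p)


def frequency_test(n_mut_gene: int, cds_length_gene: int, n_total_mut: int,
                   coding_length_total: int) -> float:
    """Upper-tail exact binomial p for a gene's mutation count.

    X ~ Binomial(N_total, L_gene / L_coding_total); p = P(X >= n_gene).
    """
    if n_total_mut < 1:
        raise ValueError("n_total_mut must be >= 1")
    if n_mut_gene <= 0:
        return 1.0
    rate = cds_length_gene / coding_length_total
    # sf(k-1) = P(X >= k), exact tail sum
    return float(min(1.0, stats.binom.sf(n_mut_gene - 1, n_total_mut, rate)))


def _tie_break(df: pd.DataFrame, p_col: str, tiebreak_col: str) -> pd.Series:
    order = df.sort_values(
        by=[p_col, tiebreak_col, "locus_tag"],
        ascending=[True, False, True], kind="mergesort").index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    return ranks.reindex(df.index)


def rank_genes(results: pd.DataFrame, method: str) -> pd.DataFrame:
    """Attach rank and BH q-value columns for one method, in place.

    Order: ascending p, ties broken by descending sumEA (EA methods) or
    descending mutation count (frequency), then locus tag. BH runs over the
    genes actually tested by the method (``tested_<method>``); untested genes
    carry q = NaN but still receive a rank.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    p_col = f"p_{method}"
    tiebreak = "n_mut" if method == "freq" else "sum_ea"
    results[f"rank_{method}"] = _tie_break(results, p_col, tiebreak)
    tested = results[f"tested_{method}"].to_numpy(dtype=bool)
    q = np.full(len(results), np.nan)
    if tested.any():
        q[tested] = multipletests(results.loc[tested, p_col],
                                  method="fdr_bh")[1]
    results[f"q_{method}"] = q
    return results


def _observed_ea(effects: Iterable[ProteinEffect], cfg: RankingConfig
                 ) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for e in effects:
        if e.effect == MISSENSE and e.ea is not None:
            out.setdefault(e.gene, []).append(e.ea)
        elif e.effect == NONSENSE and cfg.stop_gain_score is not None:
            out.setdefault(e.gene, []).append(cfg.stop_gain_score)
    return out


def _collapse_effects(effects: Sequence[ProteinEffect],
                      cfg: RankingConfig) -> list[ProteinEffect]:
    """Apply the recurrence policy: one record per (strain, gene, change) or
    per (gene, change). Identity is the amino-acid substitution, so a change
    reached by different nucleotide routes still counts once."""
    seen: set[tuple] = set()
    out = []
    for e in effects:
        if e.effect == INTERGENIC:
            continue
        ident = (e.gene, e.codon_index, e.ref_aa, e.alt_aa)
        key = (e.strain,) + ident if cfg.per_strain_recurrence else ident
        if key in seen:
            continue
        seen.add(key)
        out.append(e)
    return out


def rank_drivers(genome: ReferenceGenome, effects: Sequence[ProteinEffect],
                 background: BackgroundSet,
                 config: RankingConfig | None = None) -> pd.DataFrame:
    """Run all three gene-level tests and rank every gene in the genome.

    Returns one row per gene with counts, sumEA, the KS statistic, raw and
    BH-adjusted p-values and 1-based ranks for each method. Genes without
    enough scored missense (or with an empty background pool) get p = 1 on
    the EA tests and are excluded from the EA BH corrections.
    """
    cfg = config or RankingConfig()
    effects = _collapse_effects(effects, cfg)
    obs_ea = _observed_ea(effects, cfg)

    counted = set(NONSYNONYMOUS) | ({SYNONYMOUS} if cfg.count_synonymous
                                    else set())
    n_mut: dict[str, int] = {}
    n_scored: dict[str, int] = {}
    for e in effects:
        if e.effect in counted:
            n_mut[e.gene] = n_mut.get(e.gene, 0) + 1
        if e.effect == MISSENSE and e.ea is not None:
            n_scored[e.gene] = n_scored.get(e.gene, 0) + 1
    n_total = sum(n_mut.values())
    l_total = genome.coding_length_total

    rows = []
    for gene in sorted(genome.genes, key=lambda g: g.locus_tag):
        tag = gene.locus_tag
        obs = np.array(obs_ea.get(tag, []), dtype=float)
        pool = background.pool(tag, cfg.background_scope)
        sum_ea = float(obs.sum())
        ks_stat, p_ks, p_sum = 0.0, 1.0, 1.0
        tested_ea = obs.size >= cfg.min_mut and pool.size > 0
        if tested_ea:
            ks_stat, p_ks = ea_ks(obs, pool)
            rng = gene_rng(cfg.seed, tag)
            if cfg.conditional_sum_null:
                _, p_sum = ea_sum_test(obs, pool, cfg.n_mc, rng)
            else:
                _, p_sum = _unconditional_sum_test(
                    obs, pool, gene.cds_length, max(n_total, 1), l_total,
                    cfg.n_mc, rng)
        k = n_mut.get(tag, 0)
        p_freq = frequency_test(k, gene.cds_length, max(n_total, 1), l_total)
        rows.append({
            "locus_tag": tag, "gene_name": gene.gene_name,
            "cds_length": gene.cds_length, "n_mut": k,
            "n_missense_scored": int(obs.size) if cfg.stop_gain_score is None
            else n_scored.get(tag, 0),
            "sum_ea": sum_ea, "ks_stat": ks_stat,
            "p_ks": p_ks, "p_sum": p_sum, "p_freq": p_freq,
            "tested_ks": tested_ea, "tested_sum": tested_ea,
            "tested_freq": k >= 1,
        })
    df = pd.DataFrame(rows)
    for method in METHODS:
        rank_genes(df, method)
    cols = ["locus_tag", "gene_name", "cds_length", "n_mut",
            "n_missense_scored", "sum_ea", "ks_stat",
            "p_ks", "p_sum", "p_freq", "q_ks", "q_sum", "q_freq",
            "rank_ks", "rank_sum", "rank_freq",
            "tested_ks", "tested_sum", "tested_freq"]
    return df[cols].sort_values("locus_tag", ignore_index=True)


def _unconditional_sum_test(obs, pool, cds_length, n_total, l_total, n_mc,
                            rng) -> tuple[float, float]:
    """EA_sum null that also redraws the count ~ Binomial(N, L_g/L_tot)."""
    sum_ea = float(np.asarray(obs).sum())
    rate = cds_length / l_total
    counts = rng.binomial(n_total, rate, size=n_mc)
    null_sums = np.zeros(n_mc)
    nz = counts > 0
    if nz.any():
        total_draws = int(counts[nz].sum())
        draws = pool[rng.integers(0, pool.size, size=total_draws)]
        split = np.cumsum(counts[nz])[:-1]
        null_sums[nz] = np.array([s.sum() for s in np.split(draws, split)])
    p = (1.0 + np.count_nonzero(null_sums >= sum_ea)) / (1.0 + n_mc)
    return sum_ea, float(p)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write the gene-result table as TSV (stable column order and formats)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_manifest(path: str | Path, config: RankingConfig,
                   input_files: dict[str, str | Path] | None = None,
                   extra: dict | None = None) -> None:
    """Record config, seed and input-file SHA256 hashes for reproducibility."""
    hashes = {}
    for label, p in (input_files or {}).items():
        h = hashlib.sha256()
        h.update(Path(p).read_bytes())
        hashes[label] = h.hexdigest()
    payload = {"config": asdict(config), "input_sha256": hashes}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
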