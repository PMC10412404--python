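"""Consensus across ranking methods: Venn overlap and STRING query export.

Genes ranked highly by several independent statistics are likelier drivers.
This module takes the three methods' top-N lists, partitions their union into
the seven disjoint Venn regions, and exports gene sets as the plain-text
query a protein-protein-interaction enrichment service (STRING) accepts — the
network call itself is deliberately not made, for reproducibility.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGION_KEYS = ("ks_only", "sum_only", "freq_only", "ks_sum", "ks_freq",
               "sum_freq", "ks_sum_freq")


@dataclass
class OverlapReport:
    """Top lists per method, the 7 disjoint Venn regions, and the consensus
    (genes in at least two lists)."""

    top: dict[str, list[str]]  # method -> ordered top-N locus tags
    regions: dict[str, frozenset[str]]
    consensus: frozenset[str]
    n: int

    def region_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "top_n": self.n,
            "top_lists": self.top,
            "regions": {k: sorted(v) for k, v in self.regions.items()},
            "region_sizes": self.region_sizes(),
            "consensus": sorted(self.consensus),
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def membership_table(self) -> pd.DataFrame:
        union = sorted(set().union(*self.top.values()))
        return pd.DataFrame({
            "locus_tag": union,
            **{f"in_{m}": [g in set(self.top[m]) for g in union]
               for m in ("ks", "sum", "freq")},
            "consensus": [g in self.consensus for g in union],
        })


def top_list(results: pd.DataFrame, method: str, n: int) -> list[str]:
    """The first n locus tags of one method's ranking."""
    ordered = results.sort_values(f"rank_{method}")
    return ordered["locus_tag"].head(n).tolist()


def venn_overlap(rank_ks: Sequence[str], rank_sum: Sequence[str],
                 rank_freq: Sequence[str], n: int) -> OverlapReport:
    """Exact set algebra over the three top-N lists.

    N larger than a list is clamped (with a warning). Region sizes always sum
    to the union size; every gene lands in exactly one region.
    """
    shortest = min(len(rank_ks), len(rank_sum), len(rank_freq))
    if n > shortest:
        logger.warning("top-N %d exceeds list length %d; clamping", n, shortest)
        n = shortest
    top = {"ks": list(rank_ks[:n]), "sum": list(rank_sum[:n]),
           "freq": list(rank_freq[:n])}
    a, b, c = (set(top[m]) for m in ("ks", "sum", "freq"))
    regions = {
        "ks_only": frozenset(a - b - c),
        "sum_only": frozenset(b - a - c),
        "freq_only": frozenset(c - a - b),
        "ks_sum": frozenset((a & b) - c),
        "ks_freq": frozenset((a & c) - b),
        "sum_freq": frozenset((b & c) - a),
        "ks_sum_freq": frozenset(a & b & c),
    }
    consensus = frozenset((a & b) | (a & c) | (b & c))
    return OverlapReport(top=top, regions=regions, consensus=consensus, n=n)


def export_string_query(genes: Sequence[str] | set[str], path: str | Path,
                        taxon_id: int) -> None:
    """Write the newline-delimited gene list a STRING enrichment query takes.

    First line records the NCBI taxon as a comment; genes follow in
    lexicographic order. An empty set is an error.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("cannot export an empty gene set")
    with open(path, "w") as fh:
        fh.write(f"# taxon: {taxon_id}\n")
        fh.write("\n".join(genes) + "\n")
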