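"""Evolutionary Action (EA) score tables and per-residue score tracks.

EA scores the predicted functional impact of a missense substitution on a
0-100 scale (higher = more disruptive); they are consumed here as precomputed
tables keyed by (gene, residue position, alternate residue), never computed
from alignments. The module also generates synthetic EA tables for testing —
one Beta-distributed score per missense substitution reachable by a single
nucleotide change — and backs the quick per-substitution EA lookup.

Policy knobs (documented defaults):

* nonsense (stop-gain) substitutions are *excluded* from EA statistics by
  default but countable at a configured score (typically 100, maximally
  disruptive) via ``stop_gain_score``;
* missense substitutions absent from the table are dropped from EA statistics
  (never silently imputed) but stay in frequency counts;
* tables whose values all lie in [0, 1] are auto-rescaled to 0-100 with a
  warning, since both conventions circulate.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import STOP, ReferenceGenome, translate_codon
from .variants import _SUB_RE

logger = logging.getLogger(__name__)


class _Sentinel:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: returned by lookups when no score exists for the substitution (never 0)
MISSING = _Sentinel("MISSING")
#: returned when the query's reference residue contradicts the protein sequence
REF_MISMATCH = _Sentinel("REF_MISMATCH")


@dataclass
class EAScoreTable:
    """Per-gene mapping (residue position, alternate residue) -> EA in [0,100]."""

    scores: dict[str, dict[tuple[int, str], float]] = field(default_factory=dict)
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def add(self, gene: str, pos: int, alt_aa: str, ea: float) -> None:
        entry = self.scores.setdefault(gene, {})
        key = (pos, alt_aa)
        if key in entry and entry[key] != ea:
            raise ValueError(
                f"conflicting EA for {gene} position {pos} alt {alt_aa}: "
                f"{entry[key]} vs {ea}")
        entry[key] = ea

    def get(self, gene: str, pos: int, alt_aa: str) -> float | None:
        return self.scores.get(gene, {}).get((pos, alt_aa))

    def gene_values(self, gene: str) -> np.ndarray:
        return np.array(sorted(self.scores.get(gene, {}).values()), dtype=float)

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.scores.values())


@dataclass(frozen=True)
class ResidueScoreTrack:
    """One per-residue score vector for a protein (ET, pLDDT, sumEA, ...)."""

    gene: str
    kind: str  # ET | pLDDT | sumEA | unique_mutation_count
    values: np.ndarray  # length = protein_length; np.nan where undefined

    def __post_init__(self):
        if self.kind == "pLDDT":
            vals = self.values[~np.isnan(self.values)]
            if vals.size and (vals.min() < 0 or vals.max() > 100):
                raise ValueError("pLDDT values must lie in [0, 100]")


def _open_text(path: str | Path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def load_ea_table(path: str | Path, genome: ReferenceGenome | None = None
                  ) -> tuple[EAScoreTable, dict[str, int]]:
    """Load a tab-delimited EA table (locus_tag, position, refAA, altAA, EA).

    Rows with EA outside [0,100], positions beyond the protein, or a refAA
    that disagrees with the genome's protein sequence are rejected and
    counted. Duplicate keys with conflicting EA raise. If every value in the
    file is <= 1 the table is treated as 0-1 scaled and multiplied by 100.
    Returns (table, rejection counts by reason).
    """
    rows: list[tuple[str, int, str, str, float]] = []
    rejected: dict[str, int] = {}

    def reject(reason: str) -> None:
        rejected[reason] = rejected.get(reason, 0) + 1

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                reject("wrong_column_count")
                continue
            gene, pos_s, ref_aa, alt_aa, ea_s = fields[:5]
            try:
                pos, ea = int(pos_s), float(ea_s)
            except ValueError:
                reject("unparseable_fields")
                continue
            rows.append((gene, pos, ref_aa, alt_aa, ea))
    if rows and all(ea <= 1.0 for *_, ea in rows):
        logger.warning("EA table %s looks 0-1 scaled; rescaling to 0-100", path)
        rows = [(g, p, r, a, ea * 100.0) for g, p, r, a, ea in rows]

    table = EAScoreTable()
    for gene, pos, ref_aa, alt_aa, ea in rows:
        if not (0.0 <= ea <= 100.0):
            reject("ea_out_of_range")
            continue
        if pos < 1:
            reject("bad_position")
            continue
        if genome is not None:
            try:
                model = genome.gene(gene)
            except KeyError:
                reject("unknown_gene")
                continue
            if pos > model.protein_length:
                reject("position_beyond_protein")
                continue
            if model.protein_seq[pos - 1] != ref_aa:
                reject("ref_residue_mismatch")
                continue
            table.protein_lengths[gene] = model.protein_length
        if alt_aa == ref_aa:
            reject("alt_equals_ref")
            continue
        table.add(gene, pos, alt_aa, ea)
    if rejected:
        logger.info("EA table %s: rejected rows %s", path, rejected)
    return table, rejected


def lookup_ea(table: EAScoreTable, genome: ReferenceGenome, gene: str,
              substitution: str, *, stop_gain_score: float | None = None):
    """Quick EA search: score of one substitution (e.g. ``A12V``) in a gene.

    Returns the stored score, :data:`MISSING` when absent (never 0),
    :data:`REF_MISMATCH` when the stated reference residue contradicts the
    protein sequence, or ``stop_gain_score`` for nonsense substitutions when
    one is configured (else MISSING — EA is defined for missense only).
    """
    m = _SUB_RE.match(substitution)
    if not m:
        raise ValueError(f"malformed substitution {substitution!r}")
    ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    model = genome.resolve_gene(gene)
    if pos > model.protein_length or model.protein_seq[pos - 1] != ref_aa:
        return REF_MISMATCH
    if alt_aa == STOP:
        return stop_gain_score if stop_gain_score is not None else MISSING
    ea = table.get(model.locus_tag, pos, alt_aa)
    return MISSING if ea is None else ea


def reachable_missense(genome: ReferenceGenome, gene_tag: str
                       ) -> list[tuple[int, str, str]]:
    """All (position, refAA, altAA) missense reachable by one nt change.

    Enumerates the 9 single-nucleotide neighbours of every codon; start-codon
    changes are start-loss, not missense, so position 1 never appears.
    """
    gene = genome.gene(gene_tag)
    cds = genome.cds_sequence(gene)
    out: list[tuple[int, str, str]] = []
    seen: set[tuple[int, str]] = set()
    for ci in range(2, gene.protein_length + 1):
        codon = cds[3 * (ci - 1):3 * ci]
        ref_aa = codon and translate_codon(codon)
        for off in range(3):
            for b in "ACGT":
                if b == codon[off]:
                    continue
                alt_aa = translate_codon(codon[:off] + b + codon[off + 1:])
                if alt_aa in (ref_aa, STOP) or ref_aa == STOP:
                    continue
                if (ci, alt_aa) not in seen:
                    seen.add((ci, alt_aa))
                    out.append((ci, ref_aa, alt_aa))
    return out


def synth_ea_table(genome: ReferenceGenome, seed: int, *, alpha: float = 2.0,
                   beta: float = 2.0) -> EAScoreTable:
    """Generate a synthetic EA table covering every reachable missense.

    For every gene and every missense substitution reachable by a single
    nucleotide change from the reference codon, draws EA ~ 100 x
    Beta(alpha, beta) (default Beta(2,2): symmetric around 50, thin tails —
    a plausible stand-in for real impact-score spectra). Deterministic under
    ``seed``; genes are processed in sorted locus-tag order.
    """
    rng = np.random.default_rng(seed)
    table = EAScoreTable()
    for gene in sorted(genome.genes, key=lambda g: g.locus_tag):
        entries = reachable_missense(genome, gene.locus_tag)
        draws = 100.0 * rng.beta(alpha, beta, size=len(entries))
        for (pos, _ref, alt), ea in zip(entries, draws):
            table.add(gene.locus_tag, pos, alt, float(ea))
        table.protein_lengths[gene.locus_tag] = gene.protein_length
    return table


def write_ea_table(table: EAScoreTable, genome: ReferenceGenome,
                   path: str | Path) -> None:
    """Write a table in the tab-delimited exchange format (sorted, 4 dp)."""
    with open(path, "w") as fh:
        fh.write("#locus_tag\tposition\tref_aa\talt_aa\tEA\n")
        for gene in sorted(table.scores):
            prot = genome.gene(gene).protein_seq
            for (pos, alt), ea in sorted(table.scores[gene].items()):
                fh.write(f"{gene}\t{pos}\t{prot[pos - 1]}\t{alt}\t{ea:.4f}\n")


def load_residue_track(path: str | Path, kind: str,
                       genome: ReferenceGenome) -> dict[str, ResidueScoreTrack]:
    """Load per-residue score tracks (locus_tag, position, score) by gene.

    Positions without a row are NaN (undefined), rendered as the grey flag
    value downstream.
    """
    per_gene: dict[str, dict[int, float]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, pos_s, score_s = line.split("\t")[:3]
            per_gene.setdefault(gene, {})[int(pos_s)] = float(score_s)
    out = {}
    for gene, vals in per_gene.items():
        length = genome.gene(gene).protein_length
        arr = np.full(length, np.nan)
        for pos, score in vals.items():
            if 1 <= pos <= length:
                arr[pos - 1] = score
        out[gene] = ResidueScoreTrack(gene=gene, kind=kind, values=arr)
    return out
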