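"""Project per-residue scores onto protein structures for visual inspection.

Four per-residue tracks color a predicted structure: Evolutionary Trace (ET)
residue importance, AlphaFold's pLDDT confidence, the summed EA of observed
mutations (sumEA), and the number of distinct substitutions seen per residue.
The track is written into the B-factor column of a copy of the PDB, plus a
PyMOL command script that applies a blue-white-red spectrum over the track
range — a diffable, replayable stand-in for a binary session file.

Residues with no defined value carry the flag value -1.00 and are colored
grey, so "no data" never masquerades as a true zero.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBIO, PDBParser

from .ea import ResidueScoreTrack
from .reference import GeneModel
from .variants import MISSENSE, ProteinEffect

logger = logging.getLogger(__name__)

#: B-factor written for residues with no defined score (colored grey)
UNDEFINED_FLAG = -1.0


def residue_tracks_from_effects(effects: Iterable[ProteinEffect],
                                gene: GeneModel, *,
                                per_occurrence: bool = False
                                ) -> tuple[ResidueScoreTrack, ResidueScoreTrack]:
    """Build the (sumEA, unique mutation count) tracks for one gene.

    ``sumEA[i]`` sums the EA of scored missense at residue i across all
    strains — by default each distinct substitution counts once no matter how
    many strains carry it (set ``per_occurrence`` to sum every occurrence).
    ``unique[i]`` counts distinct alternate residues observed at i.
    """
    length = gene.protein_length
    sum_ea = np.zeros(length)
    unique = np.zeros(length)
    seen: set[tuple[int, str]] = set()
    for e in effects:
        if e.gene != gene.locus_tag or e.effect != MISSENSE or e.ea is None:
            continue
        if not (1 <= e.codon_index <= length):
            continue
        key = (e.codon_index, e.alt_aa)
        if key not in seen:
            seen.add(key)
            unique[e.codon_index - 1] += 1
            sum_ea[e.codon_index - 1] += e.ea
        elif per_occurrence:
            sum_ea[e.codon_index - 1] += e.ea
    return (ResidueScoreTrack(gene.locus_tag, "sumEA", sum_ea),
            ResidueScoreTrack(gene.locus_tag, "unique_mutation_count", unique))


def _load_single_chain(pdb_path: str | Path):
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(pdb_path))
    chains = [c for c in structure.get_chains()]
    if len(chains) != 1:
        raise ValueError(f"{pdb_path} has {len(chains)} chains; "
                         "single-chain structures only")
    return structure, chains[0]


def write_colored_pdb(pdb_path: str | Path, track: ResidueScoreTrack,
                      out_path: str | Path,
                      pml_path: str | Path | None = None) -> None:
    """Write a copy of the PDB with the track in the B-factor column.

    The structure must be single-chain with as many residues as the track
    (AlphaFold-style numbering from 1); a mismatch is a hard error naming
    both lengths. Values are clamped to [0, 999.99] (PDB fixed format, two
    decimals); undefined (NaN) residues get the -1.00 grey flag. When
    ``pml_path`` is given, a PyMOL script is written that loads the output
    and applies a blue-white-red spectrum over the track's min..max, greying
    undefined residues.
    """
    structure, chain = _load_single_chain(pdb_path)
    residues = [r for r in chain.get_residues() if r.id[0] == " "]
    values = np.asarray(track.values, dtype=float)
    if len(residues) != values.size:
        raise ValueError(
            f"residue count mismatch: PDB {pdb_path} has {len(residues)} "
            f"residues but track {track.kind}/{track.gene} has {values.size}")
    for res, val in zip(residues, values):
        b = UNDEFINED_FLAG if np.isnan(val) else float(np.clip(val, 0.0, 999.99))
        for atom in res.get_atoms():
            atom.set_bfactor(b)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path))
    if pml_path is not None:
        write_pml(out_path, track, pml_path)


def write_pml(colored_pdb: str | Path, track: ResidueScoreTrack,
              pml_path: str | Path) -> None:
    """PyMOL command script reproducing the coloring scheme."""
    defined = track.values[~np.isnan(track.values)]
    lo = float(defined.min()) if defined.size else 0.0
    hi = float(defined.max()) if defined.size else 1.0
    if hi <= lo:
        hi = lo + 1.0
    lines = [
        f"# {track.kind} coloring for {track.gene}",
        f"load {Path(colored_pdb).name}, {track.gene}",
        "hide everything",
        "show cartoon",
        f"spectrum b, blue_white_red, {track.gene} and b > -0.5, "
        f"minimum={lo:.2f}, maximum={hi:.2f}",
        f"color gray70, {track.gene} and b < -0.5",
        "bg_color white",
    ]
    Path(pml_path).write_text("\n".join(lines) + "\n")


def read_track_from_pdb(pdb_path: str | Path, gene: str,
                        kind: str) -> ResidueScoreTrack:
    """Recover a per-residue track from a colored PDB's B-factor column.

    The -1.00 grey flag maps back to NaN (undefined). Inverse of
    :func:`write_colored_pdb` up to 2-decimal quantization.
    """
    _, chain = _load_single_chain(pdb_path)
    vals = []
    for res in chain.get_residues():
        if res.id[0] != " ":
            continue
        b = next(res.get_atoms()).get_bfactor()
        vals.append(np.nan if b < -0.5 else b)
    return ResidueScoreTrack(gene, kind, np.array(vals))
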