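"""Protein FASTA ingestion, in-silico digestion, variable-modification
expansion and reversed-sequence decoy generation.

Digestion rules follow the "/P" convention: Trypsin/P cleaves C-terminal to
K/R and Chymotrypsin/P C-terminal to F/W/Y/L, in both cases with no proline
restriction.  Decoys are full-sequence reversals (deterministic, preserves
length and residue composition) and carry the ``DECOY_`` accession prefix.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import SeqIO

from .chem import AA_RESIDUES, PEPTIDE_MOD_MASSES, peptide_mass

DECOY_PREFIX = "DECOY_"

ENZYMES: Dict[str, str] = {
    "Trypsin/P": "KR",
    "Chymotrypsin/P": "FWYL",
}


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    sequence: str
    is_decoy: bool = False


@dataclass(frozen=True)
class Modification:
    position: int      # 0-based residue index
    mass_delta: float
    name: str


@dataclass(frozen=True)
class PeptideCandidate:
    sequence: str
    start: int                       # 0-based, half-open in parent
    end: int
    missed_cleavages: int
    modifications: Tuple[Modification, ...] = ()
    accessions: FrozenSet[str] = frozenset()
    is_decoy: bool = False

    @functools.cached_property
    def mono_mass(self) -> float:
        return peptide_mass(self.sequence, (m.mass_delta for m in self.modifications))

    @property
    def mod_key(self) -> Tuple[Tuple[int, str], ...]:
        return tuple((m.position, m.name) for m in self.modifications)


def read_fasta(path: str) -> List[ProteinEntry]:
    """Read a protein FASTA; UniProt-style ``db|ACC|name`` headers are parsed
    down to the accession, other headers use the first whitespace-delimited
    token."""
    entries = []
    for rec in SeqIO.parse(path, "fasta"):
        token = rec.id
        if token.count("|") >= 2:
            token = token.split("|")[1]
        entries.append(ProteinEntry(token, str(rec.seq).upper()))
    return entries


def cleavage_sites(sequence: str, enzyme: str) -> List[int]:
    """Positions *after* which the enzyme cleaves (0-based residue index)."""
    try:
        residues = ENZYMES[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme {enzyme!r}; supported: {sorted(ENZYMES)}") from None
    return [i for i, aa in enumerate(sequence[:-1]) if aa in residues]


def digest(
    protein: ProteinEntry,
    enzyme: str = "Trypsin/P",
    max_missed_cleavages: int = 2,
    min_len: int = 5,
    max_len: int = 30,
) -> List[PeptideCandidate]:
    """Enzymatic digest of one protein into peptide candidates.

    Every product with at most ``max_missed_cleavages`` internal cleavage
    sites and a length within bounds is emitted, annotated with its
    missed-cleavage count.  Peptides containing non-canonical residues
    (e.g. X) are excluded from candidates.
    """
    seq = protein.sequence
    if not seq:
        return []
    sites = cleavage_sites(seq, enzyme)
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            pep = seq[start:end]
            if not (min_len <= len(pep) <= max_len):
                continue
            if any(aa not in AA_RESIDUES for aa in pep):
                continue
            out.append(
                PeptideCandidate(
                    sequence=pep,
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                    accessions=frozenset({protein.accession}),
                    is_decoy=protein.is_decoy,
                )
            )
    return out


def expand_mods(
    peptide: PeptideCandidate,
    variable: Sequence[Tuple[str, str]] = (("M", "Oxidation"),),
    fixed: Sequence[Tuple[str, str]] = (),
    max_var_mods: int = 2,
) -> List[PeptideCandidate]:
    """Expand a peptide into all modification variants.

    ``variable``/``fixed`` are (residue, modification-name) pairs with
    deltas looked up in the standard table (Oxidation +15.994915,
    Carbamidomethyl +57.021464).  All combinations of at most
    ``max_var_mods`` variable modifications are generated; fixed
    modifications apply unconditionally.
    """
    fixed_mods = [
        Modification(i, PEPTIDE_MOD_MASSES[name], name)
        for res, name in fixed
        for i, aa in enumerate(peptide.sequence)
        if aa == res
    ]
    var_positions = [
        (i, name)
        for res, name in variable
        for i, aa in enumerate(peptide.sequence)
        if aa == res
    ]
    out = []
    for k in range(0, min(max_var_mods, len(var_positions)) + 1):
        for combo in itertools.combinations(var_positions, k):
            mods = tuple(
                sorted(
                    fixed_mods
                    + [Modification(i, PEPTIDE_MOD_MASSES[name], name) for i, name in combo],
                    key=lambda m: m.position,
                )
            )
            out.append(replace(peptide, modifications=mods))
    return out


def make_decoys(db: Sequence[ProteinEntry]) -> List[ProteinEntry]:
    """Append one reversed-sequence decoy per target entry.

    Palindromic sequences produce decoys identical to their targets; these
    are retained (and detectable by comparing sequences) so that the decoy
    count stays exactly equal to the target count.
    """
    out = list(db)
    for entry in db:
        if entry.is_decoy:
            continue
        out.append(
            ProteinEntry(DECOY_PREFIX + entry.accession, entry.sequence[::-1], is_decoy=True)
        )
    return out


def build_peptide_db(
    proteins: Sequence[ProteinEntry],
    enzyme: str = "Trypsin/P",
    max_missed_cleavages: int = 2,
    min_len: int = 5,
    max_len: int = 30,
    variable: Sequence[Tuple[str, str]] = (("M", "Oxidation"),),
    fixed: Sequence[Tuple[str, str]] = (),
    max_var_mods: int = 2,
) -> List[PeptideCandidate]:
    """Digest + modification expansion over a protein list, with identical
    (sequence, mods, decoy-flag) peptides merged and their parent accessions
    unioned."""
    merged: Dict[Tuple[str, Tuple, bool], PeptideCandidate] = {}
    for protein in proteins:
        for pep in digest(protein, enzyme, max_missed_cleavages, min_len, max_len):
            for var in expand_mods(pep, variable, fixed, max_var_mods):
                key = (var.sequence, var.mod_key, var.is_decoy)
                if key in merged:
                    prev = merged[key]
                    merged[key] = replace(prev, accessions=prev.accessions | var.accessions)
                else:
                    merged[key] = var
    return sorted(merged.values(), key=lambda p: (p.sequence, p.mod_key, p.is_decoy))
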