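"""Protein FASTA input, reversed-decoy construction and tryptic digestion.

The decoy database is built by reversing each *protein* sequence before
digestion (so decoy peptides are in general not reversals of target
peptides). Trypsin cleaves after every K and R; peptides outside the
7–30 residue window or containing 'X' are discarded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .masses import CANONICAL_RESIDUES, peptide_mass

TARGET = "target"
DECOY = "decoy"

_ALLOWED = CANONICAL_RESIDUES | {"X"}


@dataclass(frozen=True)
class Protein:
    id: str
    sequence: str
    origin: str = TARGET

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"protein {self.id!r}: unsupported residue letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with its origin, parent proteins and mass (Da)."""

    sequence: str
    origin: str
    parents: frozenset[str] = field(default_factory=frozenset)
    mass: float = 0.0

    @staticmethod
    def from_sequence(sequence: str, origin: str = TARGET,
                      parents: Iterable[str] = ()) -> "Peptide":
        return Peptide(sequence, origin, frozenset(parents), peptide_mass(sequence))


@dataclass(frozen=True)
class DigestionParams:
    min_length: int = 7
    max_length: int = 30
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


def read_fasta(path: str | Path) -> list[Protein]:
    """Read a protein FASTA file into target Proteins.

    The accession is the header token up to the first whitespace;
    sequences are uppercased. Records with empty sequences or letters
    outside the 20 canonical residues plus 'X' are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    proteins = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {record.id!r}: empty sequence")
        proteins.append(Protein(id=record.id, sequence=seq, origin=TARGET))
    return proteins


def make_decoy(proteins: Sequence[Protein], tag: str = "DECOY_") -> list[Protein]:
    """Reverse every protein sequence; prefix accessions with ``tag``."""
    decoys = []
    for p in proteins:
        if p.origin != TARGET:
            raise ValueError(f"protein {p.id!r} is not a target protein")
        decoys.append(Protein(id=tag + p.id, sequence=p.sequence[::-1], origin=DECOY))
    return decoys


def _cleave(sequence: str) -> list[str]:
    """Fragments obtained by cutting after every K and R."""
    fragments, start = [], 0
    for i, aa in enumerate(sequence):
        if aa in ("K", "R"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    return fragments


def digest(protein: Protein, params: DigestionParams = DigestionParams()) -> list[Peptide]:
    """In-silico tryptic digestion with length and 'X' filters applied."""
    fragments = _cleave(protein.sequence)
    peptides = []
    for n_missed in range(params.missed_cleavages + 1):
        for i in range(len(fragments) - n_missed):
            seq = "".join(fragments[i : i + 1 + n_missed])
            if not params.min_length <= len(seq) <= params.max_length:
                continue
            if "X" in seq:
                continue
            peptides.append(
                Peptide(seq, protein.origin, frozenset([protein.id]), peptide_mass(seq))
            )
    return peptides


def _dedup(peptides: Iterable[Peptide]) -> list[Peptide]:
    """Deduplicate by sequence within one origin, merging parent accessions."""
    merged: dict[str, Peptide] = {}
    for p in peptides:
        prev = merged.get(p.sequence)
        if prev is None:
            merged[p.sequence] = p
        else:
            if prev.origin != p.origin:
                raise ValueError("mixed origins passed to _dedup")
            merged[p.sequence] = Peptide(
                p.sequence, p.origin, prev.parents | p.parents, p.mass
            )
    return sorted(merged.values(), key=lambda p: p.sequence)


def build_peptide_sets(
    target_proteins: Sequence[Protein],
    decoy_proteins: Sequence[Protein],
    params: DigestionParams = DigestionParams(),
) -> tuple[list[Peptide], list[Peptide]]:
    """Digest both databases into (bait set, searched database).

    The bait set is the deduplicated target peptides; the database is the
    union of deduplicated target and deduplicated decoy peptides. A
    sequence present in both origins yields two database entries, one per
    origin.
    """
    target_peps = _dedup(
        itertools.chain.from_iterable(digest(p, params) for p in target_proteins)
    )
    decoy_peps = _dedup(
        itertools.chain.from_iterable(digest(p, params) for p in decoy_proteins)
    )
    if not target_peps:
        raise ValueError(
            "no target peptides survive digestion "
            f"(length window [{params.min_length}, {params.max_length}], 'X' filter)"
        )
    return target_peps, target_peps + decoy_peps


def peptides_to_frame(peptides: Iterable[Peptide]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptides],
            "origin": [p.origin for p in peptides],
            "mass": [round(p.mass, 5) for p in peptides],
            "parents": [";".join(sorted(p.parents)) for p in peptides],
        }
    )


def write_peptides_tsv(peptides: Iterable[Peptide], path: str | Path) -> None:
    peptides_to_frame(peptides).to_csv(path, sep="\t", index=False, float_format="%.5f")
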