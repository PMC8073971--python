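"""Seeded synthetic proteomes and planted-modification fixtures.

The generator produces random proteins whose K/R frequency is tuned so
tryptic digestion yields peptides mostly inside the 7–30 length window,
plus "planted" bait peptides derived from database peptides by known
editing operations. Planted baits are injected as extra experimental
baits — never into the searched database — so the true hit is always
present and the self-match exclusion cannot remove it. Every draw is
deterministic under the seed and comes with a ground-truth table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .masses import MONOISOTOPIC, peptide_mass, residues_with_mass
from .proteome import Peptide

_RESIDUES = sorted(MONOISOTOPIC)
_NON_KR = [aa for aa in _RESIDUES if aa not in ("K", "R")]

#: single-edit kinds drawn uniformly by kind="single"
SINGLE_KINDS = ("insert1", "delete", "substitute")


@dataclass(frozen=True)
class EditSpec:
    """What to plant: edit kind, how many baits, content sizes, seed."""

    kind: str = "single"  # insert1 | insertK | delete | substitute | twoSite | single
    n_baits: int = 100
    insert_len: int = 2  # for insertK
    delete_len: int = 1  # for delete
    seed: int = 0
    residues: str = "".join(_RESIDUES)  # pool for inserted/substituted content


def generate_proteome(
    n_proteins: int = 50,
    length_range: tuple[int, int] = (150, 600),
    seed: int = 0,
    kr_fraction: float = 0.12,
) -> str:
    """Random protein FASTA text, deterministic under the seed.

    Residues are drawn uniformly except K and R, which together get
    ``kr_fraction`` of the probability mass; at 0.12 the mean tryptic
    fragment length is ~8, so most peptides fall inside [7, 30].
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    probs = np.full(len(_RESIDUES), (1 - kr_fraction) / len(_NON_KR))
    for aa in ("K", "R"):
        probs[_RESIDUES.index(aa)] = kr_fraction / 2
    out = io.StringIO()
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_RESIDUES, size=length, p=probs))
        out.write(f">SYN{i + 1:04d}\n")
        for start in range(0, length, 60):
            out.write(seq[start : start + 60] + "\n")
    return out.getvalue()


def _expected_color_insert(content: str) -> str:
    if len(content) > 1:
        return "Orange"
    return "Green" if len(residues_with_mass(MONOISOTOPIC[content])) == 1 else "Orange"


def _expected_color_substitute(replacement: str) -> str:
    return "Green" if len(residues_with_mass(MONOISOTOPIC[replacement])) == 1 else "Orange"


def plant_edits(
    source_peptides: Sequence[Peptide],
    spec: EditSpec,
    forbidden: Optional[Iterable[str]] = None,
) -> tuple[list[Peptide], pd.DataFrame]:
    """Derive bait peptides from database peptides by known edits.

    ``forbidden`` is the set of sequences the baits must avoid (normally
    every database sequence, so the self-match exclusion downstream never
    hits a planted bait); defaults to the source sequences. Returns the
    baits and a truth table with the edit, its site, content, Δm, the
    expected color class and the expected coincidence-free shift SPC
    (2·min of the two peptide lengths).
    """
    rng = np.random.default_rng(spec.seed)
    forbidden = set(forbidden) if forbidden is not None else {
        p.sequence for p in source_peptides
    }
    pool = list(spec.residues)
    baits: list[Peptide] = []
    rows = []
    for _ in range(spec.n_baits):
        for _attempt in range(500):
            kind = (
                SINGLE_KINDS[int(rng.integers(len(SINGLE_KINDS)))]
                if spec.kind == "single" else spec.kind
            )
            source = source_peptides[int(rng.integers(len(source_peptides)))]
            built = _apply_edit(source.sequence, kind, spec, pool, rng)
            if built is None:
                continue
            bait_seq, site, content, expected = built
            if not 7 <= len(bait_seq) <= 30:
                continue
            if bait_seq in forbidden or bait_seq == source.sequence:
                continue
            delta_m = peptide_mass(bait_seq) - peptide_mass(source.sequence)
            if kind != "twoSite" and delta_m == 0:
                continue
            baits.append(Peptide.from_sequence(bait_seq))
            rows.append(
                {
                    "bait": bait_seq,
                    "source": source.sequence,
                    "edit_kind": kind,
                    "site": site,
                    "content": content,
                    "delta_m": round(delta_m, 5),
                    "expected_color": expected,
                    "expected_shift_spc": 2 * min(len(bait_seq), len(source.sequence)),
                }
            )
            break
        else:
            raise RuntimeError(
                f"could not plant a {spec.kind!r} edit in 500 attempts; "
                "source peptides too constrained"
            )
    return baits, pd.DataFrame(rows)


def _apply_edit(seq, kind, spec, pool, rng):
    """One edit attempt; returns (bait, site, content, expected color) or None."""
    n = len(seq)
    if kind == "insert1":
        site = int(rng.integers(0, n + 1))  # boundary: insert before position site+1
        content = pool[int(rng.integers(len(pool)))]
        return seq[:site] + content + seq[site:], site, content, _expected_color_insert(content)
    if kind == "insertK":
        site = int(rng.integers(0, n + 1))
        content = "".join(pool[int(rng.integers(len(pool)))] for _ in range(spec.insert_len))
        return seq[:site] + content + seq[site:], site, content, "Orange"
    if kind == "delete":
        d = spec.delete_len
        if n - d < 7:
            return None
        site = int(rng.integers(0, n - d + 1))
        content = seq[site : site + d]
        return seq[:site] + seq[site + d :], site, content, "Green"
    if kind == "substitute":
        # a length-n hit shares only n-1 raw masses with its substituted bait,
        # so n >= 8 is needed for the pair to pass the SPC >= 7 threshold
        if n < 8:
            return None
        site = int(rng.integers(0, n))
        old = seq[site]
        new = pool[int(rng.integers(len(pool)))]
        if new == old:
            return None
        return (
            seq[:site] + new + seq[site + 1 :],
            site,
            f"{old}>{new}",
            _expected_color_substitute(new),
        )
    if kind == "twoSite":
        # two separated substitutions; keep >= 7 intact terminal fragments so
        # the true pair stays above the candidate threshold
        if n < 11:
            return None
        q1 = int(rng.integers(1, 5))  # 1-based
        hi = n - 8 + q1
        if hi < q1 + 2:
            return None
        q2 = int(rng.integers(q1 + 2, hi + 1))
        out = list(seq)
        content_parts = []
        for q in (q1, q2):
            old = out[q - 1]
            choices = [aa for aa in pool if aa != old]
            new = choices[int(rng.integers(len(choices)))]
            out[q - 1] = new
            content_parts.append(f"{old}{q}{new}")
        return "".join(out), q1, ";".join(content_parts), "Red"
    raise ValueError(f"unknown edit kind {kind!r}")


def worked_example_fixture() -> tuple[Peptide, Peptide]:
    """The worked-example pair: bait EAEDISEK vs hit EAEISEK.

    Raw SPC 7; the best single-site realignment with Δm = mass(D) sits
    at position 3 and lifts the SPC to 14 (8 new matches, 1 removed).
    """
    return Peptide.from_sequence("EAEDISEK"), Peptide.from_sequence("EAEISEK")
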