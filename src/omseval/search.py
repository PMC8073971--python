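"""Candidate PSM enumeration over bait × database and Strategy1 selection.

An inverted index over discretized fragment masses replaces an all-pairs
scan: for each bait, the shared peaks count (SPC) against every database
spectrum is accumulated key by key, and every pair reaching the SPC
threshold becomes a candidate PSM. Strategy1 picks, per bait, the
candidate with the highest raw SPC.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .masses import DEFAULT_PRECISION
from .proteome import TARGET
from .spectra import TheoreticalSpectrum


@dataclass(frozen=True)
class CandidatePSM:
    """A (bait, hit) pair with raw SPC ≥ threshold and Δm = mass(bait) − mass(hit)."""

    bait_id: int
    hit_id: int
    raw_spc: int
    delta_m: float


@dataclass(frozen=True)
class BestPSM:
    bait_id: int
    hit_id: int
    bait_sequence: str
    hit_sequence: str
    hit_origin: str
    score: int  # raw SPC (strategy 1) or shift SPC (strategy 2)
    raw_spc: int
    delta_m: float
    strategy: int
    alignment: Optional[object] = None  # ShiftAlignment for strategy 2, Δm ≠ 0


class MassIndex:
    """Inverted index: discretized mass key → [(spectrum id, multiplicity)]."""

    def __init__(self, spectra: Sequence[TheoreticalSpectrum],
                 precision: float = DEFAULT_PRECISION):
        self.precision = precision
        self.postings: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for sid, spectrum in enumerate(spectra):
            for key, mult in spectrum.key_counter(precision).items():
                self.postings[key].append((sid, mult))

    def query(self, key: int) -> list[tuple[int, int]]:
        return self.postings.get(key, [])


def count_spc(a: TheoreticalSpectrum, b: TheoreticalSpectrum,
              precision: float = DEFAULT_PRECISION) -> int:
    """Shared peaks count: multiset intersection of discretized masses."""
    ka, kb = a.key_counter(precision), b.key_counter(precision)
    return sum((ka & kb).values())


def enumerate_candidates(
    bait_spectra: Sequence[TheoreticalSpectrum],
    db_spectra: Sequence[TheoreticalSpectrum],
    threshold: int = 7,
    precision: float = DEFAULT_PRECISION,
    index: Optional[MassIndex] = None,
) -> list[CandidatePSM]:
    """All (bait, hit) pairs with SPC ≥ threshold, self-sequence pairs excluded.

    Δm is the bait peptide mass minus the hit peptide mass; because both
    derive from exact integer residue sums, Δm is exactly 0.0 for
    equal-composition peptides. Output order is (bait_id, hit_id),
    independent of index traversal order.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if index is None:
        index = MassIndex(db_spectra, precision)
    elif index.precision != precision:
        raise ValueError("index precision does not match requested precision")
    candidates = []
    for bait_id, bait in enumerate(bait_spectra):
        acc: Counter = Counter()
        for key, a in bait.key_counter(precision).items():
            for hit_id, b in index.query(key):
                acc[hit_id] += min(a, b)
        for hit_id in sorted(hit_id for hit_id, spc in acc.items() if spc >= threshold):
            hit = db_spectra[hit_id]
            if hit.sequence == bait.sequence:
                continue
            candidates.append(
                CandidatePSM(bait_id, hit_id, acc[hit_id],
                             bait.peptide.mass - hit.peptide.mass)
            )
    return candidates


def group_by_bait(candidates: Sequence[CandidatePSM]) -> dict[int, list[CandidatePSM]]:
    grouped: dict[int, list[CandidatePSM]] = defaultdict(list)
    for c in candidates:
        grouped[c.bait_id].append(c)
    return grouped


def tie_break_key(score: int, delta_m: float, hit_origin: str, hit_sequence: str):
    """Sort key for best-PSM selection (ascending sort, best first).

    Highest score, then smallest |Δm|, then target before decoy, then
    lexicographically smallest hit sequence. The chain is a documented
    convention: the reference engine's own tie-breaking is unpublished.
    """
    return (-score, abs(delta_m), 0 if hit_origin == TARGET else 1, hit_sequence)


def select_best_strategy1(
    candidates: Sequence[CandidatePSM],
    bait_spectra: Sequence[TheoreticalSpectrum],
    db_spectra: Sequence[TheoreticalSpectrum],
) -> list[BestPSM]:
    """Per bait, the candidate with maximal raw SPC (deterministic ties)."""
    best_psms = []
    for bait_id, cands in sorted(group_by_bait(candidates).items()):
        best = min(
            cands,
            key=lambda c: tie_break_key(
                c.raw_spc, c.delta_m,
                db_spectra[c.hit_id].peptide.origin,
                db_spectra[c.hit_id].sequence,
            ),
        )
        hit = db_spectra[best.hit_id]
        best_psms.append(
            BestPSM(
                bait_id=bait_id,
                hit_id=best.hit_id,
                bait_sequence=bait_spectra[bait_id].sequence,
                hit_sequence=hit.sequence,
                hit_origin=hit.peptide.origin,
                score=best.raw_spc,
                raw_spc=best.raw_spc,
                delta_m=best.delta_m,
                strategy=1,
            )
        )
    return best_psms


def best_psms_to_frame(best_psms: Sequence[BestPSM]) -> pd.DataFrame:
    rows = []
    for p in best_psms:
        position = ""
        if p.alignment is not None and getattr(p.alignment, "position", None) is not None:
            position = p.alignment.position
        rows.append(
            (p.bait_sequence, p.hit_sequence, p.hit_origin, p.score, p.raw_spc,
             round(p.delta_m, 5), p.strategy, position)
        )
    return pd.DataFrame(
        rows,
        columns=["bait", "hit", "hit_origin", "score", "raw_spc",
                 "delta_m", "strategy", "position"],
    )
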