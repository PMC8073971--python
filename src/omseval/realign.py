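"""Strategy2: Δm shift realignment of hit spectra and best-PSM selection.

For a candidate PSM with Δm ≠ 0, the hit spectrum is realigned to the
bait by adding Δm to every fragment mass on one side of a single shift
location, for every possible location; the location yielding the highest
realigned shared peaks count ("shift SPC") is retained.

Shift locations are 1-based positions p ∈ [1, n_hit + 1], p meaning "the
modification sits at the boundary before hit residue p": b-ions with
index ≥ p and y-ions with index ≥ n_hit − p + 1 receive +Δm (those are
exactly the fragments whose mass changes when residues of total mass Δm
are inserted at that boundary). p = 1 shifts the whole b series
(N-terminal side); p = n_hit + 1 shifts the whole y series (C-terminal
side). The identity (no-shift) alignment is always a candidate, so
shift SPC ≥ raw SPC by construction; it is kept only when no shift
strictly improves, and ties between shifts go to the smallest position.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .masses import DEFAULT_PRECISION, _SCALE, discretize
from .search import (
    BestPSM,
    CandidatePSM,
    group_by_bait,
    tie_break_key,
)
from .spectra import Fragment, TheoreticalSpectrum

#: a database fragment after (possible) shifting: (fragment, mass, shifted?)
ShiftedEntry = tuple[Fragment, float, bool]


@dataclass(frozen=True)
class MatchGroup:
    """All bait and hit fragments behind one shared discretized mass."""

    key: int
    bait_fragments: tuple[Fragment, ...]
    hit_fragments: tuple[ShiftedEntry, ...]
    count: int  # multiplicity contributed to the SPC: min of the two sides


@dataclass(frozen=True)
class ShiftAlignment:
    """Best single-site realignment of a hit spectrum onto a bait spectrum."""

    position: Optional[int]  # None = identity (no shift applied)
    shift_spc: int
    delta_m: float
    matched: tuple[MatchGroup, ...] = ()

    @property
    def n_shifted_matches(self) -> int:
        return sum(
            g.count for g in self.matched
            if any(shifted for _, _, shifted in g.hit_fragments)
        )


def apply_shift(
    hit_spectrum: TheoreticalSpectrum, delta_m: float, position: int
) -> list[ShiftedEntry]:
    """Shift the hit's fragment masses by Δm at one boundary position."""
    if delta_m == 0:
        raise ValueError("apply_shift requires delta_m != 0")
    n = len(hit_spectrum.sequence)
    if not 1 <= position <= n + 1:
        raise ValueError(f"shift position {position} out of range [1, {n + 1}]")
    delta_units = round(delta_m * _SCALE)
    entries: list[ShiftedEntry] = []
    for f in hit_spectrum.fragments:
        shifted = f.index >= position if f.ion_type == "b" else f.index >= n - position + 1
        mass = (round(f.mass * _SCALE) + delta_units) / _SCALE if shifted else f.mass
        entries.append((f, mass, shifted))
    return entries


def _identity_entries(hit_spectrum: TheoreticalSpectrum) -> list[ShiftedEntry]:
    return [(f, f.mass, False) for f in hit_spectrum.fragments]


def _match_groups(
    bait_spectrum: TheoreticalSpectrum,
    entries: Sequence[ShiftedEntry],
    precision: float,
) -> tuple[MatchGroup, ...]:
    by_key_bait: dict[int, list[Fragment]] = defaultdict(list)
    for f in bait_spectrum.fragments:
        by_key_bait[discretize(f.mass, precision)].append(f)
    by_key_hit: dict[int, list[ShiftedEntry]] = defaultdict(list)
    for entry in entries:
        by_key_hit[discretize(entry[1], precision)].append(entry)
    groups = []
    for key in sorted(by_key_bait.keys() & by_key_hit.keys()):
        bait_frags = tuple(by_key_bait[key])
        hit_frags = tuple(by_key_hit[key])
        groups.append(
            MatchGroup(key, bait_frags, hit_frags, min(len(bait_frags), len(hit_frags)))
        )
    return tuple(groups)


def _spc_of_entries(
    bait_keys: Counter, entries: Sequence[ShiftedEntry], precision: float
) -> int:
    keys = Counter(discretize(mass, precision) for _, mass, _ in entries)
    return sum((bait_keys & keys).values())


def raw_alignment(
    bait_spectrum: TheoreticalSpectrum,
    hit_spectrum: TheoreticalSpectrum,
    delta_m: float,
    precision: float = DEFAULT_PRECISION,
) -> ShiftAlignment:
    """The identity alignment (used for Δm = 0 PSMs and Strategy1 evaluation)."""
    entries = _identity_entries(hit_spectrum)
    groups = _match_groups(bait_spectrum, entries, precision)
    return ShiftAlignment(None, sum(g.count for g in groups), delta_m, groups)


def best_shift(
    bait_spectrum: TheoreticalSpectrum,
    hit_spectrum: TheoreticalSpectrum,
    delta_m: float,
    precision: float = DEFAULT_PRECISION,
) -> ShiftAlignment:
    """Evaluate every shift position plus the identity; return the best.

    Ties between shift positions go to the smallest position; the
    identity alignment is returned only if no shift strictly beats the
    raw SPC.
    """
    if delta_m == 0:
        raise ValueError("best_shift requires delta_m != 0")
    bait_keys = bait_spectrum.key_counter(precision)
    n = len(hit_spectrum.sequence)
    raw_spc = _spc_of_entries(bait_keys, _identity_entries(hit_spectrum), precision)
    best_position: Optional[int] = None
    best_spc = raw_spc
    for position in range(1, n + 2):
        entries = apply_shift(hit_spectrum, delta_m, position)
        spc = _spc_of_entries(bait_keys, entries, precision)
        if spc > best_spc:
            best_spc, best_position = spc, position
    if best_position is None:
        entries = _identity_entries(hit_spectrum)
    else:
        entries = apply_shift(hit_spectrum, delta_m, best_position)
    groups = _match_groups(bait_spectrum, entries, precision)
    return ShiftAlignment(best_position, best_spc, delta_m, groups)


def gained_and_lost(
    bait_spectrum: TheoreticalSpectrum,
    hit_spectrum: TheoreticalSpectrum,
    delta_m: float,
    position: int,
    precision: float = DEFAULT_PRECISION,
) -> tuple[int, int]:
    """Matches gained and lost by shifting the hit at one position.

    Returns (new, removed) relative to the raw (unshifted) matching;
    raw SPC + new − removed = the realigned SPC at that position.
    """
    bait_keys = bait_spectrum.key_counter(precision)
    raw = bait_keys & hit_spectrum.key_counter(precision)
    entries = apply_shift(hit_spectrum, delta_m, position)
    shifted = bait_keys & Counter(discretize(m, precision) for _, m, _ in entries)
    new = sum((shifted - raw).values())
    removed = sum((raw - shifted).values())
    return new, removed


def alignment_at(
    bait_spectrum: TheoreticalSpectrum,
    hit_spectrum: TheoreticalSpectrum,
    delta_m: float,
    position: Optional[int],
    precision: float = DEFAULT_PRECISION,
) -> ShiftAlignment:
    """Rebuild the alignment at a known position (e.g. read from a report)."""
    if position is None or delta_m == 0:
        return raw_alignment(bait_spectrum, hit_spectrum, delta_m, precision)
    entries = apply_shift(hit_spectrum, delta_m, position)
    groups = _match_groups(bait_spectrum, entries, precision)
    return ShiftAlignment(position, sum(g.count for g in groups), delta_m, groups)


def select_best_strategy2(
    candidates: Sequence[CandidatePSM],
    bait_spectra: Sequence[TheoreticalSpectrum],
    db_spectra: Sequence[TheoreticalSpectrum],
    precision: float = DEFAULT_PRECISION,
) -> list[BestPSM]:
    """Per bait, the candidate with maximal shift SPC (raw SPC when Δm = 0)."""
    best_psms = []
    for bait_id, cands in sorted(group_by_bait(candidates).items()):
        scored = []
        for c in cands:
            hit = db_spectra[c.hit_id]
            if c.delta_m == 0:
                alignment = None
                score = c.raw_spc
            else:
                alignment = best_shift(
                    bait_spectra[bait_id], hit, c.delta_m, precision
                )
                score = alignment.shift_spc
            scored.append((c, alignment, score))
        best_c, best_alignment, best_score = min(
            scored,
            key=lambda item: tie_break_key(
                item[2], item[0].delta_m,
                db_spectra[item[0].hit_id].peptide.origin,
                db_spectra[item[0].hit_id].sequence,
            ),
        )
        hit = db_spectra[best_c.hit_id]
        best_psms.append(
            BestPSM(
                bait_id=bait_id,
                hit_id=best_c.hit_id,
                bait_sequence=bait_spectra[bait_id].sequence,
                hit_sequence=hit.sequence,
                hit_origin=hit.peptide.origin,
                score=best_score,
                raw_spc=best_c.raw_spc,
                delta_m=best_c.delta_m,
                strategy=2,
                alignment=best_alignment,
            )
        )
    return best_psms
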