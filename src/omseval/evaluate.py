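"""Quality measures over best PSMs.

Four instruments, usable separately:

* target/decoy FDR — fraction of best PSMs whose hit is a decoy, over
  all best PSMs at or above a score cutoff — and the smallest cutoff
  reaching a requested FDR;
* the Δm sign grouping G1 (Δm = 0), G2 (Δm > 0), G3 (Δm < 0);
* the Green/Orange/Red classification: how hard it is to reconstruct the
  bait sequence from the hit sequence, Δm and the shift location —
  Green when one unambiguous editing operation explains Δm, Orange when
  the location is known but the edited content is ambiguous (e.g. a
  multi-residue insertion whose order is undetermined), Red otherwise
  (Δm = 0, edits at two or more separated locations, or no consistent
  explanation);
* LIPR (Low Information Peaks Rate): the fraction of a PSM's shared
  masses whose generating fragment subsequences differ, i.e. mass
  matches that carry no sequence evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .masses import (
    _SCALE,
    DEFAULT_PRECISION,
    residue_mass,
    residues_with_mass,
    sequence_units,
)
from .proteome import DECOY, TARGET
from .realign import ShiftAlignment, raw_alignment
from .search import BestPSM
from .spectra import Fragment, TheoreticalSpectrum

GREEN, ORANGE, RED = "Green", "Orange", "Red"
GROUPS = ("G1", "G2", "G3")
COLORS = (GREEN, ORANGE, RED)


def delta_m_group(delta_m: float) -> str:
    """G1 for Δm = 0 (exact), G2 for Δm > 0, G3 for Δm < 0."""
    if delta_m == 0:
        return "G1"
    return "G2" if delta_m > 0 else "G3"


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalRow:
    min_score: int
    counts: dict  # (group, origin) -> int
    total_target: int
    total_decoy: int
    fdr: Optional[float]  # fraction in [0, 1]; None when no PSM remains


def compute_fdr(best_psms: Sequence[BestPSM], min_score: int = 0) -> EvalRow:
    """Count PSMs with score ≥ min_score by Δm group and hit origin.

    FDR = #decoy / (#target + #decoy) over the retained PSMs.
    """
    counts = {(g, o): 0 for g in GROUPS for o in (TARGET, DECOY)}
    for psm in best_psms:
        if psm.score >= min_score:
            counts[(delta_m_group(psm.delta_m), psm.hit_origin)] += 1
    total_target = sum(counts[(g, TARGET)] for g in GROUPS)
    total_decoy = sum(counts[(g, DECOY)] for g in GROUPS)
    total = total_target + total_decoy
    fdr = total_decoy / total if total else None
    return EvalRow(min_score, counts, total_target, total_decoy, fdr)


def threshold_at_fdr(best_psms: Sequence[BestPSM], alpha: float = 0.01) -> Optional[int]:
    """Smallest score cutoff whose FDR is below alpha; None if unreachable."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for score in sorted({p.score for p in best_psms}):
        row = compute_fdr(best_psms, score)
        if row.fdr is not None and row.fdr < alpha:
            return score
    return None


# ---------------------------------------------------------------------------
# Green / Orange / Red classification
# ---------------------------------------------------------------------------

def _edit_runs(bait_seq: str, hit_seq: str) -> list[tuple[str, str]]:
    """Contested runs of a run-minimal optimal unit-cost alignment.

    Among all minimal-edit-distance alignments of bait vs hit, pick one
    with the fewest contiguous blocks of non-matching columns (an
    arbitrary optimal path can split one deletion into two blocks around
    a coincidentally matching residue). Each run is (bait content, hit
    content) of one block; the number of runs is the number of separated
    edit locations needed to turn the hit into the bait.
    """
    nb, nh = len(bait_seq), len(hit_seq)
    INF = (1 << 30, 1 << 30)
    # state: (bait prefix, hit prefix, last column was a difference?)
    value = {(0, 0, 0): (0, 0)}
    parent: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    for i in range(nb + 1):
        for j in range(nh + 1):
            for s in (0, 1):
                here = value.get((i, j, s), INF)
                if here == INF:
                    continue
                cost, runs = here
                moves = []
                if i < nb and j < nh and bait_seq[i] == hit_seq[j]:
                    moves.append(((i + 1, j + 1, 0), (cost, runs)))
                enter = runs + (1 - s)
                if i < nb and j < nh:
                    moves.append(((i + 1, j + 1, 1), (cost + 1, enter)))
                if i < nb:
                    moves.append(((i + 1, j, 1), (cost + 1, enter)))
                if j < nh:
                    moves.append(((i, j + 1, 1), (cost + 1, enter)))
                for state, val in moves:
                    if val < value.get(state, INF):
                        value[state] = val
                        parent[state] = (i, j, s)
    end = min(
        ((i, j, s) for (i, j, s) in ((nb, nh, 0), (nb, nh, 1))),
        key=lambda st: value.get(st, INF),
    )
    # walk back, grouping difference columns into runs
    runs_out: list[list[str]] = []
    state = end
    while state != (0, 0, 0):
        i, j, s = state
        pi, pj, _ = parent[state]
        if s == 1:
            if not runs_out or runs_out[-1][2] != "open":
                runs_out.append(["", "", "open"])
            runs_out[-1][0] = bait_seq[pi:i] + runs_out[-1][0]
            runs_out[-1][1] = hit_seq[pj:j] + runs_out[-1][1]
        else:
            if runs_out:
                runs_out[-1][2] = "closed"
        state = parent[state]
    runs_out.reverse()
    return [(b, h) for b, h, _ in runs_out]


def classify_color(
    bait_seq: str,
    hit_seq: str,
    delta_m: float,
    alignment: Optional[ShiftAlignment] = None,
    precision: float = DEFAULT_PRECISION,
) -> str:
    """Green/Orange/Red verdict for a best PSM.

    Green: the bait is recovered from the hit by exactly one editing
    operation that Δm determines without ambiguity — a single-residue
    insertion whose mass matches a unique residue letter, a contiguous
    deletion of mass |Δm| (content read off the hit), or a
    single-residue substitution with a unique replacement mass.
    Orange: one edit location, but ambiguous content (multi-residue
    insertion, I/L-degenerate residue, compound local edit).
    Red: Δm = 0, edits at two or more separated locations, or an edit
    inconsistent with Δm.

    The classification is sequence-driven; the Strategy2 alignment, when
    given, carries the same Δm and is accepted for interface symmetry.
    """
    if delta_m == 0:
        return RED
    runs = _edit_runs(bait_seq, hit_seq)
    if len(runs) != 1:
        return RED
    mid_b, mid_h = runs[0]
    delta_units = round(delta_m * _SCALE)
    tol_units = round(precision * _SCALE)
    if abs(sequence_units(mid_b) - sequence_units(mid_h) - delta_units) > tol_units:
        return RED
    if not mid_h:  # pure insertion into the hit
        if len(mid_b) == 1 and len(residues_with_mass(delta_m, precision)) == 1:
            return GREEN
        return ORANGE
    if not mid_b:  # pure deletion from the hit: content is read off the hit
        return GREEN
    if len(mid_b) == 1 and len(mid_h) == 1:  # substitution
        replacement_mass = residue_mass(mid_h) + delta_m
        if len(residues_with_mass(replacement_mass, precision)) == 1:
            return GREEN
        return ORANGE
    return ORANGE


# ---------------------------------------------------------------------------
# LIPR
# ---------------------------------------------------------------------------

def _common_suffix_len(a: str, b: str) -> int:
    n = 0
    while n < len(a) and n < len(b) and a[-1 - n] == b[-1 - n]:
        n += 1
    return n


def _shifted_concordant(
    bait_frag: Fragment,
    hit_frag: Fragment,
    position: int,
    delta_m: float,
    n_hit: int,
    precision: float,
) -> bool:
    """Does a shifted mass match carry consistent sequence evidence?

    The pair is concordant iff the bait fragment equals the hit fragment
    with an interval of mass Δm inserted (or excised) exactly at the
    alignment's shift boundary: the residues outside the boundary must
    agree and the contested interval's mass difference must be Δm.
    """
    ell = position - 1  # boundary sits after hit residue ell
    sb, sh = bait_frag.subsequence, hit_frag.subsequence
    cut = ell if hit_frag.ion_type == "b" else ell - (n_hit - len(sh))
    if cut < 0 or cut > len(sh) or cut > len(sb):
        return False
    if sb[:cut] != sh[:cut]:
        return False
    tail_b, tail_h = sb[cut:], sh[cut:]
    r = _common_suffix_len(tail_b, tail_h)
    mid_b = tail_b[: len(tail_b) - r]
    mid_h = tail_h[: len(tail_h) - r]
    diff = sequence_units(mid_b) - sequence_units(mid_h)
    return abs(diff - round(delta_m * _SCALE)) <= round(precision * _SCALE)


def lipr(
    bait_spectrum: TheoreticalSpectrum,
    hit_spectrum: TheoreticalSpectrum,
    alignment: Optional[ShiftAlignment] = None,
    precision: float = DEFAULT_PRECISION,
) -> float:
    """Low Information Peaks Rate of a PSM, in [0, 1].

    numerator: shared masses for which no pair of generating fragments
    is sequence-concordant; denominator: all shared masses. Unshifted
    pairs are concordant iff their subsequences are identical strings;
    shifted pairs follow the boundary-surgery rule above. When a shared
    mass is generated by several fragments on one side, one concordant
    pairing suffices to count its copies as informative.
    """
    if alignment is None:
        alignment = raw_alignment(
            bait_spectrum, hit_spectrum,
            bait_spectrum.peptide.mass - hit_spectrum.peptide.mass, precision,
        )
    n_hit = len(hit_spectrum.sequence)
    num = den = 0
    for group in alignment.matched:
        den += group.count
        concordant = False
        for bf in group.bait_fragments:
            for hf, _, shifted in group.hit_fragments:
                if shifted:
                    assert alignment.position is not None
                    if _shifted_concordant(
                        bf, hf, alignment.position, alignment.delta_m, n_hit, precision
                    ):
                        concordant = True
                elif bf.subsequence == hf.subsequence:
                    concordant = True
                if concordant:
                    break
            if concordant:
                break
        if not concordant:
            num += group.count
    if den == 0:
        raise ValueError("LIPR undefined: the PSM shares no masses")
    return num / den


# ---------------------------------------------------------------------------
# Per-PSM evaluation and report tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmEvaluation:
    psm: BestPSM
    color: str
    lipr: float
    group: str


def evaluate_psms(
    best_psms: Sequence[BestPSM],
    bait_spectra: Sequence[TheoreticalSpectrum],
    db_spectra: Sequence[TheoreticalSpectrum],
    precision: float = DEFAULT_PRECISION,
) -> list[PsmEvaluation]:
    """Color, LIPR and Δm group for every best PSM.

    Strategy2 PSMs with Δm ≠ 0 are evaluated under their recorded shift
    alignment; everything else under the raw (identity) alignment.
    """
    out = []
    for psm in best_psms:
        bait = bait_spectra[psm.bait_id]
        hit = db_spectra[psm.hit_id]
        alignment = psm.alignment
        if alignment is None:
            alignment = raw_alignment(bait, hit, psm.delta_m, precision)
        out.append(
            PsmEvaluation(
                psm=psm,
                color=classify_color(
                    psm.bait_sequence, psm.hit_sequence, psm.delta_m, alignment, precision
                ),
                lipr=lipr(bait, hit, alignment, precision),
                group=delta_m_group(psm.delta_m),
            )
        )
    return out


def evaluations_to_frame(evaluations: Sequence[PsmEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bait": [e.psm.bait_sequence for e in evaluations],
            "hit": [e.psm.hit_sequence for e in evaluations],
            "hit_origin": [e.psm.hit_origin for e in evaluations],
            "score": [e.psm.score for e in evaluations],
            "delta_m": [round(e.psm.delta_m, 5) for e in evaluations],
            "group": [e.group for e in evaluations],
            "color": [e.color for e in evaluations],
            "lipr": [round(e.lipr, 4) for e in evaluations],
        }
    )


def summarize_scores(
    best_psms: Sequence[BestPSM], min_scores: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """Score-threshold table: PSM counts per Δm group × origin, plus FDR (%)."""
    if min_scores is None:
        min_scores = sorted({p.score for p in best_psms})
    rows = []
    for s in min_scores:
        r = compute_fdr(best_psms, s)
        rows.append(
            {
                "min_score": s,
                "dm0_target": r.counts[("G1", TARGET)],
                "dm0_decoy": r.counts[("G1", DECOY)],
                "dmneg_target": r.counts[("G3", TARGET)],
                "dmneg_decoy": r.counts[("G3", DECOY)],
                "dmpos_target": r.counts[("G2", TARGET)],
                "dmpos_decoy": r.counts[("G2", DECOY)],
                "total_target": r.total_target,
                "total_decoy": r.total_decoy,
                "fdr_percent": round(100 * r.fdr, 2) if r.fdr is not None else None,
            }
        )
    return pd.DataFrame(rows)


def summarize_colors(
    evaluations: Sequence[PsmEvaluation], label: str = ""
) -> pd.DataFrame:
    """One row per dataset: color counts and mean LIPR (%), Table-3 shaped."""
    n = {c: sum(1 for e in evaluations if e.color == c) for c in COLORS}
    mean_lipr = (
        round(100 * sum(e.lipr for e in evaluations) / len(evaluations), 2)
        if evaluations else None
    )
    return pd.DataFrame(
        [
            {
                "dataset": label,
                "n_green": n[GREEN],
                "n_orange": n[ORANGE],
                "n_red": n[RED],
                "total": len(evaluations),
                "mean_lipr_percent": mean_lipr,
            }
        ]
    )


def strategy_specific_sets(
    best1: Sequence[BestPSM], best2: Sequence[BestPSM]
) -> tuple[list[BestPSM], list[BestPSM]]:
    """PSMs on which the two strategies disagree, keyed by bait.

    Returns (SS1, SS2): for every bait whose selected hit differs between
    the strategies, the Strategy1 PSM goes to SS1 and the Strategy2 PSM
    to SS2; both sets therefore have the same size.
    """
    by_bait2 = {p.bait_id: p for p in best2}
    ss1, ss2 = [], []
    for p1 in best1:
        p2 = by_bait2.get(p1.bait_id)
        if p2 is None:
            continue
        if (p1.hit_sequence, p1.hit_origin) != (p2.hit_sequence, p2.hit_origin):
            ss1.append(p1)
            ss2.append(p2)
    return ss1, ss2


def color_fraction_curves(evaluations: Sequence[PsmEvaluation]) -> pd.DataFrame:
    """Per score cutoff: color fractions and mean LIPR of retained PSMs."""
    rows = []
    for s in sorted({e.psm.score for e in evaluations}):
        kept = [e for e in evaluations if e.psm.score >= s]
        row = {"min_score": s, "n": len(kept)}
        for c in COLORS:
            row[f"frac_{c.lower()}"] = round(
                sum(1 for e in kept if e.color == c) / len(kept), 4
            )
        row["mean_lipr_percent"] = round(
            100 * sum(e.lipr for e in kept) / len(kept), 2
        )
        rows.append(row)
    return pd.DataFrame(rows)
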