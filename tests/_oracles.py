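"""Independent oracles used by the tests.

Everything here deliberately avoids the package's index / realignment /
matching code paths: spectra are rebuilt by direct enumeration, SPC by
all-pairs double loops, realignment by reconstructing the shifted
spectrum from scratch at every location, and reference masses come from
Biopython rather than the package's residue table.
"""

from collections import Counter

from Bio.SeqUtils import molecular_weight

from omseval.masses import MONOISOTOPIC, PROTON, WATER, discretize

BIO_WATER = molecular_weight("G", seq_type="protein", monoisotopic=True) - 57.02146


def bio_peptide_mass(sequence: str) -> float:
    """Monoisotopic peptide mass from Biopython (independent mass source)."""
    return molecular_weight(sequence.replace("I", "L"), seq_type="protein",
                            monoisotopic=True)


def naive_fragment_masses(sequence: str) -> list[tuple[str, int, float, str]]:
    """(ion, index, mass, subsequence) for b1..bn, y1..yn by direct summation."""
    n = len(sequence)
    out = []
    for i in range(1, n + 1):
        prefix, suffix = sequence[:i], sequence[n - i :]
        out.append(("b", i, sum(MONOISOTOPIC[a] for a in prefix) + PROTON, prefix))
        out.append(("y", i, sum(MONOISOTOPIC[a] for a in suffix) + WATER + PROTON, suffix))
    return out


def naive_keys(sequence: str, precision: float = 0.001) -> Counter:
    return Counter(discretize(m, precision) for _, _, m, _ in naive_fragment_masses(sequence))


def naive_spc(seq_a: str, seq_b: str, precision: float = 0.001) -> int:
    """Shared peaks count by brute-force multiset intersection."""
    return sum((naive_keys(seq_a, precision) & naive_keys(seq_b, precision)).values())


def naive_best_shift(bait_seq: str, hit_seq: str, delta_m: float,
                     precision: float = 0.001) -> tuple[int | None, int]:
    """Best (position, SPC) by rebuilding the shifted spectrum at every location."""
    bait_keys = naive_keys(bait_seq, precision)
    n = len(hit_seq)
    best_pos, best = None, naive_spc(bait_seq, hit_seq, precision)
    for pos in range(1, n + 2):
        keys = Counter()
        for ion, i, mass, _ in naive_fragment_masses(hit_seq):
            if (ion == "b" and i >= pos) or (ion == "y" and i >= n - pos + 1):
                mass += delta_m
            keys[discretize(mass, precision)] += 1
        spc = sum((bait_keys & keys).values())
        if spc > best:
            best, best_pos = spc, pos
    return best_pos, best


def naive_raw_lipr(bait_seq: str, hit_seq: str, precision: float = 0.001) -> float:
    """LIPR of the unshifted matching by exhaustive fragment comparison."""
    fa = naive_fragment_masses(bait_seq)
    fb = naive_fragment_masses(hit_seq)
    keys_a = naive_keys(bait_seq, precision)
    keys_b = naive_keys(hit_seq, precision)
    num = den = 0
    for key, mult in (keys_a & keys_b).items():
        subs_a = [s for _, _, m, s in fa if discretize(m, precision) == key]
        subs_b = [s for _, _, m, s in fb if discretize(m, precision) == key]
        den += mult
        if not any(sa == sb for sa in subs_a for sb in subs_b):
            num += mult
    return num / den


def has_mass_coincidence(alignment, bait_spectrum, hit_spectrum) -> bool:
    """Detect the mass coincidences that can break shift-SPC parity.

    Either spectrum containing two fragments with the same discretized
    mass, a shared mass generated by several fragments on one side, or a
    matched group pairing different ion-type multisets, all indicate a
    compositional coincidence rather than a clean b/y realignment.
    """
    for spectrum in (bait_spectrum, hit_spectrum):
        keys = spectrum.key_counter()
        if any(v > 1 for v in keys.values()):
            return True
    for group in alignment.matched:
        if len(group.bait_fragments) > 1 or len(group.hit_fragments) > 1:
            return True
        types_b = sorted(f.ion_type for f in group.bait_fragments)
        types_h = sorted(f.ion_type for f, _, _ in group.hit_fragments)
        if types_b != types_h:
            return True
    return False
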