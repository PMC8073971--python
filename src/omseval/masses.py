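"""Monoisotopic mass arithmetic and mass discretization.

All peptide and fragment masses in this package derive from the residue
table below. Sums are carried out internally in integer units of 1e-5 Da,
so that two peptides built from the same residue multiset have *exactly*
the same floating-point mass irrespective of residue order — the Δm = 0
group test relies on this.
"""

from __future__ import annotations

#: Monoisotopic residue masses (Da), 5 decimals. I and L share a mass.
MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Mass of a proton (Da); added to every singly charged fragment ion.
PROTON: float = 1.00728
#: Mass of a water molecule (Da); part of every intact peptide and y-ion.
WATER: float = 18.01056

#: Default mass discretization step (Da) used to decide "shared" masses.
DEFAULT_PRECISION: float = 0.001

CANONICAL_RESIDUES: frozenset[str] = frozenset(MONOISOTOPIC)

# integer representation: units of 1e-5 Da
_SCALE = 100_000
RESIDUE_UNITS: dict[str, int] = {
    aa: round(m * _SCALE) for aa, m in MONOISOTOPIC.items()
}
PROTON_UNITS: int = round(PROTON * _SCALE)
WATER_UNITS: int = round(WATER * _SCALE)


def residue_mass(residue: str) -> float:
    """Monoisotopic mass (Da) of a single residue letter."""
    try:
        return MONOISOTOPIC[residue]
    except KeyError:
        raise KeyError(f"unknown residue letter {residue!r}") from None


def sequence_units(sequence: str) -> int:
    """Sum of residue masses of ``sequence`` in integer 1e-5 Da units."""
    try:
        return sum(RESIDUE_UNITS[aa] for aa in sequence)
    except KeyError as exc:
        raise KeyError(f"unknown residue letter {exc.args[0]!r} in {sequence!r}") from None


def peptide_mass(sequence: str) -> float:
    """Monoisotopic mass (Da) of an intact peptide: residue sum + water."""
    return (sequence_units(sequence) + WATER_UNITS) / _SCALE


def units_to_da(units: int) -> float:
    return units / _SCALE


def discretize(mass: float, precision: float = DEFAULT_PRECISION) -> int:
    """Map a mass to its integer key; two masses are "shared" iff keys agree.

    key = round(mass / precision). With the default 0.001 Da step,
    exact-composition coincidences (GG vs N, GA vs Q, KE vs GVT) stay
    shared while anything differing by more than the step does not.
    """
    if precision <= 0:
        raise ValueError("precision must be > 0")
    return round(mass / precision)


def residues_with_mass(mass: float, tolerance: float = DEFAULT_PRECISION) -> list[str]:
    """Residue letters whose monoisotopic mass is within ``tolerance`` of ``mass``.

    Used to decide whether a single-residue edit deduced from Δm is
    unambiguous: I and L (and any residues closer than the tolerance)
    are returned together.
    """
    return [aa for aa, m in MONOISOTOPIC.items() if abs(m - mass) <= tolerance]
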