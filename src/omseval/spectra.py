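"""Annotated theoretical spectra: the b and y fragment ion series.

A peptide of length n yields exactly 2n singly protonated fragments —
b1..bn (N-terminal prefixes, residue sum + proton) and y1..yn
(C-terminal suffixes, residue sum + water + proton), full-length ions
included. Intensities are conceptually unit-valued and not stored; only
the multiset of (discretized) masses matters for the shared peaks count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Union

import pandas as pd

from .masses import (
    PROTON_UNITS,
    RESIDUE_UNITS,
    WATER_UNITS,
    DEFAULT_PRECISION,
    discretize,
    units_to_da,
)
from .proteome import Peptide


@dataclass(frozen=True)
class Fragment:
    ion_type: str  # 'b' or 'y'
    index: int  # 1..n
    mass: float  # Da, singly protonated
    subsequence: str  # generating prefix (b) or suffix (y)


@dataclass(frozen=True)
class TheoreticalSpectrum:
    peptide: Peptide
    fragments: tuple[Fragment, ...]
    _key_cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    def masses(self) -> list[float]:
        return [f.mass for f in self.fragments]

    def key_counter(self, precision: float = DEFAULT_PRECISION) -> Counter:
        """Multiset of discretized fragment masses (cached per precision)."""
        counter = self._key_cache.get(precision)
        if counter is None:
            counter = Counter(discretize(f.mass, precision) for f in self.fragments)
            self._key_cache[precision] = counter
        return counter


def generate_spectrum(peptide: Union[Peptide, str]) -> TheoreticalSpectrum:
    """Build the 2n-fragment theoretical spectrum of a peptide.

    Accepts a Peptide or a bare sequence string (wrapped into a target
    Peptide). Fragment masses are derived from exact integer residue-mass
    sums, so equal subsequence compositions give bitwise-equal masses.
    """
    if isinstance(peptide, str):
        peptide = Peptide.from_sequence(peptide)
    seq = peptide.sequence
    n = len(seq)
    units = [RESIDUE_UNITS[aa] for aa in seq]
    fragments = []
    acc = 0
    for i in range(1, n + 1):
        acc += units[i - 1]
        fragments.append(Fragment("b", i, units_to_da(acc + PROTON_UNITS), seq[:i]))
    acc = 0
    for i in range(1, n + 1):
        acc += units[n - i]
        fragments.append(
            Fragment("y", i, units_to_da(acc + WATER_UNITS + PROTON_UNITS), seq[n - i :])
        )
    return TheoreticalSpectrum(peptide, tuple(fragments))


def spectra_to_frame(spectra: Iterable[TheoreticalSpectrum]) -> pd.DataFrame:
    rows = [
        (s.sequence, f.ion_type, f.index, round(f.mass, 5), f.subsequence)
        for s in spectra
        for f in s.fragments
    ]
    return pd.DataFrame(rows, columns=["peptide", "ionType", "index", "mass", "subsequence"])
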