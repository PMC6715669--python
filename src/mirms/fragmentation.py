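"""Theoretical MS/MS fragment ladders for RNA oligonucleotides.

Backbone cleavage nomenclature follows the standard nucleic-acid ion series:
``a/b/c/d`` ions retain the 5' terminus, ``w/x/y/z`` ions retain the 3'
terminus.  For cleavage site ``i`` (between residues ``i`` and ``i+1``) the
neutral fragment masses are, with ``S_i`` the mass of the 5'-side i-mer
carrying the parent 5' terminus and a 3'-OH, and ``T_j`` the mass of the
3'-side j-mer carrying a 5'-OH and the parent 3' terminus::

    a_i = S_i - H2O          w_j = T_j + HPO3
    b_i = S_i                x_j = T_j + HPO3 - H2O
    c_i = S_i + HPO3 - H2O   y_j = T_j
    d_i = S_i + HPO3         z_j = T_j - H2O

``a-B`` is the ``a`` ion after neutral loss of the 3'-terminal nucleobase of
the fragment (including its methyl when that base is modified).

Default series for site localization are ``{c, y, w, a-B}`` — commonly
dominant for RNA in negative mode; the choice is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Sequence, Tuple

from .rna_mass import (
    HPO3,
    NUCLEOBASES,
    WATER,
    Oligo,
    composition,
    mass_of_composition,
    mz_from_mass,
)

__all__ = ["FragmentIon", "fragment_ladder", "SERIES_LABELS", "DEFAULT_SERIES"]

SERIES_LABELS: Tuple[str, ...] = ("a", "a-B", "b", "c", "d", "w", "x", "y", "z")
DEFAULT_SERIES: Tuple[str, ...] = ("c", "y", "w", "a-B")

_FIVE_PRIME_SERIES = {"a", "a-B", "b", "c", "d"}
_THREE_PRIME_SERIES = {"w", "x", "y", "z"}


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int  # 1-based cleavage count from the series' own terminus
    neutral_mass: float
    mz: float
    charge: int
    contains_positions: FrozenSet[int]  # 1-based sequence positions spanned

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}"


def _prefix_oligo(oligo: Oligo, i: int) -> Oligo:
    mods = [(p, m) for p, m in oligo.modifications if p <= i]
    return Oligo(oligo.sequence[:i], oligo.five_prime, "hydroxyl", mods)


def _suffix_oligo(oligo: Oligo, start: int) -> Oligo:
    # start is 1-based first retained position
    mods = [(p - start + 1, m) for p, m in oligo.modifications if p >= start]
    return Oligo(oligo.sequence[start - 1:], "hydroxyl", oligo.three_prime, mods)


def _series_neutral_mass(oligo: Oligo, series: str, index: int) -> float:
    n = len(oligo)
    if series in _FIVE_PRIME_SERIES:
        frag = _prefix_oligo(oligo, index)
        comp = composition(frag)
        if series == "a":
            comp = comp - WATER
        elif series == "a-B":
            comp = comp - WATER - NUCLEOBASES[frag.sequence[-1]]
            mod = frag.modification_at(len(frag))
            if mod is not None:
                comp = comp - mod.delta
        elif series == "c":
            comp = comp + HPO3 - WATER
        elif series == "d":
            comp = comp + HPO3
        # 'b' is the prefix itself
        return mass_of_composition(comp)
    frag = _suffix_oligo(oligo, n - index + 1)
    comp = composition(frag)
    if series == "w":
        comp = comp + HPO3
    elif series == "x":
        comp = comp + HPO3 - WATER
    elif series == "z":
        comp = comp - WATER
    # 'y' is the suffix itself
    return mass_of_composition(comp)


def fragment_ladder(
    oligo: Oligo,
    series: Iterable[str] = DEFAULT_SERIES,
    charges: Sequence[int] = (1,),
) -> List[FragmentIon]:
    """All fragment ions of the requested series, ordered (series, index, charge).

    For every series there are exactly ``len(oligo) - 1`` cleavage sites.
    Modification mass deltas are included iff the modified position lies in
    the fragment's span.
    """
    n = len(oligo)
    if n < 2:
        raise ValueError("fragmentation requires an oligo of length >= 2")
    series = list(series)
    unknown = set(series) - set(SERIES_LABELS)
    if unknown:
        raise ValueError(f"unknown ion series: {sorted(unknown)}")
    if any(not isinstance(z, int) or z < 1 for z in charges):
        raise ValueError("charges must be positive integers")

    ions: List[FragmentIon] = []
    for s in series:
        for i in range(1, n):
            neutral = _series_neutral_mass(oligo, s, i)
            if s in _FIVE_PRIME_SERIES:
                span = frozenset(range(1, i + 1))
            else:
                span = frozenset(range(n - i + 1, n + 1))
            for z in charges:
                ions.append(
                    FragmentIon(
                        series=s,
                        index=i,
                        neutral_mass=neutral,
                        mz=mz_from_mass(neutral, z),
                        charge=z,
                        contains_positions=span,
                    )
                )
    ions.sort(key=lambda f: (f.series, f.index, f.charge))
    return ions
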