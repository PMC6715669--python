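"""Elemental composition and mass computation for modified RNA oligonucleotides.

Conventions
-----------
* Sequences are strings over ``{A, C, G, U}``.
* Modification positions are **1-based from the 5' end**.
* Mature miRNAs default to a 5'-phosphate and a 3'-hydroxyl terminus.
* Only negative-ion m/z is supported (MALDI-TOF operated in negative mode).

The residue model treats every residue as a nucleoside-3'-monophosphate minus
water; the chain is closed with one water and then adjusted for terminal
chemistry.  Each methyl modification contributes exactly ``CH2``
(+14.01565 Da monoisotopic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Sequence, Tuple

__all__ = [
    "ElementalComposition",
    "Modification",
    "MODIFICATIONS",
    "Oligo",
    "IsotopeEnvelope",
    "composition",
    "mass",
    "mass_of_composition",
    "mz_from_mass",
    "neutral_from_mz",
    "isotope_envelope",
    "METHYL_SHIFT",
    "PROTON_MASS",
    "WATER_MONO",
    "ADDUCT_SHIFTS",
]

# ---------------------------------------------------------------------------
# Atomic data — single source of truth.
# Monoisotopic masses and isotopic abundances: IUPAC/CIAAW 2013 tables.
# Average (standard) atomic weights: IUPAC 2021 conventional values.
# ---------------------------------------------------------------------------

MONOISOTOPIC: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

AVERAGE: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
    "Na": 22.98976928,
    "K": 39.0983,
}

#: (isotope mass, abundance) per element, abundance-sorted by mass.
ISOTOPES: Dict[str, List[Tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.0141017778, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317, 0.00038), (17.999161, 0.00205)],
    "P": [(30.97376163, 1.0)],
    "Na": [(22.9897692809, 1.0)],
    "K": [(38.96370668, 0.932581), (39.96399848, 0.000117), (40.96182576, 0.067302)],
}

ELEMENTS: Tuple[str, ...] = ("C", "H", "N", "O", "P", "Na", "K")

PROTON_MASS = 1.007276466879  # CODATA
METHYL_SHIFT = MONOISOTOPIC["C"] + 2 * MONOISOTOPIC["H"]  # 14.01565 Da
WATER_MONO = 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]

#: Neutral-mass shifts of monovalent cation adducts (cation replaces a proton).
ADDUCT_SHIFTS: Dict[str, float] = {
    "Na": MONOISOTOPIC["Na"] - MONOISOTOPIC["H"],  # +21.98194
    "K": MONOISOTOPIC["K"] - MONOISOTOPIC["H"],  # +37.95588
}


class CompositionError(ValueError):
    """Raised for invalid elemental-composition arithmetic."""


@dataclass(frozen=True)
class ElementalComposition:
    """Immutable element → count mapping with element-wise arithmetic."""

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Dict[str, int] | Iterable[Tuple[str, int]] = ()):
        items = dict(counts)
        for el, n in items.items():
            if el not in ELEMENTS:
                raise CompositionError(f"unknown element {el!r}")
            if not isinstance(n, int) or n < 0:
                raise CompositionError(f"count for {el} must be a non-negative int, got {n!r}")
        clean = tuple((el, items[el]) for el in ELEMENTS if items.get(el, 0) > 0)
        object.__setattr__(self, "counts", clean)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        a, b = self.as_dict(), other.as_dict()
        return ElementalComposition({el: a.get(el, 0) + b.get(el, 0) for el in ELEMENTS})

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        a, b = self.as_dict(), other.as_dict()
        out = {}
        for el in ELEMENTS:
            n = a.get(el, 0) - b.get(el, 0)
            if n < 0:
                raise CompositionError(f"subtraction yields negative count for {el}")
            out[el] = n
        return ElementalComposition(out)

    def __mul__(self, n: int) -> "ElementalComposition":
        if not isinstance(n, int) or n < 0:
            raise CompositionError("multiplier must be a non-negative int")
        return ElementalComposition({el: c * n for el, c in self.counts})

    __rmul__ = __mul__

    def total_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def formula(self) -> str:
        return "".join(f"{el}{n}" for el, n in self.counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ElementalComposition({self.formula()})"


def _comp(**kw: int) -> ElementalComposition:
    return ElementalComposition(kw)


WATER = _comp(H=2, O=1)
HPO3 = _comp(H=1, P=1, O=3)
METHYL = _comp(C=1, H=2)  # CH2 net addition of a methyl group

# Nucleoside compositions (ribonucleosides).
_NUCLEOSIDES: Dict[str, ElementalComposition] = {
    "A": _comp(C=10, H=13, N=5, O=4),  # adenosine
    "C": _comp(C=9, H=13, N=3, O=5),  # cytidine
    "G": _comp(C=10, H=13, N=5, O=5),  # guanosine
    "U": _comp(C=9, H=12, N=2, O=6),  # uridine
}

#: Internal residue = nucleoside-3'-monophosphate minus water.
RESIDUES: Dict[str, ElementalComposition] = {
    b: ns + HPO3 - WATER for b, ns in _NUCLEOSIDES.items()
}

#: Neutral nucleobase compositions (for a-B base-loss fragments).
NUCLEOBASES: Dict[str, ElementalComposition] = {
    "A": _comp(C=5, H=5, N=5),  # adenine
    "C": _comp(C=4, H=5, N=3, O=1),  # cytosine
    "G": _comp(C=5, H=5, N=5, O=1),  # guanine
    "U": _comp(C=4, H=4, N=2, O=2),  # uracil
}


@dataclass(frozen=True)
class Modification:
    """A methyl modification of a specific nucleobase.

    ``blocks_adenine_n1`` marks modifications occupying adenine N1 (inert to
    dimethyl-sulfate alkylation); ``hydrazine_protective`` marks cytosine
    methylation that resists hydrazine cleavage.
    """

    identifier: str
    parent_base: str
    delta: ElementalComposition = field(default=METHYL)
    blocks_adenine_n1: bool = False
    hydrazine_protective: bool = False

    def __post_init__(self) -> None:
        if self.parent_base not in ("A", "C"):
            raise ValueError(f"unsupported parent base {self.parent_base!r}")
        if self.delta != METHYL:
            raise ValueError("methyl modifications must add exactly CH2")


MODIFICATIONS: Dict[str, Modification] = {
    "m6A": Modification("m6A", "A"),
    "m1A": Modification("m1A", "A", blocks_adenine_n1=True),
    "m5C": Modification("m5C", "C", hydrazine_protective=True),
    "m3C": Modification("m3C", "C"),
}

FivePrime = Literal["phosphate", "hydroxyl"]
ThreePrime = Literal["hydroxyl", "phosphate", "cyclic-phosphate"]


@dataclass(frozen=True)
class Oligo:
    """A (possibly methylated) RNA oligonucleotide.

    Parameters
    ----------
    sequence : str
        Over ``{A, C, G, U}``; length >= 1.
    five_prime, three_prime : str
        Terminal chemistry.  Defaults match mature miRNAs
        (5'-phosphate / 3'-hydroxyl).
    modifications : sequence of (position, Modification or identifier)
        Positions are 1-based from the 5' end; at most one per position; the
        modification's parent base must match the sequence.
    """

    sequence: str
    five_prime: FivePrime = "phosphate"
    three_prime: ThreePrime = "hydroxyl"
    modifications: Tuple[Tuple[int, Modification], ...] = ()

    def __init__(
        self,
        sequence: str,
        five_prime: FivePrime = "phosphate",
        three_prime: ThreePrime = "hydroxyl",
        modifications: Sequence[Tuple[int, Modification | str]] = (),
    ):
        sequence = str(sequence).upper().replace("T", "U")
        if len(sequence) < 1:
            raise ValueError("sequence must have length >= 1")
        bad = set(sequence) - set("ACGU")
        if bad:
            raise ValueError(f"invalid residue character(s): {sorted(bad)}")
        if five_prime not in ("phosphate", "hydroxyl"):
            raise ValueError(f"invalid 5' terminus {five_prime!r}")
        if three_prime not in ("hydroxyl", "phosphate", "cyclic-phosphate"):
            raise ValueError(f"invalid 3' terminus {three_prime!r}")
        mods: List[Tuple[int, Modification]] = []
        seen: set[int] = set()
        for pos, mod in modifications:
            if isinstance(mod, str):
                try:
                    mod = MODIFICATIONS[mod]
                except KeyError:
                    raise ValueError(f"unknown modification {mod!r}") from None
            if not 1 <= pos <= len(sequence):
                raise ValueError(f"modification position {pos} outside [1, {len(sequence)}]")
            if pos in seen:
                raise ValueError(f"multiple modifications at position {pos}")
            if sequence[pos - 1] != mod.parent_base:
                raise ValueError(
                    f"{mod.identifier} requires {mod.parent_base} at position {pos}, "
                    f"found {sequence[pos - 1]}"
                )
            seen.add(pos)
            mods.append((pos, mod))
        mods.sort(key=lambda pm: pm[0])
        object.__setattr__(self, "sequence", sequence)
        object.__setattr__(self, "five_prime", five_prime)
        object.__setattr__(self, "three_prime", three_prime)
        object.__setattr__(self, "modifications", tuple(mods))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def modified_positions(self) -> Tuple[int, ...]:
        return tuple(p for p, _ in self.modifications)

    def modification_at(self, position: int) -> Modification | None:
        for p, m in self.modifications:
            if p == position:
                return m
        return None

    def with_modifications(
        self, modifications: Sequence[Tuple[int, Modification | str]]
    ) -> "Oligo":
        return Oligo(self.sequence, self.five_prime, self.three_prime, modifications)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Unit-mass-aggregated isotope distribution."""

    peaks: Tuple[Tuple[float, float], ...]  # (mass Da, abundance), mass ascending
    truncation: float

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("envelope masses must be strictly increasing")
        if any(not 0.0 < p <= 1.0 for _, p in self.peaks):
            raise ValueError("abundances must lie in (0, 1]")
        if sum(p for _, p in self.peaks) < 1.0 - self.truncation - 1e-12:
            raise ValueError("envelope abundance below truncation contract")

    @property
    def monoisotopic_mass(self) -> float:
        return self.peaks[0][0]

    def abundance_near(self, mass: float, tol: float = 0.3) -> float:
        """Summed abundance of envelope peaks within ``tol`` Da of ``mass``."""
        return sum(p for m, p in self.peaks if abs(m - mass) <= tol)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def composition(oligo: Oligo) -> ElementalComposition:
    """Elemental composition of a modified oligo (neutral molecule)."""
    total = WATER
    for base in oligo.sequence:
        total = total + RESIDUES[base]
    if oligo.five_prime == "hydroxyl":
        total = total - HPO3
    if oligo.three_prime == "phosphate":
        total = total + HPO3
    elif oligo.three_prime == "cyclic-phosphate":
        total = total + HPO3 - WATER
    for _, mod in oligo.modifications:
        total = total + mod.delta
    return total


def mass_of_composition(
    comp: ElementalComposition, kind: Literal["monoisotopic", "average"] = "monoisotopic"
) -> float:
    table = {"monoisotopic": MONOISOTOPIC, "average": AVERAGE}.get(kind)
    if table is None:
        raise ValueError(f"kind must be 'monoisotopic' or 'average', got {kind!r}")
    return sum(n * table[el] for el, n in comp.counts)


def mass(oligo: Oligo, kind: Literal["monoisotopic", "average"] = "monoisotopic") -> float:
    """Neutral mass of the oligo in Da."""
    return mass_of_composition(composition(oligo), kind)


def mz_from_mass(neutral_mass: float, charge: int, polarity: str = "negative") -> float:
    """m/z of the ``[M - zH]^(z-)`` ion."""
    if polarity != "negative":
        raise ValueError("only negative-ion mode is supported")
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (neutral_mass - charge * PROTON_MASS) / charge


def neutral_from_mz(mz: float, charge: int, polarity: str = "negative") -> float:
    """Inverse of :func:`mz_from_mass`."""
    if polarity != "negative":
        raise ValueError("only negative-ion mode is supported")
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return mz * charge + charge * PROTON_MASS


def _single_atom_dist(element: str) -> Dict[int, Tuple[float, float]]:
    iso = ISOTOPES[element]
    base = round(iso[0][0])
    return {round(m) - base: (p, m) for m, p in iso}


def _convolve(
    a: Dict[int, Tuple[float, float]], b: Dict[int, Tuple[float, float]], prune: float
) -> Dict[int, Tuple[float, float]]:
    out: Dict[int, List[float]] = {}
    for oa, (pa, ma) in a.items():
        for ob, (pb, mb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            acc = out.setdefault(oa + ob, [0.0, 0.0])
            acc[0] += p
            acc[1] += p * (ma + mb)
    return {o: (p, wm / p) for o, (p, wm) in out.items()}


def _element_power(
    element: str, n: int, prune: float
) -> Dict[int, Tuple[float, float]]:
    # exponentiation by squaring over nucleon-offset convolution
    result: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    base = _single_atom_dist(element)
    while n:
        if n & 1:
            result = _convolve(result, base, prune)
        n >>= 1
        if n:
            base = _convolve(base, base, prune)
    return result


def isotope_envelope(
    comp: ElementalComposition, truncation: float = 1e-4
) -> IsotopeEnvelope:
    """Isotope envelope aggregated by nucleon count (unit-mass binning).

    Sufficient at MALDI-TOF resolution; deterministic for fixed inputs.
    """
    if not 0.0 < truncation <= 0.01:
        raise ValueError("truncation must lie in (0, 0.01]")
    if comp.total_atoms() == 0:
        raise ValueError("empty composition has no isotope envelope")
    prune = truncation * 1e-9
    dist: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    for el, n in comp.counts:
        dist = _convolve(dist, _element_power(el, n, prune), prune)
    peaks = sorted((m, p) for _, (p, m) in dist.items())
    # drop the least-abundant tail while staying within the truncation budget
    total = sum(p for _, p in peaks)
    budget = total - (1.0 - truncation)
    keep = []
    for m, p in sorted(peaks, key=lambda mp: mp[1]):
        if p <= budget:
            budget -= p
        else:
            keep.append((m, p))
    keep.sort()
    return IsotopeEnvelope(tuple(keep), truncation)
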