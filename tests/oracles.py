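"""Independent brute-force oracles used to validate library computations.

Everything here is derived from first principles (literal structural
formulas, exhaustive enumeration, pairwise counting) and deliberately does
not reuse the library's internals beyond its public data types.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Dict, List, Mapping, Sequence, Tuple

# Independent copy of atomic data (IUPAC/CIAAW).
ATOMIC_MONO = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

# Molecular formulas of the four ribonucleosides, written out literally.
NUCLEOSIDE_FORMULAS: Dict[str, Dict[str, int]] = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 4},
    "C": {"C": 9, "H": 13, "N": 3, "O": 5},
    "G": {"C": 10, "H": 13, "N": 5, "O": 5},
    "U": {"C": 9, "H": 12, "N": 2, "O": 6},
}

HPO3 = {"H": 1, "P": 1, "O": 3}
H2O = {"H": 2, "O": 1}
CH2 = {"C": 1, "H": 2}


def formula_add(*formulas: Mapping[str, int], scale: Sequence[int] | None = None) -> Dict[str, int]:
    total: Counter = Counter()
    scales = scale or [1] * len(formulas)
    for f, s in zip(formulas, scales):
        for el, n in f.items():
            total[el] += s * n
    return {el: n for el, n in total.items() if n != 0}


def formula_mass(formula: Mapping[str, int]) -> float:
    return sum(n * ATOMIC_MONO[el] for el, n in formula.items())


def oligo_formula(
    sequence: str,
    five_prime: str = "phosphate",
    three_prime: str = "hydroxyl",
    n_methyl: int = 0,
) -> Dict[str, int]:
    """Structural-formula oligo composition, built bond by bond.

    n nucleosides joined by (n-1) phosphodiester bonds (each bond:
    +HPO3 - H2O), plus terminal groups: 5'-phosphate is a monoester
    (+HPO3); 3'-phosphate likewise; 3'-cyclic phosphate is the diester
    (+HPO3 - H2O).  Each methyl adds CH2.
    """
    n = len(sequence)
    total: Counter = Counter()
    for base in sequence:
        total.update(NUCLEOSIDE_FORMULAS[base])
    for _ in range(n - 1):  # internal phosphodiester bonds
        total.update(HPO3)
        total.subtract(H2O)
    if five_prime == "phosphate":
        total.update(HPO3)
    if three_prime == "phosphate":
        total.update(HPO3)
    elif three_prime == "cyclic-phosphate":
        total.update(HPO3)
        total.subtract(H2O)
    for _ in range(n_methyl):
        total.update(CH2)
    return {el: c for el, c in total.items() if c != 0}


def oligo_mass(sequence: str, five_prime: str = "phosphate",
               three_prime: str = "hydroxyl", n_methyl: int = 0) -> float:
    return formula_mass(oligo_formula(sequence, five_prime, three_prime, n_methyl))


def enumerate_isotopologues(
    composition: Mapping[str, int],
    isotopes: Mapping[str, Sequence[Tuple[float, float]]],
) -> List[Tuple[float, float]]:
    """Exhaustive isotopologue enumeration aggregated by nucleon count.

    Feasible only for tiny compositions (<= ~8 atoms).
    """
    atoms: List[Sequence[Tuple[float, float]]] = []
    for el, n in composition.items():
        atoms.extend([isotopes[el]] * n)
    bins: Dict[int, Tuple[float, float]] = {}
    for combo in itertools.product(*atoms):
        mass = sum(m for m, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        key = round(mass)
        acc = bins.get(key, (0.0, 0.0))
        bins[key] = (acc[0] + prob, acc[1] + prob * mass)
    return sorted((wm / p, p) for p, wm in bins.values())


def pairwise_auc(cases: Sequence[float], controls: Sequence[float]) -> float:
    """Brute-force AUC: fraction of case/control pairs correctly ordered,
    ties counting one half."""
    wins = 0.0
    for x in cases:
        for y in controls:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(cases) * len(controls))
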