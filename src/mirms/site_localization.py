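"""Methylation-site assignment from MS/MS ladders and derivatization logic.

Site localization places the methyl at every legal position, generates the
theoretical fragment ladder for each placement, and scores placements by
matched fragments that discriminate between placements (supporting minus
contradicting counts).  Ties produce an ambiguity set.  The score is a
fragment count, not a probability — likelihood-based scoring is an
extension point.

Two derivatization assays type the modification:

* Hydrazine cleaves RNA at every cytosine; m5C resists cleavage, so the
  cleavage-product mass pattern reveals which cytosines are methylated.
* Dimethyl sulfate (DMS) alkylates adenine N1.  Under a complete-reaction
  model a sequence with ``nA`` adenines gains ``nA x 14.01565`` Da when the
  unknown methyl is m6A (all N1 free) but only ``(nA - 1) x 14.01565`` when
  it is m1A (its own N1 blocked).  DMS reactivity toward guanine N7 is
  ignored (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from .fragmentation import DEFAULT_SERIES, fragment_ladder
from .rna_mass import METHYL_SHIFT, Modification, MODIFICATIONS, Oligo, mass
from .spectra_io import PeakList

__all__ = [
    "SiteAssignment",
    "localize",
    "hydrazine_cleavage_pattern",
    "classify_adenine_methylation",
]


@dataclass(frozen=True)
class SiteAssignment:
    position: int
    modification: str
    score: int  # supporting minus contradicting matched-fragment count
    supporting: int
    contradicting: int
    ambiguity_set: FrozenSet[int]  # positions tied at the top score


def _matched_ion_keys(
    oligo_with_mod: Oligo,
    peaks_mz,
    series: Iterable[str],
    tol_ppm: float,
) -> Dict[Tuple[str, int], float]:
    """(series, index) -> theoretical m/z, restricted to ions matched by a peak."""
    out: Dict[Tuple[str, int], float] = {}
    for ion in fragment_ladder(oligo_with_mod, series=series):
        tol = ion.mz * tol_ppm * 1e-6
        for mz in peaks_mz:
            if abs(mz - ion.mz) <= tol:
                out[(ion.series, ion.index)] = ion.mz
                break
    return out


def localize(
    msms: PeakList,
    oligo: Oligo,
    mod: Modification | str,
    tol_ppm: float = 100.0,
    series: Iterable[str] = DEFAULT_SERIES,
) -> List[SiteAssignment]:
    """Rank candidate methylation positions by discriminating-fragment score.

    ``oligo`` is the unmodified sequence; candidates are every position whose
    base matches the modification's parent base.  For each candidate
    placement the theoretical ladder is matched against the MS/MS peaks
    within ``tol_ppm``.  An ion supports a placement when it is matched
    under that placement but at least one alternative placement fails to
    explain it; it contradicts the placement when only alternative
    placements explain it.  Score = supporting - contradicting.
    """
    if isinstance(mod, str):
        mod = MODIFICATIONS[mod]
    candidates = [
        i + 1 for i, b in enumerate(oligo.sequence) if b == mod.parent_base
    ]
    if not candidates:
        raise ValueError(
            f"sequence has no {mod.parent_base} residue; no legal site for {mod.identifier}"
        )
    peaks_mz = [p.mz for p in msms]
    matched: Dict[int, Set[Tuple[str, int]]] = {}
    for p in candidates:
        placed = oligo.with_modifications([(p, mod)])
        matched[p] = set(_matched_ion_keys(placed, peaks_mz, series, tol_ppm))

    assignments: List[SiteAssignment] = []
    scores: Dict[int, Tuple[int, int]] = {}
    for p in candidates:
        others_union: Set[Tuple[str, int]] = set()
        others_inter: Set[Tuple[str, int]] | None = None
        for q in candidates:
            if q == p:
                continue
            others_union |= matched[q]
            others_inter = (
                set(matched[q]) if others_inter is None else others_inter & matched[q]
            )
        if others_inter is None:  # single candidate
            others_inter = set(matched[p])
        # supporting: matched ions some alternative placement fails to explain
        supporting = len(matched[p] - others_inter)
        # contradicting: ions explained only by alternative placements
        contradicting = len(others_union - matched[p])
        scores[p] = (supporting, contradicting)

    top = max(s - c for s, c in scores.values())
    ambiguity = frozenset(p for p, (s, c) in scores.items() if s - c == top)
    for p in candidates:
        s, c = scores[p]
        assignments.append(
            SiteAssignment(p, mod.identifier, s - c, s, c, ambiguity)
        )
    assignments.sort(key=lambda a: (-a.score, a.position))
    return assignments


def hydrazine_cleavage_pattern(
    oligo: Oligo, protected_positions: Iterable[int] = ()
) -> List[float]:
    """Expected neutral product masses after hydrazine treatment.

    Hydrazine excises every unprotected cytosine and cleaves the backbone
    there; m5C positions (``protected_positions``) survive.  The upstream
    product of each cleavage carries a 3'-phosphate and the downstream
    product a 5'-phosphate (aniline-strand-scission convention); terminal
    segments keep the parent termini on their outer ends.  Masses are
    returned sorted ascending.  When the oligo already carries m5C
    modifications those positions are implicitly protected.
    """
    protected = set(protected_positions) | {
        p for p, m in oligo.modifications if m.hydrazine_protective
    }
    n = len(oligo)
    for p in protected:
        if not 1 <= p <= n or oligo.sequence[p - 1] != "C":
            raise ValueError(f"protected position {p} is not a cytosine")
    cleave = [
        i + 1
        for i, b in enumerate(oligo.sequence)
        if b == "C" and (i + 1) not in protected
    ]
    if not cleave:
        return [mass(oligo)]
    masses: List[float] = []
    bounds = [0] + cleave + [n + 1]
    for left, right in zip(bounds[:-1], bounds[1:]):
        start, stop = left + 1, right - 1  # excised C removed
        if start > stop:
            continue
        five = oligo.five_prime if left == 0 else "phosphate"
        three = oligo.three_prime if right == n + 1 else "phosphate"
        mods = [
            (p - start + 1, m)
            for p, m in oligo.modifications
            if start <= p <= stop
        ]
        masses.append(mass(Oligo(oligo.sequence[start - 1:stop], five, three, mods)))
    return sorted(masses)


def classify_adenine_methylation(
    oligo: Oligo, observed_post_dms_shift: float, tol: float = 0.5
) -> str:
    """Type an adenine methyl as m6A or m1A from the post-DMS mass shift.

    Assumes a complete DMS reaction: every adenine with a free N1 gains one
    methyl.  With ``nA`` adenines, m6A predicts a shift of ``nA x 14.01565``
    Da and m1A predicts ``(nA - 1) x 14.01565`` Da.  Returns
    ``"undetermined"`` when the observed shift matches neither hypothesis
    within ``tol`` (or both, possible only for tol >= half a methyl).
    """
    n_a = oligo.sequence.count("A")
    if n_a == 0:
        raise ValueError("sequence contains no adenine")
    shift_m6a = n_a * METHYL_SHIFT
    shift_m1a = (n_a - 1) * METHYL_SHIFT
    hit_m6a = abs(observed_post_dms_shift - shift_m6a) <= tol
    hit_m1a = abs(observed_post_dms_shift - shift_m1a) <= tol
    if hit_m6a and not hit_m1a:
        return "m6A"
    if hit_m1a and not hit_m6a:
        return "m1A"
    return "undetermined"
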