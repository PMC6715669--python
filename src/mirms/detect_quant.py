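"""Intact-species peak matching and methylation-stoichiometry estimation.

A methylated miRNA appears as a ladder of peaks spaced +14.01565 Da
(one spacing per methyl group) above the unmethylated species, optionally
accompanied by Na/K adduct satellites.  The methylation fraction is the
methylated share of total matched intensity, ``sum_{k>=1} I_k / sum_k I_k``;
when no methylated species is detected the fraction is reported as 0 with a
below-detection flag.

Calibration against synthetic standard mixtures corrects for differential
ionization efficiency of methylated vs non-methylated oligos.  The fit is
linear in odds space (measured odds = response_factor x true odds), so the
fitted slope is the relative response factor of the methylated species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .rna_mass import (
    ADDUCT_SHIFTS,
    METHYL_SHIFT,
    IsotopeEnvelope,
    Oligo,
    mass,
    mz_from_mass,
    neutral_from_mz,
)
from .spectra_io import Peak, PeakList

__all__ = [
    "SpeciesPrediction",
    "SpeciesMatch",
    "MethylationFraction",
    "CalibrationCurve",
    "predict_species",
    "match_species",
    "methylation_fraction",
    "fit_calibration",
    "apply_calibration",
    "isotope_overlap_correction",
    "DEFAULT_TOL_PPM",
]

DEFAULT_TOL_PPM = 50.0


@dataclass(frozen=True)
class SpeciesPrediction:
    mirna_id: str
    k: int  # methyl count
    adduct: str  # "none" | "Na" | "K"
    neutral_mass: float
    mz: float  # charge 1, negative mode

    @property
    def label(self) -> str:
        ad = "" if self.adduct == "none" else f"+{self.adduct}"
        return f"{self.mirna_id}[{self.k}Me]{ad}"


@dataclass(frozen=True)
class SpeciesMatch:
    prediction: SpeciesPrediction
    peak: Optional[Peak]
    ppm_error: Optional[float]
    accepted: bool

    @property
    def intensity(self) -> float:
        return self.peak.intensity if (self.accepted and self.peak) else 0.0


@dataclass(frozen=True)
class MethylationFraction:
    mirna_id: str
    fraction: float
    per_k_intensity: Tuple[Tuple[int, float], ...]
    below_detection: bool


@dataclass(frozen=True)
class CalibrationCurve:
    """Fit of measured vs known methylated fraction for standard mixtures."""

    points: Tuple[Tuple[float, float], ...]  # (known fraction, measured fraction)
    slope: float  # relative response factor of the methylated species
    intercept: float
    residuals: Tuple[float, ...]  # measured - predicted, fraction scale


def predict_species(
    oligo: Oligo,
    kmax: int,
    adducts: Iterable[str] = (),
    mirna_id: str = "",
) -> List[SpeciesPrediction]:
    """Predicted intact species for 0..kmax methyl groups and cation adducts.

    Methyl masses are positional-composition-independent (+CH2 each), so
    predictions do not require knowing where the methyls sit.
    """
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    n_sites = sum(oligo.sequence.count(b) for b in "AC")
    if kmax > n_sites:
        raise ValueError(
            f"kmax={kmax} exceeds the {n_sites} methylatable (A/C) residues"
        )
    adducts = list(adducts)
    for ad in adducts:
        if ad not in ADDUCT_SHIFTS:
            raise ValueError(f"unknown adduct {ad!r}")
    base = mass(oligo)
    preds = []
    for k in range(kmax + 1):
        for ad in ["none"] + adducts:
            m = base + k * METHYL_SHIFT + (ADDUCT_SHIFTS[ad] if ad != "none" else 0.0)
            preds.append(
                SpeciesPrediction(mirna_id, k, ad, m, mz_from_mass(m, 1))
            )
    return preds


def match_species(
    pl: PeakList,
    predictions: Sequence[SpeciesPrediction],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> List[SpeciesMatch]:
    """Assign observed peaks to predicted species within a ppm tolerance.

    Each peak satisfies at most one prediction and vice versa: candidate
    pairs are ranked by absolute ppm error with ties broken toward lower
    methyl count, then assigned greedily.  Unmatched predictions are
    returned with ``accepted=False``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not predictions:
        raise ValueError("prediction list is empty")
    candidates = []
    for pi, pred in enumerate(predictions):
        for qi, peak in enumerate(pl):
            ppm = (peak.mz - pred.mz) / pred.mz * 1e6
            if abs(ppm) <= tol_ppm:
                candidates.append((abs(ppm), pred.k, pi, qi, ppm))
    candidates.sort()
    used_pred: set[int] = set()
    used_peak: set[int] = set()
    assigned: Dict[int, Tuple[int, float]] = {}
    for _, _, pi, qi, ppm in candidates:
        if pi in used_pred or qi in used_peak:
            continue
        used_pred.add(pi)
        used_peak.add(qi)
        assigned[pi] = (qi, ppm)
    out = []
    peaks = list(pl)
    for pi, pred in enumerate(predictions):
        if pi in assigned:
            qi, ppm = assigned[pi]
            out.append(SpeciesMatch(pred, peaks[qi], ppm, True))
        else:
            out.append(SpeciesMatch(pred, None, None, False))
    return out


def methylation_fraction(
    matches: Sequence[SpeciesMatch],
    snr_floor: float = 0.0,
    corrected_intensities: Optional[Sequence[float]] = None,
) -> MethylationFraction:
    """Methylated intensity share from accepted species matches.

    Intensities are summed per methyl count k across adducts.  A methylated
    match counts as detected when its peak SNR (if recorded) is at least
    ``snr_floor``; when no methylated species is detected the fraction is 0
    with ``below_detection`` set.  If the k=0 species is absent but
    methylated species are present the fraction is 1.
    """
    if not any(m.prediction.k == 0 for m in matches):
        raise ValueError("the k=0 (unmethylated) species must be among the predictions")
    if corrected_intensities is not None and len(corrected_intensities) != len(matches):
        raise ValueError("corrected_intensities must align with matches")
    if not any(m.accepted for m in matches):
        raise ValueError("no accepted matches; fraction undefined")

    per_k: Dict[int, float] = {}
    methylated_detected = False
    for i, m in enumerate(matches):
        if not m.accepted:
            continue
        inten = (
            float(corrected_intensities[i])
            if corrected_intensities is not None
            else m.intensity
        )
        if inten <= 0:
            continue
        snr_ok = m.peak.snr is None or m.peak.snr >= snr_floor
        if m.prediction.k >= 1:
            if not snr_ok:
                continue
            methylated_detected = True
        per_k[m.prediction.k] = per_k.get(m.prediction.k, 0.0) + inten

    mirna_id = matches[0].prediction.mirna_id
    shares = tuple(sorted(per_k.items()))
    if not methylated_detected:
        return MethylationFraction(mirna_id, 0.0, shares, below_detection=True)
    total = sum(per_k.values())
    methylated = sum(v for k, v in per_k.items() if k >= 1)
    return MethylationFraction(mirna_id, methylated / total, shares, False)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_ODDS_CAP = 1e12


def _odds(f: float) -> float:
    f = min(max(f, 0.0), 1.0)
    if f >= 1.0:
        return _ODDS_CAP
    return f / (1.0 - f)


def _from_odds(o: float) -> float:
    o = max(o, 0.0)
    return o / (1.0 + o)


def fit_calibration(
    points: Sequence[Tuple[float, float]]
) -> CalibrationCurve:
    """Least-squares fit of measured vs known methylated fraction.

    Each point is (known molar fraction, measured fraction).  Fitting in
    odds space makes the slope the relative ionization response factor of
    the methylated species; a factor of 1 gives the identity curve.
    """
    if len(points) < 2:
        raise ValueError("at least 2 calibration points are required")
    x = np.array([_odds(p[0]) for p in points])
    y = np.array([_odds(p[1]) for p in points])
    if np.ptp(x) <= 0:
        raise ValueError("calibration points must span >= 2 distinct known fractions")
    # relative (1/x^2-weighted) least squares: intensity noise is
    # multiplicative, so odds errors scale with the odds themselves
    w = 1.0 / np.maximum(x, 1e-9) ** 2
    design = np.vstack([x, np.ones_like(x)]).T
    slope, intercept = np.linalg.solve(
        design.T @ (w[:, None] * design), design.T @ (w * y)
    )
    if slope <= 0:
        raise ValueError("non-positive calibration slope; curve is not monotone")
    predicted = [_from_odds(slope * xi + intercept) for xi in x]
    residuals = tuple(float(p[1] - pf) for p, pf in zip(points, predicted))
    return CalibrationCurve(tuple((float(a), float(b)) for a, b in points),
                            float(slope), float(intercept), residuals)


def apply_calibration(curve: CalibrationCurve, raw_fraction: float) -> float:
    """Invert the calibration: raw measured fraction -> corrected fraction in [0,1]."""
    if raw_fraction >= 1.0:
        return 1.0
    corrected_odds = (_odds(raw_fraction) - curve.intercept) / curve.slope
    return min(max(_from_odds(corrected_odds), 0.0), 1.0)


# ---------------------------------------------------------------------------
# Isotope-envelope overlap correction
# ---------------------------------------------------------------------------


def isotope_overlap_correction(
    matches: Sequence[SpeciesMatch],
    envelopes: Mapping[Tuple[int, str], IsotopeEnvelope],
    bin_tol: float = 0.3,
) -> List[float]:
    """Subtract each species' isotope-envelope tail from the next species up.

    ``envelopes`` maps (k, adduct) to the species envelope.  Returns corrected
    intensities aligned with ``matches`` (clamped at 0).  At 14 Da spacing and
    MALDI-scale envelopes the correction is ~0; it matters only when envelopes
    are broad enough to reach the next species' matched position.
    """
    corrected = [m.intensity for m in matches]
    by_key = {
        (m.prediction.k, m.prediction.adduct): i
        for i, m in enumerate(matches)
        if m.accepted
    }
    for (k, ad), i in sorted(by_key.items()):
        nxt = by_key.get((k + 1, ad))
        if nxt is None:
            continue
        env = envelopes.get((k, ad))
        if env is None:
            continue
        donor = matches[i]
        acceptor = matches[nxt]
        own = env.abundance_near(neutral_from_mz(donor.peak.mz, 1), bin_tol)
        if own <= 0:
            continue
        spill = env.abundance_near(neutral_from_mz(acceptor.peak.mz, 1), bin_tol)
        contribution = corrected[i] * spill / own
        corrected[nxt] = max(corrected[nxt] - contribution, 0.0)
    return corrected
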