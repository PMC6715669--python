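import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirms.detect_quant import (
    apply_calibration,
    fit_calibration,
    isotope_overlap_correction,
    match_species,
    methylation_fraction,
    predict_species,
)
from mirms.rna_mass import (
    IsotopeEnvelope,
    Oligo,
    composition,
    isotope_envelope,
    mass,
)
from mirms.spectra_io import Peak, PeakList


@pytest.fixture
def oligo():
    return Oligo("CAAAGUGCUUACAGUGCAGGUAG")  # miR-17-5p


def peaklist_at(mzs, intensities, snrs=None):
    snrs = snrs or [None] * len(mzs)
    order = np.argsort(mzs)
    return PeakList(
        tuple(Peak(mzs[i], intensities[i], snrs[i]) for i in order)
    )


class TestPredictSpecies:
    def test_spacing_is_methyl_shift(self, oligo):
        preds = predict_species(oligo, kmax=3)
        assert len(preds) == 4
        masses = [p.neutral_mass for p in preds]
        for a, b in zip(masses, masses[1:]):
            assert b - a == pytest.approx(14.01565, abs=1e-5)

    def test_kmax_zero_single_species(self, oligo):
        preds = predict_species(oligo, kmax=0)
        assert len(preds) == 1
        assert preds[0].k == 0
        assert preds[0].neutral_mass == pytest.approx(mass(oligo), abs=1e-9)

    def test_adduct_masses(self, oligo):
        preds = predict_species(oligo, kmax=0, adducts=["Na", "K"])
        by_adduct = {p.adduct: p.neutral_mass for p in preds}
        assert by_adduct["Na"] - by_adduct["none"] == pytest.approx(21.98194, abs=1e-5)
        assert by_adduct["K"] - by_adduct["none"] == pytest.approx(37.95588, abs=1e-5)

    def test_count_with_adducts(self, oligo):
        preds = predict_species(oligo, kmax=2, adducts=["Na"])
        assert len(preds) == 3 * 2  # (kmax+1) x (1 + |adducts|)

    def test_kmax_exceeding_ac_residues_rejected(self):
        with pytest.raises(ValueError, match="methylatable"):
            predict_species(Oligo("GUGU"), kmax=1)
        with pytest.raises(ValueError, match="methylatable"):
            predict_species(Oligo("ACGU"), kmax=3)

    def test_negative_kmax_rejected(self, oligo):
        with pytest.raises(ValueError):
            predict_species(oligo, kmax=-1)


class TestMatchSpecies:
    def test_exact_peaks_all_matched(self, oligo):
        preds = predict_species(oligo, kmax=2)
        pl = peaklist_at([p.mz for p in preds], [100.0, 50.0, 25.0])
        matches = match_species(pl, preds, tol_ppm=50)
        assert all(m.accepted for m in matches)
        assert all(abs(m.ppm_error) < 1e-9 for m in matches)

    def test_peak_outside_tolerance_unmatched(self, oligo):
        preds = predict_species(oligo, kmax=0)
        displaced = preds[0].mz * (1 + 100e-6)
        matches = match_species(peaklist_at([displaced], [10.0]), preds, tol_ppm=50)
        assert not matches[0].accepted

    def test_nearest_ppm_wins(self, oligo):
        preds = predict_species(oligo, kmax=0)
        mz0 = preds[0].mz
        near, far = mz0 * (1 + 5e-6), mz0 * (1 + 30e-6)
        matches = match_species(peaklist_at([near, far], [1.0, 2.0]), preds, 50)
        assert matches[0].peak.mz == pytest.approx(near)
        assert matches[0].ppm_error == pytest.approx(5.0, abs=0.01)

    def test_tie_broken_toward_lower_k(self, oligo):
        # one peak equidistant (in ppm) from nothing; simpler: peak exactly
        # between would differ in ppm. Instead one peak inside tolerance of
        # both k=0 and k=1 predictions cannot happen at 14 Da spacing, so
        # construct two predictions sharing a mass via adduct coincidence is
        # artificial; assert documented behaviour with equal ppm by feeding
        # the same prediction list twice.
        preds = predict_species(oligo, kmax=1)
        pl = peaklist_at([preds[0].mz], [5.0])
        matches = match_species(pl, list(preds) + [preds[0]], tol_ppm=50)
        accepted = [i for i, m in enumerate(matches) if m.accepted]
        assert accepted == [0]  # first (lower-k, first-listed) wins the peak

    def test_peak_used_once(self, oligo):
        preds = predict_species(oligo, kmax=1)
        pl = peaklist_at([preds[0].mz], [5.0])
        matches = match_species(pl, preds, tol_ppm=50)
        assert matches[0].accepted and not matches[1].accepted

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            match_species(peaklist_at([100.0], [1.0]), [], 50)

    def test_nonpositive_tolerance_rejected(self, oligo):
        preds = predict_species(oligo, 0)
        with pytest.raises(ValueError):
            match_species(peaklist_at([100.0], [1.0]), preds, 0)


class TestMethylationFraction:
    def make_matches(self, oligo, intensities, snrs=None):
        preds = predict_species(oligo, kmax=len(intensities) - 1)
        keep = [i for i, v in enumerate(intensities) if v is not None]
        pl = peaklist_at(
            [preds[i].mz for i in keep],
            [intensities[i] for i in keep],
            [None if snrs is None else snrs[i] for i in keep],
        )
        return match_species(pl, preds, 50)

    def test_equal_intensities_give_half(self, oligo):
        frac = methylation_fraction(self.make_matches(oligo, [100.0, 100.0]))
        assert frac.fraction == pytest.approx(0.5)
        assert not frac.below_detection

    def test_no_methylated_peak_below_detection_zero(self, oligo):
        frac = methylation_fraction(self.make_matches(oligo, [100.0, None]))
        assert frac.fraction == 0.0
        assert frac.below_detection

    def test_methylated_only_gives_one(self, oligo):
        frac = methylation_fraction(self.make_matches(oligo, [None, 80.0]))
        assert frac.fraction == 1.0

    def test_snr_floor_suppresses_weak_methylated(self, oligo):
        matches = self.make_matches(oligo, [100.0, 5.0], snrs=[50.0, 1.5])
        frac = methylation_fraction(matches, snr_floor=3.0)
        assert frac.below_detection and frac.fraction == 0.0

    def test_per_k_shares(self, oligo):
        frac = methylation_fraction(self.make_matches(oligo, [60.0, 30.0, 10.0]))
        assert dict(frac.per_k_intensity) == {0: 60.0, 1: 30.0, 2: 10.0}
        assert frac.fraction == pytest.approx(0.4)

    def test_no_accepted_matches_is_error(self, oligo):
        preds = predict_species(oligo, kmax=1)
        matches = match_species(peaklist_at([100.0], [1.0]), preds, 50)
        with pytest.raises(ValueError, match="no accepted"):
            methylation_fraction(matches)

    def test_missing_k0_prediction_is_error(self, oligo):
        preds = [p for p in predict_species(oligo, kmax=1) if p.k == 1]
        matches = match_species(peaklist_at([preds[0].mz], [1.0]), preds, 50)
        with pytest.raises(ValueError, match="k=0"):
            methylation_fraction(matches)


class TestCalibration:
    def test_identity_points(self):
        points = [(f, f) for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        curve = fit_calibration(points)
        assert curve.slope == pytest.approx(1.0, abs=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        for f, _ in points:
            assert apply_calibration(curve, f) == pytest.approx(f, abs=1e-9)

    def test_response_factor_is_slope(self):
        r = 0.8
        points = [(f, r * f / (r * f + 1 - f)) for f in np.linspace(0.1, 0.9, 9)]
        curve = fit_calibration(points)
        assert curve.slope == pytest.approx(r, abs=1e-9)
        # inversion recovers the true fraction
        for f, measured in points:
            assert apply_calibration(curve, measured) == pytest.approx(f, abs=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.5, 0.5)])

    def test_identical_x_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.5, 0.4), (0.5, 0.6)])

    def test_apply_clamps_to_unit_interval(self):
        curve = fit_calibration([(0.1, 0.1), (0.9, 0.9)])
        assert apply_calibration(curve, 1.2) == 1.0
        assert 0.0 <= apply_calibration(curve, 0.0) <= 1.0

    @settings(max_examples=25, deadline=None)
    @given(r=st.floats(0.3, 2.0))
    def test_monotone_on_unit_interval(self, r):
        points = [(f, r * f / (r * f + 1 - f)) for f in np.linspace(0.1, 0.9, 9)]
        curve = fit_calibration(points)
        grid = np.linspace(0.0, 1.0, 101)
        out = [apply_calibration(curve, g) for g in grid]
        assert all(b >= a - 1e-12 for a, b in zip(out, out[1:]))


class TestIsotopeOverlapCorrection:
    def make_matches(self, oligo, intensities):
        preds = predict_species(oligo, kmax=len(intensities) - 1)
        pl = peaklist_at([p.mz for p in preds], intensities)
        return match_species(pl, preds, 50)

    def test_correction_negligible_at_14da_spacing(self, oligo):
        matches = self.make_matches(oligo, [100.0, 50.0])
        comp = composition(oligo)
        envs = {
            (0, "none"): isotope_envelope(comp, truncation=1e-4),
        }
        corrected = isotope_overlap_correction(matches, envs)
        assert corrected[1] == pytest.approx(50.0, abs=1e-6)

    def test_broadened_envelope_reduces_next_species(self, oligo):
        matches = self.make_matches(oligo, [100.0, 50.0])
        m0 = matches[0].prediction.neutral_mass
        fake = IsotopeEnvelope(
            ((m0, 0.7), (m0 + 14.0157, 0.3)), truncation=0.01
        )
        corrected = isotope_overlap_correction(matches, {(0, "none"): fake})
        assert corrected[0] == pytest.approx(100.0)
        assert corrected[1] == pytest.approx(50.0 - 100.0 * 0.3 / 0.7, abs=1e-6)

    def test_clamped_at_zero(self, oligo):
        matches = self.make_matches(oligo, [100.0, 1.0])
        m0 = matches[0].prediction.neutral_mass
        fake = IsotopeEnvelope(((m0, 0.5), (m0 + 14.0157, 0.5)), truncation=0.01)
        corrected = isotope_overlap_correction(matches, {(0, "none"): fake})
        assert corrected[1] == 0.0

    def test_missing_envelope_is_noop(self, oligo):
        matches = self.make_matches(oligo, [100.0, 50.0])
        assert isotope_overlap_correction(matches, {}) == [100.0, 50.0]
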