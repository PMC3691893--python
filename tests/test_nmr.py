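"""Spectrum handling, multiplet integration and the correction factor."""

import numpy as np
import pytest

from pabaflux import (MultipletAreas, PeakTable, QuantificationError, Spectrum,
                      SpectrumLayout, assemble_areas, correction_factor,
                      integrate_multiplets, lorentzian_window_fraction)
from pabaflux.nmr import PEAK_LABELS


def lorentzian(x, center, area, fwhm):
    g = fwhm / 2.0
    return area * g / (np.pi * ((x - center) ** 2 + g ** 2))


@pytest.fixture
def layout() -> SpectrumLayout:
    return SpectrumLayout()


def dense_axis(layout, pad=1.0):
    step = layout.linewidth_ppm / 10
    segs = []
    for c in (layout.c2_center_ppm, layout.aromatic_35_ppm,
              layout.aromatic_26_ppm, layout.c1_center_ppm):
        segs.append(np.arange(c - pad, c + pad, step))
    return np.concatenate(segs)


class TestSpectrum:
    def test_rejects_non_monotone_axis(self):
        with pytest.raises(QuantificationError):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(QuantificationError):
            Spectrum(np.array([1.0, 2.0]), np.zeros(3))

    def test_descending_axis_accepted_and_flipped(self):
        s = Spectrum(np.array([3.0, 2.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        asc = s.ascending()
        assert asc.ppm_axis[0] == 1.0 and asc.intensity[0] == 3.0

    def test_csv_round_trip(self, tmp_path):
        s = Spectrum(np.linspace(0, 10, 50), np.random.default_rng(0).normal(size=50))
        p = tmp_path / "spec.csv"
        s.to_csv(p)
        s2 = Spectrum.from_csv(p)
        np.testing.assert_allclose(s2.ppm_axis, s.ppm_axis)
        np.testing.assert_allclose(s2.intensity, s.intensity)


class TestIntegration:
    def test_flat_zero_spectrum_gives_zero_areas(self, layout):
        x = dense_axis(layout)
        peaks = integrate_multiplets(Spectrum(x, np.zeros_like(x)), layout)
        assert all(abs(a) < 1e-12 for _l, _c, a in peaks.rows)

    def test_unit_lorentzian_recovered_at_ten_linewidths(self, layout):
        """A unit-area line at the C2S center integrates to 1.00 ± 2% with a
        window of only 10 linewidths, thanks to the analytic truncation and
        baseline-loss correction."""
        x = dense_axis(layout)
        y = lorentzian(x, layout.c2_center_ppm, 1.0, layout.linewidth_ppm)
        w = 10 * layout.linewidth_ppm
        peaks = integrate_multiplets(Spectrum(x, y), layout, window=w)
        assert peaks.area("C2S") == pytest.approx(1.0, rel=0.02)

    def test_raw_truncated_area_matches_closed_form(self, layout):
        """Without the correction, the raw baseline-subtracted trapezoidal
        area equals the analytic captured fraction of the Lorentzian."""
        x = dense_axis(layout)
        y = lorentzian(x, layout.c2_center_ppm, 1.0, layout.linewidth_ppm)
        for mult in (5.0, 10.0, 20.0):
            w = mult * layout.linewidth_ppm
            peaks = integrate_multiplets(Spectrum(x, y), layout, window=w,
                                         tail_correction=False, edge_points=1)
            expected = lorentzian_window_fraction(w, layout.linewidth_ppm)
            assert peaks.area("C2S") == pytest.approx(expected, rel=5e-3)

    def test_raw_area_converges_monotonically_with_window(self, layout):
        x = dense_axis(layout, pad=2.0)
        y = lorentzian(x, layout.c2_center_ppm, 1.0, layout.linewidth_ppm)
        areas = []
        for mult in (3, 6, 12, 24):
            w = mult * layout.linewidth_ppm
            peaks = integrate_multiplets(Spectrum(x, y), layout, window=w,
                                         tail_correction=False,
                                         subtract_baseline=False)
            areas.append(peaks.area("C2S"))
        assert all(b > a for a, b in zip(areas, areas[1:]))
        assert areas[-1] == pytest.approx(1.0, rel=0.02)

    def test_window_outside_spectrum_names_label(self, layout):
        x = np.arange(20.0, 26.0, 0.001)  # covers C2 region only
        with pytest.raises(QuantificationError, match="P26|P35|C1S"):
            integrate_multiplets(Spectrum(x, np.zeros_like(x)), layout)

    def test_overlapping_windows_rejected(self, layout):
        x = dense_axis(layout)
        spec = Spectrum(x, np.zeros_like(x))
        with pytest.raises(QuantificationError, match="overlap"):
            integrate_multiplets(spec, layout, window=0.3)


class TestAssemble:
    def make_table(self, **areas):
        base = {lab: 0.0 for lab in PEAK_LABELS}
        base.update(areas)
        return PeakTable(tuple((lab, 0.0, a) for lab, a in base.items()))

    def test_doublet_halves_sum(self):
        t = self.make_table(C2D_left=0.5, C2D_right=0.5, P26=1, P35=1)
        areas = assemble_areas(t)
        assert areas.c2_doublet == pytest.approx(1.0)

    def test_all_zero_table_is_valid(self):
        areas = assemble_areas(self.make_table())
        assert areas.c2_total == 0.0 and areas.c1_total == 0.0

    def test_missing_label_reported(self):
        rows = tuple((lab, 0.0, 1.0) for lab in PEAK_LABELS if lab != "C2S")
        with pytest.raises(QuantificationError, match="C2S"):
            assemble_areas(PeakTable(rows))

    def test_peak_table_csv_round_trip(self, tmp_path):
        t = self.make_table(C2S=1.5, P26=2.0, P35=2.0)
        p = tmp_path / "peaks.csv"
        t.to_csv(p)
        t2 = PeakTable.from_csv(p)
        assert t2.area("C2S") == pytest.approx(1.5)


class TestCorrectionFactor:
    def test_identity_when_acetyl_matches_per_carbon_reference(self):
        # per-carbon aromatic = 0.5*(2+2)/2 = 1.0; C2 total = 1.0
        ref = MultipletAreas(0, 0, 1.0, 0, 2.0, 2.0)
        assert correction_factor(ref) == pytest.approx(1.0)

    def test_attenuated_acetyl_inverts(self):
        # acetyl area 0.8x the per-carbon aromatic area -> CF = 1.25
        ref = MultipletAreas(0, 0, 0.8, 0, 2.0, 2.0)
        assert correction_factor(ref) == pytest.approx(1.25)

    def test_zero_aromatic_rejected(self):
        with pytest.raises(QuantificationError):
            correction_factor(MultipletAreas(0, 0, 1.0, 0, 0.0, 0.0))
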