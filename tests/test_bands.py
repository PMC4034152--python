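import numpy as np
import pytest
import scipy.signal

import ectospec as es
from ectospec.bands import FSDConfig, fsd
from conftest import lorentzian, gaussian, make_spectrum


def area_lorentzian(wn, center, fwhm, area=1.0):
    hw = fwhm / 2.0
    return (area / np.pi) * hw / ((wn - center) ** 2 + hw**2)


def measure_fwhm(wn, y):
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = np.interp(half, y[: i + 1], wn[: i + 1])
    right = np.interp(half, y[i:][::-1], wn[i:][::-1])
    return right - left


class TestFsd:
    def test_identity_as_enhancement_approaches_one(self, grid):
        y = area_lorentzian(grid.wavenumbers, 1650, 12)
        out = fsd(make_spectrum(y), FSDConfig(12, 1.0 + 1e-7, "boxcar"))
        assert np.max(np.abs(out.absorbance - y)) / y.max() < 1e-6

    def test_matched_lorentzian_narrows_and_keeps_position(self, grid):
        wn = grid.wavenumbers
        y = area_lorentzian(wn, 1650, 12)
        out = fsd(make_spectrum(y), FSDConfig(12, 2.0)).absorbance
        assert wn[np.argmax(out)] == pytest.approx(1650, abs=grid.step)
        assert measure_fwhm(wn, out) <= 7.0

    def test_fwhm_halving_within_15_percent_fine_grid(self):
        # finer sampling so the measured width is not resolution-limited
        g = es.WavenumberGrid(1000, 2000, 0.5)
        wn = g.wavenumbers
        y = area_lorentzian(wn, 1650, 12)
        s = es.Spectrum(g, y, es.SampleMeta(sample_id="x"))
        out = fsd(s, FSDConfig(12, 2.0)).absorbance
        assert measure_fwhm(wn, out) == pytest.approx(6.0, rel=0.15)

    @pytest.mark.parametrize("enhancement", [1.5, 2.0, 3.0])
    def test_isolated_band_area_preserved(self, grid, enhancement):
        wn = grid.wavenumbers
        y = area_lorentzian(wn, 1650, 12)
        out = fsd(make_spectrum(y), FSDConfig(12, enhancement)).absorbance
        sl = grid.slice(1450, 1850)
        ratio = np.trapezoid(out[sl], wn[sl]) / np.trapezoid(y[sl], wn[sl])
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_splits_unresolved_beta_sheet_doublet(self, grid):
        # 1627/1618 cm-1, FWHM 16: the raw sum has a single maximum
        wn = grid.wavenumbers
        y = area_lorentzian(wn, 1627, 16) + area_lorentzian(wn, 1618, 16)
        sl = grid.slice(1590, 1660)
        raw_maxima = wn[sl][scipy.signal.find_peaks(y[sl])[0]]
        assert len(raw_maxima) == 1
        out = fsd(make_spectrum(y), FSDConfig(16, 2.5)).absorbance
        maxima = wn[sl][scipy.signal.find_peaks(out[sl], prominence=1e-3)[0]]
        assert len(maxima) == 2
        assert np.min(np.abs(maxima - 1627)) <= 2.0
        assert np.min(np.abs(maxima - 1618)) <= 2.0

    def test_white_noise_survives_with_finite_amplification(self, grid):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, grid.n_points)
        out = fsd(make_spectrum(noise)).absorbance
        assert np.all(np.isfinite(out))
        assert out.std() < 1e3  # amplified, but bounded

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FSDConfig(enhancement=1.0)
        with pytest.raises(ValueError):
            FSDConfig(band_fwhm=-3)
        with pytest.raises(ValueError):
            FSDConfig(apodization="hamming")


class TestPickPeaks:
    def test_two_gaussians_found_at_centers(self, grid):
        wn = grid.wavenumbers
        y = gaussian(wn, 1632, 20, 1.0) + gaussian(wn, 1515, 20, 0.6)
        pl = es.pick_peaks(
            make_spectrum(y), es.SpectralWindow("w", 1480, 1700),
            rel_threshold=0.1,
        )
        kinds = [p for p in pl.peaks if p.kind == "peak"]
        assert len(kinds) == 2
        assert abs(kinds[0].center - 1632) <= 2.0
        assert abs(kinds[1].center - 1515) <= 2.0

    def test_flat_spectrum_yields_empty_list(self, grid):
        pl = es.pick_peaks(
            make_spectrum(np.zeros(grid.n_points)),
            es.SpectralWindow("w", 1480, 1700),
        )
        assert len(pl) == 0

    def test_band_at_window_edge_never_reported_outside(self, grid):
        wn = grid.wavenumbers
        y = gaussian(wn, 1480, 20)
        pl = es.pick_peaks(make_spectrum(y), es.SpectralWindow("w", 1480, 1700))
        assert all(1480 <= p.center <= 1700 for p in pl.peaks)

    def test_positive_scaling_invariance(self, grid):
        wn = grid.wavenumbers
        y = gaussian(wn, 1632, 20) + gaussian(wn, 1515, 14, 0.4)
        w = es.SpectralWindow("w", 1480, 1700)
        p1 = es.pick_peaks(make_spectrum(y), w)
        p2 = es.pick_peaks(make_spectrum(123.4 * y), w)
        assert p1.centers == p2.centers
        assert [p.kind for p in p1.peaks] == [p.kind for p in p2.peaks]

    def test_min_separation_merges_keeping_deeper(self, grid):
        wn = grid.wavenumbers
        y = gaussian(wn, 1600, 12, 1.0) + gaussian(wn, 1604, 12, 0.8)
        pl = es.pick_peaks(
            make_spectrum(y), es.SpectralWindow("w", 1550, 1650),
            min_separation=10.0,
        )
        assert len(pl) == 1

    def test_shoulders_flagged_between_thresholds(self, grid):
        wn = grid.wavenumbers
        y = gaussian(wn, 1630, 20, 1.0) + gaussian(wn, 1500, 14, 0.05)
        pl = es.pick_peaks(
            make_spectrum(y), es.SpectralWindow("w", 1480, 1700),
            rel_threshold=0.2,
        )
        by_kind = {p.kind for p in pl.peaks}
        assert "peak" in by_kind and "shoulder" in by_kind


class TestMeanSpectrum:
    def test_mean_of_identical_spectra_is_that_spectrum(self, grid):
        y = lorentzian(grid.wavenumbers, 1632, 16)
        ds = es.SpectralDataset([
            make_spectrum(y, "a", species="Lactarius_subdulcis"),
            make_spectrum(y.copy(), "b", species="Lactarius_subdulcis"),
        ])
        m = es.mean_spectrum(ds, lambda meta: True, "g")
        assert np.array_equal(m.absorbance, y)
        assert m.meta.n == 2

    def test_opposite_spectra_cancel(self, grid):
        y = lorentzian(grid.wavenumbers, 1632, 16)
        ds = es.SpectralDataset([make_spectrum(y, "a"), make_spectrum(-y, "b")])
        m = es.mean_spectrum(ds, lambda meta: True)
        assert np.allclose(m.absorbance, 0.0)

    def test_group_size_recorded_for_species_group(self, default_dataset):
        m = es.mean_spectrum(
            default_dataset,
            lambda meta: meta.species == "Lactarius_subdulcis",
            "Ls",
        )
        assert m.meta.n == 67

    def test_empty_selection_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="no sample"):
            es.mean_spectrum(default_dataset, lambda meta: False)


class TestCelluloseScreen:
    def test_positive_on_synthetic_cellulose(self):
        s = es.generate_cellulose_spectrum(es.GeneratorConfig().noiseless())
        res = es.cellulose_screen(s)
        assert res.contaminated
        assert len(res.matched) == 4

    @pytest.mark.parametrize("species", sorted(es.PHYLUM))
    def test_negative_on_noiseless_species_templates(self, species, templates):
        s = es.template_spectrum(species, templates=templates)
        res = es.cellulose_screen(s)
        assert not res.contaminated, res.matched

    def test_two_markers_are_not_enough(self, grid):
        wn = grid.wavenumbers
        y = gaussian(wn, 1641, 12) + gaussian(wn, 1427, 12)
        res = es.cellulose_screen(make_spectrum(y))
        assert not res.contaminated
        assert len(res.matched) == 2

    def test_cellulose_detected_in_mixture_with_fungal_spectrum(self, templates):
        cell = es.generate_cellulose_spectrum(es.GeneratorConfig().noiseless())
        fungus = es.template_spectrum("Cenococcum_geophilum", templates=templates)
        mixed = make_spectrum(cell.absorbance + fungus.absorbance, "mix")
        assert es.cellulose_screen(mixed).contaminated


class TestCompareBandSets:
    @staticmethod
    def _pl(name, centers):
        return es.PeakList(name, [es.Peak(c, 1.0) for c in centers])

    def test_five_supplementary_bands_in_mixed_stand(self):
        shared = [2925.0, 1617.0, 1515.0, 1108.0, 1031.0]
        a = self._pl("mixed", [2363.0, 1663.0, 1453.0, 1372.0, 830.0] + shared)
        b = self._pl("mono", shared)
        comp = es.compare_band_sets(a, b, tolerance=4.0)
        assert comp.supplementary_in_a == [2363.0, 1663.0, 1453.0, 1372.0, 830.0]
        assert comp.supplementary_in_b == []
        assert len(comp.shared) == len(shared)

    def test_identical_lists_fully_shared(self):
        a = self._pl("x", [1500.0, 1000.0])
        b = self._pl("y", [1500.0, 1000.0])
        comp = es.compare_band_sets(a, b)
        assert comp.supplementary_in_a == comp.supplementary_in_b == []
        assert comp.shared == [(1500.0, 1500.0), (1000.0, 1000.0)]

    def test_tolerance_boundary(self):
        a, b = self._pl("a", [1000.0]), self._pl("b", [1003.0])
        wide = es.compare_band_sets(a, b, tolerance=4.0)
        assert wide.shared == [(1000.0, 1003.0)]
        narrow = es.compare_band_sets(a, b, tolerance=2.0)
        assert narrow.shared == []
        assert narrow.supplementary_in_a == [1000.0]
        assert narrow.supplementary_in_b == [1003.0]

    def test_symmetry(self):
        a = self._pl("a", [2363.0, 1663.0, 1500.0, 1372.0])
        b = self._pl("b", [1501.0, 1371.0, 900.0])
        ab = es.compare_band_sets(a, b)
        ba = es.compare_band_sets(b, a)
        assert ab.supplementary_in_a == ba.supplementary_in_b
        assert ab.supplementary_in_b == ba.supplementary_in_a
        assert sorted(ab.shared) == sorted((y, x) for x, y in ba.shared)

    def test_every_peak_lands_in_exactly_one_list(self):
        a = self._pl("a", [1000.0, 1004.0, 1008.0])
        b = self._pl("b", [1002.0, 1006.0])
        comp = es.compare_band_sets(a, b, tolerance=3.0)
        n_from_a = len(comp.supplementary_in_a) + len(comp.shared)
        n_from_b = len(comp.supplementary_in_b) + len(comp.shared)
        assert n_from_a == 3 and n_from_b == 2
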