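import numpy as np
import pytest

from needlefield.focality import compare_montages, focal_area, fwhm
from needlefield.head import icosphere


def great_circle_distance(surface, seed, R):
    cosg = np.clip(surface.vertices @ surface.vertices[seed] / R**2, -1, 1)
    return R * np.arccos(cosg)


@pytest.fixture(scope="module")
def sphere_gaussian(ico4):
    """Gaussian field of scale s = 2 mm imposed via exact great-circle distance."""
    d = great_circle_distance(ico4, 0, 10.0)
    return ico4, d, np.exp(-(d**2) / (2.0 * 2.0**2))


class TestFwhm:
    def test_gaussian_fwhm_matches_closed_form(self, sphere_gaussian):
        surf, _, f = sphere_gaussian
        res = fwhm(surf, f)
        assert res.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0, rel=0.03)
        assert res.peak_vertex == 0
        assert res.geodesic_distances[res.peak_vertex] == 0.0

    def test_constant_field_rejected(self, ico3):
        with pytest.raises(ValueError, match="constant"):
            fwhm(ico3, np.ones(ico3.n_vertices))

    def test_indicator_cap_fwhm_within_one_bin(self, ico4):
        d = great_circle_distance(ico4, 0, 10.0)
        res = fwhm(ico4, (d <= 2.0).astype(float))
        assert abs(res.fwhm - 4.0) <= res.bin_width

    def test_profile_is_non_increasing(self, sphere_gaussian):
        surf, _, f = sphere_gaussian
        res = fwhm(surf, f)
        assert (np.diff(res.profile[:, 1]) <= 1e-12).all()

    def test_normalized_field_spans_unit_interval(self, sphere_gaussian):
        surf, _, f = sphere_gaussian
        res = fwhm(surf, f)
        assert res.normalized_field.min() == 0.0
        assert res.normalized_field.max() == 1.0

    def test_fwhm_scale_invariance(self, sphere_gaussian):
        surf, _, f = sphere_gaussian
        a = fwhm(surf, f)
        b = fwhm(surf, 10.0 * f)
        assert a.fwhm == pytest.approx(b.fwhm, rel=1e-12)
        assert a.focal_area == pytest.approx(b.focal_area, rel=1e-12)

    def test_peak_ties_break_to_lowest_index(self, ico3):
        f = np.zeros(ico3.n_vertices)
        f[[5, 40]] = 1.0
        res = fwhm(ico3, f)
        assert res.peak_vertex == 5

    def test_refinement_improves_gaussian_fwhm(self):
        true = 2 * np.sqrt(2 * np.log(2)) * 2.0
        errs = []
        for sub in (3, 4):
            s = icosphere(sub, 10.0)
            d = great_circle_distance(s, 0, 10.0)
            f = np.exp(-(d**2) / 8.0)
            errs.append(abs(fwhm(s, f).fwhm - true))
        assert errs[1] < errs[0]

    def test_bad_bin_width_rejected(self, sphere_gaussian):
        surf, _, f = sphere_gaussian
        with pytest.raises(ValueError, match="bin_width"):
            fwhm(surf, f, bin_width=-1.0)


class TestFocalArea:
    def test_indicator_cap_matches_spherical_cap_area(self):
        R = 10.0
        s = icosphere(6, R)
        d = great_circle_distance(s, 0, R)
        area = focal_area(s, (d <= 4.0).astype(float))
        true = 2 * np.pi * R**2 * (1 - np.cos(4.0 / R))
        assert area == pytest.approx(true, rel=0.05)

    def test_single_vertex_above_half_max_has_zero_area(self, ico3):
        f = np.zeros(ico3.n_vertices)
        f[7] = 1.0
        assert focal_area(ico3, f) == 0.0

    def test_scaling_leaves_focal_area_unchanged(self, ico4):
        d = great_circle_distance(ico4, 0, 10.0)
        f = np.exp(-(d**2) / 8.0)
        assert focal_area(ico4, f) == focal_area(ico4, 10.0 * f)


class TestCompareMontages:
    def _result(self, ico3, fwhm_mm, peak):
        from needlefield.focality import FocalityResult

        return FocalityResult(
            peak_vertex=0,
            peak_value=peak,
            geodesic_distances=np.zeros(ico3.n_vertices),
            profile=np.zeros((1, 2)),
            fwhm=fwhm_mm,
            focal_area=1.0,
            normalized_field=np.zeros(ico3.n_vertices),
        )

    def test_identical_inputs_give_zero_difference_and_unit_ratio(self, ico3):
        a = self._result(ico3, 3.0, 1.0)
        cmp = compare_montages(a, a)
        assert cmp["peak_difference_percent"] == 0.0
        assert cmp["fwhm_ratio_percent"] == 100.0
        assert cmp["focal_area_ratio_percent"] == 100.0

    def test_printed_fwhm_pair_gives_64_5_percent_ratio(self, ico3):
        a = self._result(ico3, 0.0020, 1.0)
        b = self._result(ico3, 0.0031, 1.0)
        assert compare_montages(a, b)["fwhm_ratio_percent"] == pytest.approx(
            64.5, abs=0.05
        )

    def test_peak_difference_arithmetic(self, ico3):
        a = self._result(ico3, 1.0, 1.129)
        b = self._result(ico3, 1.0, 1.000)
        assert compare_montages(a, b)["peak_difference_percent"] == pytest.approx(12.9)

    def test_mismatched_surfaces_rejected(self, ico3, ico4):
        a = self._result(ico3, 1.0, 1.0)
        b = self._result(ico4, 1.0, 1.0)
        b.geodesic_distances = np.zeros(ico4.n_vertices)
        with pytest.raises(ValueError, match="different surfaces"):
            compare_montages(a, b)

    def test_ratio_reciprocity_under_swap(self, ico3):
        a = self._result(ico3, 2.0, 1.2)
        b = self._result(ico3, 4.0, 1.0)
        ab = compare_montages(a, b)
        ba = compare_montages(b, a)
        assert ab["fwhm_ratio_percent"] * ba["fwhm_ratio_percent"] == pytest.approx(
            100.0 * 100.0
        )
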