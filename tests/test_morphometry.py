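"""Lower-VT measures: definitional chain, percentage change, error estimate."""

import numpy as np
import pytest

from vtmorph import morphometry as mm
from vtmorph import synthetic as sv
from vtmorph.containers import CrossSectionStack, LandmarkSet


def _stack_with_areas(pixels_per_slice, closed_at=None, spacing=0.3255,
                      flags=None):
    """Stack with exact per-slice pixel counts (pixel pitch 1 mm)."""
    n = len(pixels_per_slice)
    size = int(np.ceil(np.sqrt(max(pixels_per_slice)))) + 2
    masks = np.zeros((n, size, size), dtype=bool)
    for i, px in enumerate(pixels_per_slice):
        masks[i].flat[:px] = True
    closed = np.zeros(n, dtype=bool)
    if closed_at is not None:
        closed[closed_at] = True
    return CrossSectionStack(masks, spacing=spacing, pixel_pitch=1.0,
                             posterior_closed=closed, flags=flags)


def _stack_with_widths(sides, spacing=1.0):
    """Stack of centered squares so the left-right width equals ``sides``."""
    n = len(sides)
    size = max(sides) + 4
    masks = np.zeros((n, size, size), dtype=bool)
    for i, side in enumerate(sides):
        lo = (size - side) // 2
        masks[i, lo:lo + side, lo:lo + side] = True
    return CrossSectionStack(masks, spacing=spacing, pixel_pitch=1.0)


class TestReferencePlane:
    def test_just_below_uppermost_closure(self):
        stack = _stack_with_areas([100] * 60, closed_at=range(35, 41))
        assert mm.find_reference_plane(stack) == 39

    def test_closure_at_top_slice(self):
        stack = _stack_with_areas([100] * 10, closed_at=[9])
        assert mm.find_reference_plane(stack) == 8

    def test_no_closure_errors(self):
        stack = _stack_with_areas([100] * 10)
        with pytest.raises(ValueError, match="closure"):
            mm.find_reference_plane(stack)


class TestAreaLookups:
    def test_ela_is_five_slices_below(self):
        px = [100] * 50
        px[40 - 5] = 55
        stack = _stack_with_areas(px)
        assert mm.measure_ELA(stack, ref=40) == 55.0

    def test_ela_window_underflow(self):
        stack = _stack_with_areas([100] * 50)
        with pytest.raises(IndexError):
            mm.measure_ELA(stack, ref=3)

    def test_hpa_is_thirty_slices_above(self):
        px = [100] * 50
        px[10 + 30] = 400
        stack = _stack_with_areas(px)
        assert mm.measure_HPA(stack, ref=10) == 400.0

    def test_hpa_window_overflow(self):
        stack = _stack_with_areas([100] * 30)
        with pytest.raises(IndexError):
            mm.measure_HPA(stack, ref=10)

    def test_generator_areas_recovered(self, speech_profile):
        truth = sv.truth_measures(speech_profile)
        stack = sv.analytic_stack(speech_profile)
        meas = mm.measure_record(stack)
        assert meas.ELA == pytest.approx(truth["ELA"], rel=0.03)
        assert meas.HPA == pytest.approx(truth["HPA"], rel=0.03)

    def test_injected_hpa_ratio_recovered(self, speech_profile, singing_profile):
        """The singing/speech HPA ratio equals the injected 1.219 within
        rasterization tolerance."""
        r = (mm.measure_record(sv.analytic_stack(singing_profile)).HPA
             / mm.measure_record(sv.analytic_stack(speech_profile)).HPA)
        assert r == pytest.approx(1.219, rel=0.02)


class TestElvLowerBorder:
    def test_fold_constriction_found(self):
        """A fold constriction 10 slices below the reference plane (1 mm
        slices) is returned as the lower ELV border."""
        sides = [30] * 60
        sides[30] = 20
        stack = _stack_with_widths(sides, spacing=1.0)
        assert mm.find_elv_lower_border(stack, ref=40) == 30

    def test_tie_broken_toward_reference(self):
        sides = [30] * 60
        sides[25] = 20
        sides[30] = 20
        stack = _stack_with_widths(sides, spacing=1.0)
        assert mm.find_elv_lower_border(stack, ref=40) == 30

    def test_flat_profile_errors(self):
        stack = _stack_with_widths([30] * 60, spacing=1.0)
        with pytest.raises(ValueError, match="minimum"):
            mm.find_elv_lower_border(stack, ref=40)

    def test_height_warning_outside_typical_band(self):
        sides = [30] * 60
        sides[40 - 5] = 20  # 5 mm height, below the typical 6 mm
        stack = _stack_with_widths(sides, spacing=1.0)
        with pytest.warns(UserWarning, match="ELV height"):
            mm.find_elv_lower_border(stack, ref=40)


class TestVolume:
    def test_constant_area_arithmetic(self):
        masks = np.ones((35, 20, 20), dtype=bool)  # 400 px = 400 mm^2
        stack = CrossSectionStack(masks, spacing=0.3255, pixel_pitch=1.0)
        v = mm.measure_volume(stack, 0, 30)
        assert v == pytest.approx(400.0 * 9.765, rel=1e-12)

    def test_generator_volumes_match_truth(self, speech_profile):
        """Finer in-plane pitch so the fold-width minimum is localized well
        (the quantized left-right width has plateaus at coarse pitch)."""
        truth = sv.truth_measures(speech_profile)
        stack = sv.analytic_stack(speech_profile, pixel_pitch=0.15)
        meas = mm.measure_record(stack)
        assert meas.ELV == pytest.approx(truth["ELV"], rel=0.08)
        assert meas.HPV == pytest.approx(truth["HPV"], rel=0.05)

    def test_invalid_range(self):
        stack = CrossSectionStack(np.ones((10, 4, 4), dtype=bool), spacing=1.0)
        with pytest.raises(ValueError):
            mm.measure_volume(stack, 5, 5)

    def test_flagged_slice_raises_unless_interpolated(self):
        flags = np.zeros(10, dtype=bool)
        flags[4] = True
        stack = CrossSectionStack(np.ones((10, 4, 4), dtype=bool), spacing=1.0,
                                  flags=flags)
        with pytest.raises(ValueError, match="flagged"):
            mm.measure_volume(stack, 0, 10)
        v = mm.measure_volume(stack, 0, 10, interpolate_flagged=True)
        assert v == pytest.approx(160.0)


class TestLarynxHeight:
    def _lm(self, c1, c7, com):
        z = np.zeros(3)
        return LandmarkSet(uvula_tip=z, arytenoid_ventricular_crossing=z,
                           c1_anterior_rim=np.asarray(c1, float),
                           c7_upper_anterior_rim=np.asarray(c7, float),
                           anterior_commissure=np.asarray(com, float))

    def test_orthogonal_projection(self):
        lm = self._lm((0, 100, 0), (0, 0, 0), (30, 40, 0))
        assert mm.measure_LH(lm) == pytest.approx(40.0)

    def test_commissure_on_helpline(self):
        lm = self._lm((0, 100, 0), (0, 0, 0), (0, 25, 0))
        assert mm.measure_LH(lm) == pytest.approx(25.0)

    def test_coincident_vertebrae_error(self):
        lm = self._lm((1, 2, 3), (1, 2, 3), (5, 5, 5))
        with pytest.raises(ValueError, match="coincide"):
            mm.measure_LH(lm)

    def test_cohort_mean_lowering_recovered(self, default_cohort):
        """The injected 8 mm larynx lowering is recovered as the cohort mean
        delta-LH from the measured table."""
        from vtmorph import stats as st
        con = st.mode_contrasts(default_cohort.table)
        assert con["delta_LH"].mean() == pytest.approx(8.0, abs=0.3)


class TestPercentageChange:
    def test_identity(self):
        pc, delta = mm.percentage_change(50.0, 50.0)
        assert pc == 100.0 and delta == 0.0

    def test_plus_21_9_percent(self):
        pc, delta = mm.percentage_change(121.9, 100.0)
        assert delta == pytest.approx(21.9)

    def test_nonpositive_reference(self):
        with pytest.raises(ValueError):
            mm.percentage_change(10.0, 0.0)


class TestScalingInvariants:
    def test_measures_scale_with_geometry(self, speech_profile):
        """Isotropic scaling: areas scale quadratically, volumes cubically.

        Scaling arc length by k and areas by k^2 multiplies the slice count
        per mm window accordingly; compare against truth of the scaled
        profile."""
        k = 1.3
        base = sv.truth_measures(speech_profile)
        import vtmorph
        scaled_af = vtmorph.AreaFunction(
            speech_profile.positions * k, speech_profile.areas * k**2,
            {n: p * k for n, p in speech_profile.annotations.items()})
        scaled = sv.truth_measures(scaled_af, spacing=sv.SLICE_SPACING_MM * k)
        assert scaled["ELA"] / base["ELA"] == pytest.approx(k**2, rel=0.02)
        assert scaled["HPA"] / base["HPA"] == pytest.approx(k**2, rel=0.02)
        assert scaled["ELV"] / base["ELV"] == pytest.approx(k**3, rel=0.02)
        assert scaled["HPV"] / base["HPV"] == pytest.approx(k**3, rel=0.02)


class TestAreaErrorEstimate:
    def test_small_larynx_area_worked_example(self):
        """55 mm^2 with 1 mm diameter uncertainty: diameter 8.36 mm, real
        areas 42.64 / 68.93 mm^2, relative errors 29 % / 20 %."""
        e = mm.area_error_estimate(55.0, 1.0)
        assert e.diameter == pytest.approx(8.36, abs=0.01)
        assert e.area_minus == pytest.approx(42.64, abs=0.01)
        assert e.area_plus == pytest.approx(68.93, abs=0.01)
        assert round(e.rel_err_minus) == 29
        assert round(e.rel_err_plus) == 20

    def test_large_hypopharynx_area_worked_example(self):
        e = mm.area_error_estimate(860.0, 1.0)
        assert e.rel_err_minus == pytest.approx(6.3, abs=0.05)
        assert e.rel_err_plus == pytest.approx(5.8, abs=0.05)

    def test_zero_uncertainty(self):
        e = mm.area_error_estimate(123.0, 0.0)
        assert e.rel_err_minus == 0.0 and e.rel_err_plus == 0.0

    def test_uncertainty_exceeding_diameter(self):
        with pytest.raises(ValueError):
            mm.area_error_estimate(1.0, 5.0)


class TestEllipticalRobustness:
    def test_elliptical_sections_recovered(self, speech_profile):
        """Equal-area elliptical cross-sections give the same areas as
        circular ones (robustness to non-circular lumina)."""
        truth = sv.truth_measures(speech_profile)
        stack = sv.analytic_stack(speech_profile, eccentricity=0.6)
        meas = mm.measure_record(stack)
        assert meas.HPA == pytest.approx(truth["HPA"], rel=0.04)
        assert meas.HPV == pytest.approx(truth["HPV"], rel=0.06)
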