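"""Profile extraction, FWHM trough widths, and SPAS measurement tables."""

import math

import numpy as np
import pandas as pd
import pytest

import spasquant as sq
from spasquant import sizing as sz
from conftest import single_spas_truth


def make_profile(values, sampling_mm, direction=sz.LONGITUDINAL):
    values = np.asarray(values, float)
    n = len(values)
    assert n % 2 == 1
    offsets = (np.arange(n) - n // 2) * sampling_mm
    return sz.ProfileLine((0.0, 0.0), direction, offsets[-1], sampling_mm,
                          offsets, values)


def trough_profile(shape, width_mm, depth, sampling_mm=0.05,
                   half_length_mm=6.0, baseline=0.0):
    n = 2 * int(half_length_mm / sampling_mm) + 1
    x = (np.arange(n) - n // 2) * sampling_mm
    if shape == "rect":
        v = baseline - depth * (np.abs(x) <= width_mm / 2)
    else:  # gaussian with sigma = width_mm
        v = baseline - depth * np.exp(-x**2 / (2 * width_mm**2))
    return make_profile(v, sampling_mm)


class TestExtractProfile:
    def test_constant_image(self, default_truth):
        img = sq.render_image(default_truth, sq.ImagingMode.reference())
        img.pixels[:] = -500.0
        prof = sz.extract_profile(img, (17.5, 30.0), sz.TRANSVERSE, 4.0)
        assert np.allclose(prof.values, -500.0)
        assert len(prof.values) % 2 == 1
        assert prof.positions_mm[len(prof.values) // 2] == 0.0

    def test_step_edge_midpoint(self):
        pixels = np.full((32, 32), 100.0)
        pixels[:, 16:] = 200.0
        img = sq.CTImage(pixels, 1.0, "REFERENCE")
        # the edge sits at x = 16 mm (boundary between pixel centers
        # 15.5 and 16.5); bilinear interpolation gives the mean there
        prof = sz.extract_profile(img, (16.0, 16.0), sz.TRANSVERSE, 3.0)
        mid = prof.values[len(prof.values) // 2]
        assert mid == pytest.approx(150.0)

    def test_minimum_near_center_for_rendered_spas(self):
        truth = single_spas_truth(2.0, 2.0)
        img = sq.render_image(truth, sq.ImagingMode.reference())
        s = truth.spas[0]
        prof = sz.extract_profile(img, (s.center_y_mm, s.center_x_mm),
                                  sz.LONGITUDINAL, 3.0)
        # the bottom is flat: the center sample must attain the minimum
        center_val = prof.values[len(prof.values) // 2]
        assert center_val == pytest.approx(prof.values.min(), abs=1e-6)

    def test_out_of_bounds_rejected(self, default_truth):
        img = sq.render_image(default_truth, sq.ImagingMode.nr(noise_sd_hu=0.0))
        with pytest.raises(ValueError):
            sz.extract_profile(img, (0.5, 30.0), sz.LONGITUDINAL, 5.0)


class TestFwhmWidth:
    @pytest.mark.parametrize("w", [0.8, 1.5, 3.0])
    def test_rectangular_trough(self, w):
        prof = trough_profile("rect", w, 300.0)
        got = sz.fwhm_width(prof)
        assert got == pytest.approx(w, abs=2 * prof.sampling_mm)

    @pytest.mark.parametrize("sigma", [0.4, 0.8, 1.2])
    def test_gaussian_trough_closed_form(self, sigma):
        prof = trough_profile("gauss", sigma, 300.0, half_length_mm=8.0)
        got = sz.fwhm_width(prof)
        assert got == pytest.approx(2 * math.sqrt(2 * math.log(2)) * sigma,
                                    rel=0.02)

    def test_shallow_trough_not_measurable(self):
        prof = trough_profile("rect", 1.0, 30.0)
        assert sz.fwhm_width(prof, contrast_floor=50.0) is None

    def test_affine_intensity_invariance(self):
        prof = trough_profile("gauss", 0.7, 200.0, baseline=-600.0)
        w0 = sz.fwhm_width(prof)
        scaled = make_profile(2.5 * prof.values + 300.0, prof.sampling_mm)
        assert sz.fwhm_width(scaled, contrast_floor=125.0) == pytest.approx(w0)

    def test_sampling_refinement_consistency(self):
        coarse = trough_profile("gauss", 0.9, 300.0, sampling_mm=0.125)
        fine = trough_profile("gauss", 0.9, 300.0, sampling_mm=0.0625)
        w_c, w_f = sz.fwhm_width(coarse), sz.fwhm_width(fine)
        assert abs(w_c - w_f) < 0.125


class TestMeasureSpas:
    def test_ellipse_area_on_reference(self):
        truth = single_spas_truth(1.5, 3.0)
        img = sq.render_image(truth, sq.ImagingMode.reference())
        m = sz.measure_spas(img, truth.spas[0])
        assert m.measurable
        assert m.area_mm2 == pytest.approx(math.pi / 4 * 1.5 * 3.0, rel=0.07)
        assert m.area_mm2 == pytest.approx(
            math.pi / 4 * m.d_long_mm * m.d_trans_mm, rel=1e-12)

    def test_unmeasurable_propagates(self):
        truth = single_spas_truth(1.5, 3.0)
        img = sq.render_image(truth, sq.ImagingMode.reference())
        img.pixels[:] = truth.matrix_hu  # erase the lumen
        m = sz.measure_spas(img, truth.spas[0])
        assert not m.measurable
        assert m.area_mm2 is None

    def test_reference_within_5pct_of_truth(self):
        for seed in (3, 7):
            truth = sq.generate_phantom(sq.PhantomSpec(seed=seed))
            spec = truth.parent_spec
            img = sq.render_image(truth, sq.ImagingMode.reference())
            for s in truth.open_spas:
                # interior SPAS only: the profile window must fit inside
                # the section for the baseline flanks to be clean
                fits = (min(s.center_x_mm, spec.width_mm - s.center_x_mm)
                        >= 2 * s.d_trans_mm
                        and min(s.center_y_mm, spec.height_mm - s.center_y_mm)
                        >= 2 * s.d_long_mm)
                if fits and min(s.d_long_mm, s.d_trans_mm) >= 1.0:
                    m = sz.measure_spas(img, s)
                    assert m.measurable
                    assert m.d_long_mm == pytest.approx(s.d_long_mm, rel=0.05)
                    assert m.d_trans_mm == pytest.approx(s.d_trans_mm, rel=0.05)


class TestDeviationTable:
    def frame(self, rows):
        return pd.DataFrame(rows)

    def base_row(self, **kw):
        row = dict(spas_id=1, mode="NR", compression_pct=0.0, phase=0,
                   d_long_mm=1.3, d_trans_mm=2.7, area_mm2=2.76,
                   measurable=True)
        row.update(kw)
        return row

    def test_identical_measurements_zero_deviation(self):
        ct = self.frame([self.base_row()])
        ref = self.frame([self.base_row(mode="REFERENCE")])
        dev = sz.deviation_table(ct, ref)
        assert (dev["deviation"] == 0).all()
        assert set(dev["dimension"]) == {"longitudinal", "transverse", "area"}

    def test_positive_longitudinal_deviation(self):
        ct = self.frame([self.base_row(d_long_mm=1.8)])
        ref = self.frame([self.base_row(mode="REFERENCE", d_long_mm=1.3)])
        dev = sz.deviation_table(ct, ref)
        row = dev[dev["dimension"] == "longitudinal"].iloc[0]
        assert row["deviation"] == pytest.approx(0.5)

    def test_unpaired_rows_skipped(self):
        ct = self.frame([self.base_row(), self.base_row(spas_id=2)])
        ref = self.frame([self.base_row(mode="REFERENCE")])
        dev = sz.deviation_table(ct, ref)
        assert set(dev["spas_id"]) == {1}


class TestTrajectoryTable:
    def test_four_phase_rows(self):
        rows = [dict(spas_id=5, mode="UHR", compression_pct=c, phase=i,
                     d_long_mm=2.0 - 0.02 * c, d_trans_mm=3.0,
                     area_mm2=1.0, measurable=True)
                for i, c in enumerate([0.0, 12.0, 24.0, 35.0])]
        out = sz.trajectory_table(pd.DataFrame(rows))
        assert len(out) == 4
        assert not out["truncated"].any()

    def test_truncation_on_unmeasurable(self):
        rows = [dict(spas_id=5, mode="NR", compression_pct=c, phase=i,
                     d_long_mm=2.0, d_trans_mm=3.0, area_mm2=1.0,
                     measurable=(c < 24.0))
                for i, c in enumerate([0.0, 12.0, 24.0, 35.0])]
        out = sz.trajectory_table(pd.DataFrame(rows))
        assert len(out) == 2
        assert out["truncated"].all()

    def test_single_phase_rejected(self):
        rows = [dict(spas_id=5, mode="NR", compression_pct=0.0, phase=0,
                     d_long_mm=2.0, d_trans_mm=3.0, area_mm2=1.0,
                     measurable=True)]
        with pytest.raises(ValueError):
            sz.trajectory_table(pd.DataFrame(rows))


def test_reference_d_long_strictly_decreasing_with_compression():
    """With lumens shrinking faster than the bulk, reference-measured
    longitudinal diameters fall monotonically along the phase series."""
    truth0 = sq.generate_phantom(sq.PhantomSpec(seed=9))
    truths = [sq.compress_phantom(truth0, c) for c in (0.0, 12.0, 24.0, 35.0)]
    tracked = sz.select_trackable_spas(truths, max_spas=5)
    assert tracked
    for sid in tracked:
        vals = []
        for t in truths:
            img = sq.render_image(t, sq.ImagingMode.reference())
            s = {x.id: x for x in t.spas}[sid]
            m = sz.measure_spas(img, s)
            assert m.measurable
            vals.append(m.d_long_mm)
        assert all(b < a for a, b in zip(vals, vals[1:]))
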