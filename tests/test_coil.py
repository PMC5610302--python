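"""Coil geometry, Biot-Savart kernel, closed-form oracles, waveform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elfdose import (CoilGeometry, GeometryError, HeadModel, PulseWaveform,
                     SingularityError, biot_savart_segment, coil_field,
                     make_rect_coil, pulse_waveform, rect_axis_field,
                     rect_center_field, warp_coil)
from elfdose.coil import MU0

from conftest import quadrature_segment_field


class TestRectCoil:
    def test_perimeter_and_centroid(self):
        coil = make_rect_coil()
        assert coil.perimeter_m == pytest.approx(2 * (0.14 + 0.106))
        assert np.allclose(coil.centroid, 0.0, atol=1e-15)

    def test_minimal_discretization_is_corners(self):
        coil = make_rect_coil(n_segments=4)
        corners = {(-0.07, -0.053), (0.07, -0.053), (0.07, 0.053), (-0.07, 0.053)}
        got = {(round(x, 9), round(y, 9)) for x, y, _ in coil.vertices}
        assert got == corners

    @pytest.mark.parametrize("n", [4, 7, 100, 720])
    def test_refinement_preserves_perimeter_and_corners(self, n):
        coil = make_rect_coil(n_segments=n)
        assert coil.n_segments == n
        assert coil.perimeter_m == pytest.approx(0.492)
        verts = {(round(x, 9), round(y, 9)) for x, y, _ in coil.vertices}
        assert {(-0.07, -0.053), (0.07, 0.053)} <= verts

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_rect_coil(width_m=-0.1)
        with pytest.raises(ValueError):
            make_rect_coil(n_segments=3)

    def test_vertex_file_roundtrip(self, tmp_path):
        coil = make_rect_coil(n_segments=16)
        coil.save_vertices(tmp_path / "coil.txt")
        back = CoilGeometry.load_vertices(tmp_path / "coil.txt", coil.current_A)
        assert np.allclose(back.vertices, coil.vertices)


class TestWarp:
    def test_flat_limit(self):
        coil = make_rect_coil(n_segments=400)
        warped = warp_coil(coil, HeadModel(curvature_radius_mm=1e12))
        assert np.max(np.linalg.norm(warped.vertices - coil.vertices, axis=1)) < 1e-6

    def test_arc_length_preserved(self):
        coil = make_rect_coil(n_segments=400)
        warped = warp_coil(coil, HeadModel(curvature_radius_mm=90.0))
        assert warped.perimeter_m == pytest.approx(coil.perimeter_m, rel=1e-3)

    def test_radius_too_small_rejected(self):
        with pytest.raises(GeometryError):
            warp_coil(make_rect_coil(), HeadModel(curvature_radius_mm=50.0))

    def test_field_converges_to_flat_as_radius_grows(self):
        flat = make_rect_coil(n_segments=400)
        pts = np.array([[0.0, 0.0, 0.04], [0.02, 0.01, 0.05], [-0.03, 0.02, 0.06]])
        ref = coil_field(flat, pts).B
        errs = []
        for radius_mm in (320.0, 3200.0, 32000.0):
            warped = warp_coil(flat, HeadModel(curvature_radius_mm=radius_mm))
            errs.append(np.max(np.linalg.norm(coil_field(warped, pts).B - ref, axis=1)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] / np.max(np.linalg.norm(ref, axis=1)) < 1e-3


class TestSegmentKernel:
    def test_infinite_wire_limit(self):
        B = biot_savart_segment((0, -100, 0), (0, 100, 0), 1.0, (0.01, 0, 0))
        assert np.linalg.norm(B) == pytest.approx(MU0 * 1.0 / (2 * np.pi * 0.01), rel=1e-4)

    def test_collinear_point_outside_segment_zero(self):
        B = biot_savart_segment((0, 0, 0), (0, 0, 1), 5.0, (0, 0, 2.5))
        assert np.allclose(B, 0.0)

    def test_on_conductor_raises_with_guard(self):
        with pytest.raises(SingularityError) as exc:
            biot_savart_segment((0, 0, 0), (1, 0, 0), 1.0, (0.5, 0.0004, 0))
        assert exc.value.guard_m == pytest.approx(1e-3)

    def test_matches_quadrature_oracle(self):
        """Closed form vs adaptive quadrature of the raw integrand, random geometry."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            p0, p1 = rng.normal(size=(2, 3)) * 0.1
            point = rng.normal(size=3) * 0.2
            if np.linalg.norm(np.cross(p1 - p0, point - p0)) < 1e-4:
                continue
            got = biot_savart_segment(p0, p1, 3.7, point)
            want = quadrature_segment_field(p0, p1, 3.7, point)
            assert np.allclose(got, want, rtol=1e-6, atol=1e-15)


class TestCoilField:
    def test_center_field_matches_closed_form_and_device_spec(self):
        """Segment sum at the coil center: 2.272 mT, the 'about 2 mT' operating point."""
        coil = make_rect_coil()
        got = coil_field(coil, [[0, 0, 0]]).magnitude_mT[0]
        assert got == pytest.approx(rect_center_field(0.07, 0.053, 240.0) * 1e3, rel=5e-3)
        assert got == pytest.approx(2.272, abs=5e-3)

    def test_on_axis_matches_closed_form(self):
        coil = make_rect_coil()
        got = coil_field(coil, [[0, 0, 0.033]]).magnitude_mT[0]
        assert got == pytest.approx(rect_axis_field(0.07, 0.053, 240.0, 0.033) * 1e3, rel=5e-3)
        assert got == pytest.approx(1.61, abs=5e-3)

    def test_linearity_and_orientation(self):
        coil = make_rect_coil()
        pts = np.array([[0.01, -0.02, 0.05], [0, 0, 0.03]])
        B1 = coil_field(coil, pts).B
        B2 = coil_field(coil.with_current(480.0), pts).B
        assert np.allclose(B2, 2 * B1, rtol=1e-12)
        Brev = coil_field(coil.reversed(), pts).B
        assert np.allclose(Brev, -B1, rtol=1e-12)

    def test_axis_field_strictly_decreasing(self):
        coil = make_rect_coil()
        z = np.linspace(0.0, 0.15, 40)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        mag = coil_field(coil, pts).magnitude_T
        assert np.all(np.diff(mag) < 0)

    def test_divergence_free(self):
        """Central-difference div B on a grid 2 cm off the coil plane is ~0."""
        coil = make_rect_coil()
        h = 0.004
        ax = np.arange(-3, 4) * h
        X, Y, Z = np.meshgrid(ax, ax, 0.05 + np.arange(-3, 4) * h, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        B = coil_field(coil, pts).B.reshape(7, 7, 7, 3)
        div = (np.gradient(B[..., 0], h, axis=0)
               + np.gradient(B[..., 1], h, axis=1)
               + np.gradient(B[..., 2], h, axis=2))
        inner = div[1:-1, 1:-1, 1:-1]
        scale = np.linalg.norm(B, axis=3)[1:-1, 1:-1, 1:-1] / h
        assert np.max(np.abs(inner) / scale) < 1e-3

    def test_chunking_invariance(self):
        coil = make_rect_coil(n_segments=12)
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3)) * 0.1 + [0, 0, 0.2]
        assert np.allclose(coil_field(coil, pts, chunk=7).B, coil_field(coil, pts).B)


class TestClosedForms:
    def test_center_value(self):
        assert rect_center_field(0.07, 0.053, 240.0) == pytest.approx(2.272e-3, rel=2e-4)

    def test_square_specialization(self):
        # square loop of side L: B = 2 sqrt(2) mu0 I / (pi L), with L = 2a
        a = 0.05
        assert rect_center_field(a, a, 10.0) == pytest.approx(
            MU0 * 10.0 * 2 * np.sqrt(2) / (np.pi * 2 * a))

    def test_zero_current(self):
        assert rect_center_field(0.07, 0.053, 0.0) == 0.0

    def test_axis_consistency_at_zero(self):
        assert rect_axis_field(0.07, 0.053, 240.0, 0.0) == pytest.approx(
            rect_center_field(0.07, 0.053, 240.0))

    def test_axis_value_at_67mm(self):
        assert rect_axis_field(0.07, 0.053, 240.0, 0.067) * 1e3 == pytest.approx(0.785, abs=5e-3)

    def test_dipole_decay(self):
        vals = [rect_axis_field(0.07, 0.053, 240.0, z) for z in (2.0, 4.0, 8.0)]
        assert vals[0] / vals[1] == pytest.approx(8.0, rel=1e-2)
        assert vals[1] / vals[2] == pytest.approx(8.0, rel=1e-2)


class TestWaveform:
    def test_duty_fraction(self):
        assert PulseWaveform().duty_fraction == pytest.approx(0.0975)

    def test_pulse_train_values(self):
        wave = PulseWaveform()
        assert pulse_waveform(wave, 0.0) == pytest.approx(1.8)
        assert pulse_waveform(wave, 1.2e-3) == pytest.approx(1.8)
        assert pulse_waveform(wave, 5e-3) == 0.0
        # periodicity
        assert pulse_waveform(wave, 0.5e-3 + 3 * wave.period_s) == pytest.approx(1.8)

    def test_mean_over_period_is_peak_times_duty(self):
        wave = PulseWaveform()
        t = (np.arange(100000) + 0.5) / 100000 * wave.period_s
        assert pulse_waveform(wave, t).mean() == pytest.approx(1.8 * 0.0975, rel=1e-3)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            PulseWaveform(frequency_Hz=75.0, pulse_width_s=0.02)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_amplitude_is_peak_or_zero(self, t):
        wave = PulseWaveform()
        assert float(pulse_waveform(wave, t)) in (0.0, 1.8)
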