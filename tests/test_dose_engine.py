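import numpy as np
import pytest

from ctdr.dose_engine import (
    Beam,
    Plan,
    build_sobp,
    compute_dose,
    depth_dose,
    design_beam,
    plan_from_json,
    plan_to_json,
    range_sigma,
    trace_wet,
)
from ctdr.volumes import ROISet, Volume


def water_rsp(shape=(60, 30, 30), spacing=(2.0, 2.0, 2.0)):
    return Volume(np.ones(shape), spacing, quantity="RSP")


def water_ct(shape=(96, 48, 48), spacing=(2.0, 2.0, 2.0)):
    return Volume(np.zeros(shape), spacing, quantity="HU")


def single_spot_beam(R, u, v, direction="+x", rs_wet=0.0, sigma_air=5.0):
    return Beam(direction, [R], [u], [v], np.ones((1, 1, 1)),
                sigma_air=sigma_air, range_shifter_wet=rs_wet)


class TestTraceWet:
    def test_uniform_water(self):
        w = trace_wet(water_rsp(), (0.0, 30.0, 30.0), (1.0, 0.0, 0.0), [100.0])
        np.testing.assert_allclose(w, [100.0], atol=1e-6)

    def test_lung_slab_arithmetic(self):
        """20 mm of RSP 0.25 inside water: WET over 100 mm = 85 mm."""
        rsp = water_rsp()
        x = np.arange(60) * 2.0
        slab = (x >= 40) & (x < 60)
        rsp.data[slab] = 0.25
        w = trace_wet(rsp, (0.0, 30.0, 30.0), (1.0, 0.0, 0.0), [100.0])
        np.testing.assert_allclose(w, [85.0], atol=0.3)

    def test_monotone_non_decreasing(self):
        rsp = water_rsp()
        t = np.linspace(0, 110, 45)
        w = trace_wet(rsp, (0.0, 30.0, 30.0), (1.0, 0.0, 0.0), t)
        assert np.all(np.diff(w) >= -1e-12)

    def test_oblique_vs_fine_grid_oracle(self):
        """30-degree ray through a voxelized slab agrees with a 10x finer
        grid to < 0.5 mm WET."""
        def slab_volume(spacing):
            n = int(120 / spacing)
            data = np.ones((n, n, 8))
            x = (np.arange(n) + 0.5) * spacing
            data[(x >= 30) & (x < 50)] = 0.25
            return Volume(data, (spacing, spacing, 2.0), quantity="RSP")

        d = (np.cos(np.pi / 6), np.sin(np.pi / 6), 0.0)
        entry = (0.0, 10.0, 4.0)
        coarse = trace_wet(slab_volume(2.0), entry, d, [90.0])
        fine = trace_wet(slab_volume(0.2), entry, d, [90.0])
        assert abs(coarse[0] - fine[0]) < 0.5

    def test_entry_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            trace_wet(water_rsp(), (-50.0, 0.0, 0.0), (1.0, 0.0, 0.0), [10.0])


class TestDepthDose:
    @pytest.mark.parametrize("R", [50.0, 100.0, 200.0])
    def test_peak_at_range(self, R):
        wet = np.linspace(0, R * 1.2, 4000)
        d = depth_dose(R, wet)
        assert abs(wet[np.argmax(d)] - R) < 0.5

    def test_zero_beyond_straggling_tail(self):
        R = 100.0
        assert depth_dose(R, np.array([R + 10 * range_sigma(R)]))[0] == 0.0

    def test_peak_to_entrance_ratio(self):
        d = depth_dose(150.0, np.array([0.0, 150.0]))
        assert d[1] / d[0] >= 3.0

    def test_finite_positive_integral(self):
        wet = np.linspace(0, 150, 2000)
        integral = np.trapezoid(depth_dose(120.0, wet), wet)
        assert 0 < integral < np.inf


class TestComputeDose:
    def test_bragg_peak_depth_with_range_shifter(self):
        """Nominal range 180 mm behind a 7.4 cm WET shifter peaks at 106 mm."""
        ct = water_ct()
        beam = single_spot_beam(180.0, 47.0, 47.0, rs_wet=7.4)
        plan = Plan([beam], prescription=1.0)
        dose = compute_dose(plan, ct)
        profile = dose.data[:, 24, 24]  # lateral voxel nearest the spot at 47 mm
        depth_mm = (np.argmax(profile) + 0.5) * 2.0
        assert abs(depth_mm - 106.0) <= 1.0

    def test_linearity_in_weights(self):
        ct = water_ct((48, 32, 32))
        b1 = single_spot_beam(80.0, 31.0, 31.0)
        b2 = single_spot_beam(80.0, 31.0, 31.0)
        b2.weights = b1.weights * 2.0
        d1 = compute_dose(Plan([b1], 1.0), ct)
        d2 = compute_dose(Plan([b2], 1.0), ct)
        np.testing.assert_allclose(d2.data, 2.0 * d1.data, rtol=1e-12)

    def test_determinism(self):
        ct = water_ct((48, 32, 32))
        plan = Plan([single_spot_beam(80.0, 31.0, 31.0)], 1.0)
        np.testing.assert_array_equal(
            compute_dose(plan, ct).data, compute_dose(plan, ct).data
        )

    def test_monotone_range(self):
        ct = water_ct()
        depths = []
        for R in (60.0, 100.0, 140.0):
            d = compute_dose(Plan([single_spot_beam(R, 47.0, 47.0)], 1.0), ct)
            depths.append(np.argmax(d.data[:, 24, 24]))
        assert depths[0] < depths[1] < depths[2]

    def test_translation_equivariance(self):
        """Shifting anatomy and spots together by one voxel shifts the dose
        by one voxel (interior voxels)."""
        ct = water_ct((64, 32, 32))
        ct.data[20:30] = 700.0  # bone slab perpendicular to the beam
        b = single_spot_beam(90.0, 31.0, 31.0)
        d0 = compute_dose(Plan([b], 1.0), ct)

        ct2 = water_ct((64, 32, 32))
        ct2.data[:, :, :] = np.roll(ct.data, 1, axis=1)
        b2 = single_spot_beam(90.0, 33.0, 31.0)  # spot moved +2 mm in u = y
        d1 = compute_dose(Plan([b2], 1.0), ct2)
        np.testing.assert_allclose(
            d1.data[:, 5:-5, 5:-5], np.roll(d0.data, 1, axis=1)[:, 5:-5, 5:-5],
            atol=1e-9 * d0.data.max() + 1e-12,
        )

    def test_beam_validation(self):
        with pytest.raises(ValueError, match="direction"):
            single_spot_beam(100.0, 0.0, 0.0, direction="oblique")
        with pytest.raises(ValueError, match="range"):
            single_spot_beam(50.0, 0.0, 0.0, rs_wet=7.4)  # 50 mm < 74 mm WET
        with pytest.raises(ValueError, match="non-negative"):
            Beam("+x", [100.0], [0.0], [0.0], -np.ones((1, 1, 1)))


class TestBuildSobp:
    def test_single_layer(self):
        ranges, w, flat = build_sobp((120.0, 120.0), 1)
        assert w.tolist() == [1.0] and flat == 1.0

    def test_plateau_flatness(self):
        ranges, w, flat = build_sobp((100.0, 140.0), 12)
        assert flat <= 1.04
        assert np.all(w >= 0)

    def test_weights_non_negative(self):
        for span in ((60, 90), (150, 200)):
            _, w, _ = build_sobp(span, 10)
            assert np.all(w >= 0)


class TestPlanJson:
    def test_round_trip(self, tmp_path):
        ct = water_ct((48, 32, 32))
        ctv = np.zeros(ct.shape, bool)
        ctv[20:26, 12:20, 12:20] = True
        beam = design_beam(ct, ctv, "+x")
        plan = Plan([beam], 54.0, 3.0, 0.035)
        plan_to_json(plan, tmp_path / "plan.json")
        back = plan_from_json(tmp_path / "plan.json")
        assert back.prescription == plan.prescription
        np.testing.assert_allclose(back.beams[0].weights, plan.beams[0].weights)
        d1 = compute_dose(plan, ct)
        d2 = compute_dose(back, ct)
        np.testing.assert_allclose(d1.data, d2.data)
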