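import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdr.volumes import (
    CalibrationCurve,
    DEFAULT_CALIBRATION,
    ROISet,
    Volume,
    expand_external,
    external_from_hu,
    hu_to_rsp,
    read_roiset,
    read_volume,
    write_roiset,
    write_volume,
)


class TestVolumeIO:
    @pytest.mark.parametrize("ext", ["nrrd", "nii", "nii.gz"])
    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (1.0, 1.0, 3.0)])
    def test_round_trip(self, tmp_path, ext, spacing):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(9, 7, 5)), spacing, origin=(1.5, -2.0, 0.0))
        path = tmp_path / f"vol.{ext}"
        write_volume(v, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, v.data)
        np.testing.assert_allclose(back.spacing, v.spacing, atol=1e-6)
        np.testing.assert_allclose(back.origin, v.origin, atol=1e-6)

    def test_unknown_format_rejected(self, tmp_path):
        v = Volume(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError, match="format"):
            write_volume(v, tmp_path / "vol.tiff")

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), tmp_path / "flat.nii")
        with pytest.raises(ValueError, match="3D"):
            read_volume(tmp_path / "flat.nii")

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            Volume(np.zeros((2, 2, 2)), (1.0, 0.0, 1.0))

    def test_roiset_round_trip(self, tmp_path):
        geom = Volume(np.zeros((6, 6, 6)), (2, 2, 2))
        ext = np.ones((6, 6, 6), bool)
        ctv = np.zeros((6, 6, 6), bool)
        ctv[2:4, 2:4, 2:4] = True
        rois = ROISet({"external": ext, "CTV": ctv}, {"external": "external", "CTV": "CTV"})
        write_roiset(rois, tmp_path / "rois", geom)
        back = read_roiset(tmp_path / "rois")
        np.testing.assert_array_equal(back["CTV"], ctv)
        assert back.roles["CTV"] == "CTV"


class TestROISet:
    def test_nesting_enforced(self):
        outer = np.zeros((4, 4, 4), bool)
        outer[1:3] = True
        inner = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="nesting"):
            ROISet(
                {"external": outer, "CTV": inner},
                {"external": "external", "CTV": "CTV"},
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            ROISet({"a": np.zeros((3, 3, 3), bool), "b": np.zeros((4, 4, 4), bool)})


class TestCalibration:
    def test_anchor_identities(self):
        assert hu_to_rsp(Volume(np.full((2, 2, 2), 0.0), (1, 1, 1))).data[0, 0, 0] == 1.000
        assert hu_to_rsp(Volume(np.full((2, 2, 2), -1000.0), (1, 1, 1))).data[0, 0, 0] == 0.001

    def test_midway_is_mean_of_anchors(self):
        # linear interpolation between the (0, 1.000) and (60, 1.04) anchors
        v = Volume(np.full((2, 2, 2), 30.0), (1, 1, 1))
        np.testing.assert_allclose(hu_to_rsp(v).data, (1.000 + 1.04) / 2)

    def test_clamped_outside_range(self):
        v = Volume(np.full((2, 2, 2), -2000.0), (1, 1, 1))
        np.testing.assert_allclose(hu_to_rsp(v).data, 0.001)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError, match="monotonically"):
            CalibrationCurve([(-1024, 0.0), (0, 1.0), (100, 0.5), (3000, 2.0)])

    def test_csv_round_trip(self, tmp_path):
        DEFAULT_CALIBRATION.to_csv(tmp_path / "curve.csv")
        back = CalibrationCurve.from_csv(tmp_path / "curve.csv")
        np.testing.assert_allclose(back.hu, DEFAULT_CALIBRATION.hu)
        np.testing.assert_allclose(back.rsp, DEFAULT_CALIBRATION.rsp)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        hu=st.lists(
            st.floats(min_value=-1024, max_value=3000), min_size=2, max_size=2
        )
    )
    def test_monotone_in_hu(self, hu):
        lo, hi = sorted(hu)
        v = Volume(np.array([[[lo, hi]] * 2] * 2), (1, 1, 1))
        r = hu_to_rsp(v).data
        assert r[0, 0, 0] <= r[0, 0, 1]


class TestExternal:
    def test_cylinder_in_air(self):
        x, y, z = np.mgrid[:30, :30, :10]
        hu = np.where((x - 15) ** 2 + (y - 15) ** 2 <= 100, 0.0, -1000.0)
        mask = external_from_hu(Volume(hu, (1, 1, 1)), threshold=-300)
        assert mask[15, 15, 5]
        assert not mask[0, 0, 5]

    def test_all_air_rejected(self):
        with pytest.raises(ValueError, match="external"):
            external_from_hu(Volume(np.full((5, 5, 5), -1000.0), (1, 1, 1)))

    def test_largest_component_selected(self):
        from scipy import ndimage

        hu = np.full((30, 30, 10), -1000.0)
        hu[2:6, 2:6, 2:6] = 0.0  # small distractor
        hu[10:26, 10:26, 1:9] = 0.0  # the body
        mask = external_from_hu(Volume(hu, (1, 1, 1)))
        _, n = ndimage.label(mask)
        assert n == 1
        assert mask[18, 18, 5] and not mask[3, 3, 3]

    def test_expand_identity_at_zero(self):
        m = np.zeros((8, 8, 8), bool)
        m[3:5, 3:5, 3:5] = True
        np.testing.assert_array_equal(expand_external(m, 0.0, (1, 1, 1)), m)

    def test_expand_margin(self):
        m = np.zeros((11, 11, 11), bool)
        m[5, 5, 5] = True
        out = expand_external(m, 4.0, (1.0, 1.0, 1.0))
        assert out[3, 5, 5] and out[7, 5, 5] and out[5, 5, 3]

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=st.floats(0, 6), b=st.floats(0, 6), seed=st.integers(0, 100))
    def test_expand_monotone_in_width(self, a, b, seed):
        a, b = sorted((a, b))
        rng = np.random.default_rng(seed)
        m = rng.random((10, 10, 10)) > 0.9
        m[5, 5, 5] = True
        small = expand_external(m, a, (1.5, 1.5, 1.5))
        big = expand_external(m, b, (1.5, 1.5, 1.5))
        assert not np.any(small & ~big)
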