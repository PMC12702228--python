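"""Container round-trip and min-max normalization contracts."""

import h5py
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raman3d.cube import (
    HyperspectralCube,
    ScaleRecord,
    min_max_denormalize,
    min_max_normalize,
    read_cube,
    write_cube,
)
from raman3d.errors import FormatError, ShapeError, ValidationError


class TestRoundTrip:
    def test_write_read_identity(self, small_cube, tmp_path):
        path = tmp_path / "cube.h5"
        write_cube(small_cube, path)
        back = read_cube(path)
        # data stored as float32: round-trip is exact at stored precision
        np.testing.assert_array_equal(back.data, small_cube.data.astype(np.float32))
        np.testing.assert_array_equal(back.wavenumbers, small_cube.wavenumbers)
        assert back.pixel_size == small_cube.pixel_size
        assert back.integration_time == small_cube.integration_time
        assert back.provenance == small_cube.provenance

    def test_axis_endpoints_preserved_exactly(self, tmp_path):
        """A 600–1800 cm⁻¹ axis over 812 bands keeps its endpoints bit-exactly."""
        wn = np.linspace(600.0, 1800.0, 812)
        cube = HyperspectralCube(data=np.ones((2, 2, 812)), wavenumbers=wn)
        path = tmp_path / "hela_axis.h5"
        write_cube(cube, path)
        back = read_cube(path)
        assert back.wavenumbers[0] == 600.0
        assert back.wavenumbers[-1] == 1800.0
        np.testing.assert_array_equal(back.wavenumbers, wn)

    def test_full_hela_extent_shape_preserved(self, tmp_path):
        cube = HyperspectralCube(
            data=np.zeros((58, 58, 812), dtype=np.float32),
            wavenumbers=np.linspace(600, 1800, 812),
        )
        path = tmp_path / "hela.h5"
        write_cube(cube, path)
        assert read_cube(path).shape == (58, 58, 812)

    def test_overwrite_requires_flag(self, small_cube, tmp_path):
        path = tmp_path / "cube.h5"
        write_cube(small_cube, path)
        with pytest.raises(FileExistsError):
            write_cube(small_cube, path)
        write_cube(small_cube, path, overwrite=True)  # explicit flag allowed

    def test_missing_wavenumber_axis_is_format_error(self, tmp_path):
        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=np.zeros((2, 2, 3), dtype=np.float32))
        with pytest.raises(FormatError, match="wavenumber_cm1"):
            read_cube(path)

    def test_axis_length_mismatch_is_shape_error(self, tmp_path):
        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=np.zeros((2, 2, 3), dtype=np.float32))
            f.create_dataset("wavenumber_cm1", data=np.arange(5.0))
        with pytest.raises(ShapeError):
            read_cube(path)

    def test_non_increasing_wavenumbers_rejected(self, tmp_path):
        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=np.zeros((2, 2, 3), dtype=np.float32))
            f.create_dataset("wavenumber_cm1", data=np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValidationError):
            read_cube(path)


class TestCubeInvariants:
    def test_rejects_nan(self):
        data = np.zeros((2, 2, 3))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            HyperspectralCube(data=data, wavenumbers=np.arange(3.0))

    def test_rejects_wrong_ndim(self):
        with pytest.raises(ShapeError):
            HyperspectralCube(data=np.zeros((2, 3)), wavenumbers=np.arange(3.0))


class TestMinMaxNormalize:
    def test_closed_form_values(self):
        cube = HyperspectralCube(
            data=np.array([0.0, 5.0, 10.0] * 2).reshape(1, 2, 3),
            wavenumbers=np.arange(3.0),
        )
        out, record = min_max_normalize(cube)
        np.testing.assert_allclose(out.data.ravel()[:3], [0.0, 0.5, 1.0])
        assert record == ScaleRecord(0.0, 10.0, degenerate=False)

    def test_constant_cube_degenerate(self):
        cube = HyperspectralCube(data=np.full((2, 2, 3), 7.0), wavenumbers=np.arange(3.0))
        out, record = min_max_normalize(cube)
        assert record.degenerate
        np.testing.assert_array_equal(out.data, 0.0)
        restored = min_max_denormalize(out, record)
        np.testing.assert_array_equal(restored.data, 7.0)

    def test_global_not_per_band(self):
        """Per-band extrema differ, yet one global (min, max) is used."""
        data = np.zeros((1, 2, 2))
        data[0, :, 0] = [0.0, 1.0]  # band 0 spans [0, 1]
        data[0, :, 1] = [2.0, 4.0]  # band 1 spans [2, 4]
        cube = HyperspectralCube(data=data, wavenumbers=np.arange(2.0))
        out, record = min_max_normalize(cube)
        assert (record.x_min, record.x_max) == (0.0, 4.0)
        np.testing.assert_allclose(out.data[0, :, 1], [0.5, 1.0])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_normalize_invert_recovers_input(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(-50.0, 150.0, size=(3, 4, 5))
        cube = HyperspectralCube(data=data, wavenumbers=np.arange(5.0))
        out, record = min_max_normalize(cube)
        assert out.data.min() == 0.0 and out.data.max() == 1.0
        restored = min_max_denormalize(out, record)
        np.testing.assert_allclose(restored.data, data, rtol=1e-6)

    def test_idempotent(self, rng):
        data = rng.uniform(0, 100, size=(4, 4, 6))
        cube = HyperspectralCube(data=data, wavenumbers=np.arange(6.0))
        once, _ = min_max_normalize(cube)
        twice, _ = min_max_normalize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)
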