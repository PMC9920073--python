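import math

import numpy as np
import pytest

from afm3d.curve_io import (
    ForceCurve,
    ForceVolumeGrid,
    deflection_to_force_indentation,
    detect_contact_point,
    read_force_curve,
    read_force_volume,
    write_force_curve,
    write_force_volume,
)
from afm3d.errors import (
    ConsistencyError,
    DataError,
    FormatError,
    ParameterError,
)
from afm3d.units import NM, NN


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


def _curve_text(rows, units="nm nN", extra_headers=()):
    lines = ["# units: " + units, *extra_headers]
    lines += [f"{h}\t{f}" for h, f in rows]
    return "\n".join(lines) + "\n"


SIMPLE_ROWS = [(0, 0), (100, 1), (200, 3), (300, 6), (400, 10), (500, 15), (600, 21), (700, 28)]


class TestReadForceCurve:
    def test_direct_parse_nm_nn(self, tmp_path):
        p = _write(tmp_path / "c.txt", _curve_text(SIMPLE_ROWS))
        curve = read_force_curve(p)
        np.testing.assert_allclose(curve.h, np.array([r[0] for r in SIMPLE_ROWS]) * NM)
        np.testing.assert_allclose(curve.F, np.array([r[1] for r in SIMPLE_ROWS]) * NN)

    def test_shuffled_rows_sort_invariance(self, tmp_path):
        rng = np.random.default_rng(3)
        shuffled = [SIMPLE_ROWS[i] for i in rng.permutation(len(SIMPLE_ROWS))]
        c1 = read_force_curve(_write(tmp_path / "a.txt", _curve_text(SIMPLE_ROWS)))
        c2 = read_force_curve(_write(tmp_path / "b.txt", _curve_text(shuffled)))
        np.testing.assert_array_equal(c1.h, c2.h)
        np.testing.assert_array_equal(c1.F, c2.F)

    def test_duplicate_depths_averaged(self, tmp_path):
        rows = SIMPLE_ROWS + [(100, 3)]  # duplicate of the 100 nm sample (F=1)
        curve = read_force_curve(_write(tmp_path / "d.txt", _curve_text(rows)))
        assert len(curve) == len(SIMPLE_ROWS)
        idx = np.argmin(np.abs(curve.h - 100 * NM))
        assert curve.F[idx] == pytest.approx(2.0 * NN)

    def test_missing_units_header(self, tmp_path):
        p = _write(tmp_path / "c.txt", "\n".join(f"{h} {f}" for h, f in SIMPLE_ROWS))
        with pytest.raises(FormatError, match="units"):
            read_force_curve(p)

    def test_unparseable_row_names_line(self, tmp_path):
        text = _curve_text(SIMPLE_ROWS) + "not a number either\n"
        with pytest.raises(FormatError, match=r":1?\d"):
            read_force_curve(_write(tmp_path / "c.txt", text))

    def test_too_few_samples(self, tmp_path):
        p = _write(tmp_path / "c.txt", _curve_text(SIMPLE_ROWS[:3]))
        with pytest.raises(DataError, match="samples"):
            read_force_curve(p)

    def test_unknown_unit(self, tmp_path):
        p = _write(tmp_path / "c.txt", _curve_text(SIMPLE_ROWS, units="furlong nN"))
        with pytest.raises(FormatError, match="furlong"):
            read_force_curve(p)

    def test_micron_units_scaled(self, tmp_path):
        p = _write(tmp_path / "c.txt", _curve_text(SIMPLE_ROWS, units="um pN"))
        curve = read_force_curve(p)
        assert curve.h[1] == pytest.approx(100e-6)
        assert curve.F[1] == pytest.approx(1e-12)

    def test_z_d_columns_converted(self, tmp_path):
        # z in nm, d in nm, k = 0.01 N/m -> F = k*d, h = z - d
        rows = [(z, z * 0.1) for z in range(0, 800, 100)]
        text = _curve_text(
            rows, units="nm nm",
            extra_headers=["# columns: z d", "# spring_constant_N_per_m: 0.01"],
        )
        curve = read_force_curve(_write(tmp_path / "zd.txt", text))
        np.testing.assert_allclose(curve.h, np.array([z * 0.9 for z, _ in rows]) * NM)
        np.testing.assert_allclose(curve.F, np.array([d for _, d in rows]) * 0.1 * 0.01 * NM * 10)

    def test_z_d_requires_spring_constant(self, tmp_path):
        rows = [(z, z * 0.1) for z in range(0, 800, 100)]
        text = _curve_text(rows, units="nm nm", extra_headers=["# columns: z d"])
        with pytest.raises(FormatError, match="spring_constant"):
            read_force_curve(_write(tmp_path / "zd.txt", text))


class TestWriteForceCurve:
    def test_round_trip_identity(self, tmp_path, homogeneous_curve):
        p = tmp_path / "out.txt"
        write_force_curve(homogeneous_curve, p)
        back = read_force_curve(p)
        np.testing.assert_allclose(back.h, homogeneous_curve.h, rtol=1e-12)
        np.testing.assert_allclose(back.F, homogeneous_curve.F, rtol=1e-12)

    def test_empty_metadata_still_valid(self, tmp_path):
        curve = ForceCurve(np.arange(8) * 10 * NM + NM, np.arange(8) * NN)
        p = tmp_path / "out.txt"
        write_force_curve(curve, p)
        assert read_force_curve(p).metadata["source_file"] == str(p)

    def test_unicode_probe_id_preserved(self, tmp_path):
        curve = ForceCurve(
            np.arange(8) * 10 * NM + NM, np.arange(8) * NN, metadata={"probe": "µ-sphère #7"}
        )
        p = tmp_path / "out.txt"
        write_force_curve(curve, p)
        assert read_force_curve(p).metadata["probe"] == "µ-sphère #7"

    def test_pixel_index_round_trip(self, tmp_path):
        curve = ForceCurve(np.arange(8) * 10 * NM + NM, np.arange(8) * NN, pixel_index=(3, 5))
        write_force_curve(curve, tmp_path / "p.txt")
        assert read_force_curve(tmp_path / "p.txt").pixel_index == (3, 5)


class TestForceCurveInvariants:
    def test_rejects_non_monotone(self):
        with pytest.raises(DataError):
            ForceCurve(np.array([1, 3, 2, 4, 5, 6, 7, 8.0]) * NM, np.zeros(8))

    def test_rejects_negative_depth(self):
        with pytest.raises(DataError):
            ForceCurve(np.array([-1, 1, 2, 3, 4, 5, 6, 7.0]) * NM, np.zeros(8))

    def test_rejects_nan_force(self):
        F = np.zeros(8)
        F[3] = np.nan
        with pytest.raises(DataError):
            ForceCurve(np.arange(8.0) * NM, F)

    def test_rejects_short(self):
        with pytest.raises(DataError):
            ForceCurve(np.arange(5.0) * NM, np.zeros(5))


def _grid_from_curves(tmp_path, shape=(2, 2)):
    ny, nx = shape
    curves = []
    for r in range(ny):
        row = []
        for c in range(nx):
            h = np.linspace(10, 800, 16) * NM
            F = (1 + r + c) * h * 1e-3
            row.append(ForceCurve(h, F, pixel_index=(r, c)))
        curves.append(row)
    return ForceVolumeGrid(curves, pixel_size=100 * NM)


class TestForceVolume:
    def test_manifest_round_trip_per_pixel(self, tmp_path):
        grid = _grid_from_curves(tmp_path)
        manifest = write_force_volume(grid, tmp_path / "fv", packed=False)
        back = read_force_volume(manifest)
        assert back.shape == (2, 2)
        for r, c, curve in back.iter_pixels():
            np.testing.assert_allclose(curve.h, grid[r, c].h, rtol=1e-12)
            np.testing.assert_allclose(curve.F, grid[r, c].F, rtol=1e-12)

    def test_packed_equals_per_pixel(self, tmp_path):
        grid = _grid_from_curves(tmp_path)
        m1 = write_force_volume(grid, tmp_path / "a", packed=False)
        m2 = write_force_volume(grid, tmp_path / "b", packed=True)
        g1, g2 = read_force_volume(m1), read_force_volume(m2)
        for r, c, curve in g1.iter_pixels():
            np.testing.assert_allclose(curve.h, g2[r, c].h, rtol=1e-12)
            np.testing.assert_allclose(curve.F, g2[r, c].F, rtol=1e-12)

    def test_row_major_addressing(self, tmp_path):
        grid = _grid_from_curves(tmp_path)
        manifest = write_force_volume(grid, tmp_path / "fv", packed=False)
        back = read_force_volume(manifest)
        # pixel (1, 0) is stiffer than (0, 0) by construction
        assert back[1, 0].F[5] > back[0, 0].F[5]
        assert back[1, 0].pixel_index == (1, 0)

    def test_missing_pixel_file_warns(self, tmp_path):
        grid = _grid_from_curves(tmp_path)
        manifest = write_force_volume(grid, tmp_path / "fv", packed=False)
        (tmp_path / "fv" / "pixel_r001_c001.txt").unlink()
        with pytest.warns(UserWarning, match="missing pixel"):
            back = read_force_volume(manifest)
        assert back[1, 1] is None
        assert back.n_missing == 1

    def test_dimension_mismatch(self, tmp_path):
        grid = _grid_from_curves(tmp_path)
        manifest = write_force_volume(grid, tmp_path / "fv", packed=False)
        import json

        doc = json.loads(manifest.read_text())
        doc["paths"][0]["row"] = 5  # outside the declared 2x2 grid
        manifest.write_text(json.dumps(doc))
        with pytest.raises(ConsistencyError):
            read_force_volume(manifest)

    def test_manifest_missing_dims(self, tmp_path):
        p = tmp_path / "m.json"
        p.write_text('{"paths": []}')
        with pytest.raises(FormatError):
            read_force_volume(p)


class TestDeflectionConversion:
    def test_zero_deflection(self):
        z = np.linspace(0, 1e-6, 20)
        curve = deflection_to_force_indentation(z, np.zeros_like(z), 0.01)
        np.testing.assert_array_equal(curve.F, 0.0)
        np.testing.assert_allclose(curve.h, z)

    def test_hand_evaluated_force(self):
        # k = 0.01 N/m, d = 100 nm -> F = 1 nN
        z = np.linspace(0, 1e-6, 20)
        d = np.linspace(0, 100e-9, 20)
        curve = deflection_to_force_indentation(z, d, 0.01)
        assert curve.F[-1] == pytest.approx(1e-9, rel=1e-12)

    def test_inversion_round_trip(self, homogeneous_curve):
        k = 0.01
        d = homogeneous_curve.F / k
        z = homogeneous_curve.h + d
        back = deflection_to_force_indentation(z, d, k)
        np.testing.assert_allclose(back.h, homogeneous_curve.h, rtol=1e-12)
        np.testing.assert_allclose(back.F, homogeneous_curve.F, rtol=1e-12)

    def test_invalid_spring_constant(self):
        z = np.linspace(0, 1e-6, 20)
        with pytest.raises(ParameterError):
            deflection_to_force_indentation(z, np.zeros_like(z), 0.0)

    def test_negative_h_clipped(self):
        z = np.linspace(-1e-7, 1e-6, 30)
        curve = deflection_to_force_indentation(z, np.zeros_like(z), 0.01)
        assert np.all(curve.h >= 0)


class TestContactPointDetection:
    @staticmethod
    def _flat_then_hertz(n=200, split=50):
        z = np.linspace(0, 1000, n)
        sig = np.zeros(n)
        sig[split:] = 1e-3 * (z[split:] - z[split]) ** 1.5
        return z, sig

    def test_construction_oracle(self):
        z, sig = self._flat_then_hertz()
        cp = detect_contact_point(z, sig)
        assert cp.confident
        assert abs(cp.index - 50) <= 2

    def test_pure_noise_low_confidence(self):
        z = np.linspace(0, 1000, 200)
        noise = np.random.default_rng(11).normal(0, 1, 200)
        cp = detect_contact_point(z, noise)
        assert not cp.confident
        assert cp.offset == 0.0

    def test_constant_offset_invariance(self):
        z, sig = self._flat_then_hertz()
        cp1 = detect_contact_point(z, sig)
        cp2 = detect_contact_point(z, sig + 7.5)
        assert cp1.index == cp2.index

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            detect_contact_point(np.arange(10.0), np.zeros(10))
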