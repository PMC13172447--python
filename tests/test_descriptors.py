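"""Cell descriptors (V, d_V, S_A, E, gamma) and Wasserstein comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import voroslice as vs


def _ball_mask(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


class TestCellVolume:
    def test_full_image(self):
        assert vs.cell_volume(np.zeros((10, 10), dtype=int), 0) == 100

    def test_checkerboard(self):
        img = np.indices((4, 4)).sum(axis=0) % 2
        assert vs.cell_volume(img, 0) == 8
        assert vs.cell_volume(img, 1) == 8

    def test_matches_brute_force_scan(self, tiny_pattern):
        vol = vs.voxelize(tiny_pattern)
        for label in (0, 5, 19):
            expected = sum(1 for v in vol.ravel().tolist() if v == label)
            assert vs.cell_volume(vol, label) == expected

    def test_absent_label(self):
        with pytest.raises(KeyError):
            vs.cell_volume(np.zeros((4, 4), dtype=int), 3)

    def test_partition_conservation(self, tiny_pattern):
        vol = vs.voxelize(tiny_pattern)
        total = sum(vs.cell_volume(vol, int(l)) for l in np.unique(vol))
        assert total == vol.size


class TestEquivalentDiameter:
    def test_unit_radius_disk_inversion(self):
        assert vs.equivalent_diameter(np.pi, 2) == pytest.approx(2.0)

    def test_single_voxel_3d(self):
        assert vs.equivalent_diameter(1, 3) == pytest.approx(
            2 * (3 / (4 * np.pi)) ** (1 / 3)
        )

    def test_hundred_pixels_2d(self):
        assert vs.equivalent_diameter(100, 2) == pytest.approx(2 * (100 / np.pi) ** 0.5)

    def test_strictly_increasing_in_volume(self):
        v = np.arange(1, 50)
        for dim in (2, 3):
            d = [vs.equivalent_diameter(x, dim) for x in v]
            assert np.all(np.diff(d) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            vs.equivalent_diameter(0, 2)


class TestSurfaceArea:
    def test_single_cell_periodic_no_boundary(self):
        assert vs.surface_area(np.zeros((8, 8, 8), dtype=int), 0, periodic=True) == 0.0

    def test_digitized_disk_perimeter(self):
        img = _ball_mask((64, 64), (32, 32), 20).astype(int)
        per = vs.surface_area(img, 1)
        assert abs(per - 2 * np.pi * 20) / (2 * np.pi * 20) < 0.03

    def test_digitized_ball_area(self):
        img = _ball_mask((32, 32, 32), (16, 16, 16), 10).astype(int)
        area = vs.surface_area(img, 1)
        assert abs(area - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.05

    def test_ball_bias_within_5pct_and_decreasing(self):
        errs = []
        for r in (5, 10, 20):
            s = 2 * r + 12
            img = _ball_mask((s, s, s), (s // 2,) * 3, r).astype(int)
            area = vs.surface_area(img, 1)
            errs.append(abs(area - 4 * np.pi * r**2) / (4 * np.pi * r**2))
        assert max(errs) < 0.05
        assert errs[-1] <= errs[0]

    def test_periodic_wrap_counted_once(self):
        # ball centered on a corner: identical physical body as a centered ball
        img_c = _ball_mask((40, 40), (20, 20), 8).astype(int)
        grids = np.ogrid[0:40, 0:40]
        d2 = sum(((g - 0 + 20) % 40 - 20) ** 2 for g in grids)
        img_w = (d2 <= 64).astype(int)
        a = vs.surface_area(img_c, 1, periodic=True)
        b = vs.surface_area(img_w, 1, periodic=True)
        assert a == pytest.approx(b, rel=1e-6)


class TestElongation:
    def test_ball_isotropic(self):
        img = _ball_mask((48, 48, 48), (24, 24, 24), 12).astype(int)
        assert vs.elongation(img, 1) == pytest.approx(1.0, abs=0.05)

    def test_pixel_row_is_line(self):
        img = np.zeros((5, 25), dtype=int)
        img[2, 2:22] = 1
        assert vs.elongation(img, 1) == 0.0

    def test_matches_dense_eigendecomposition(self, rng):
        img = (rng.random((20, 20)) < 0.4).astype(int)
        coords = np.argwhere(img == 1).astype(float)
        ev = np.linalg.eigvalsh(np.cov(coords.T))
        assert vs.elongation(img, 1) == pytest.approx(ev[0] / ev[-1])

    def test_single_point_convention(self):
        img = np.zeros((5, 5), dtype=int)
        img[2, 2] = 1
        assert vs.elongation(img, 1) == 1.0

    def test_periodic_unwrapping_of_boundary_cell(self):
        # a 4x12 rectangle crossing the wrap equals the same centered rectangle
        img_c = np.zeros((20, 20), dtype=int)
        img_c[8:12, 4:16] = 1
        img_w = np.zeros((20, 20), dtype=int)
        img_w[8:12, :6] = 1
        img_w[8:12, 14:] = 1
        assert vs.elongation(img_w, 1, periodic=True) == pytest.approx(
            vs.elongation(img_c, 1, periodic=False)
        )


class TestNeighborCount:
    def test_three_stripes_cyclic(self):
        img = np.repeat(np.arange(3), 4)[None, :] * np.ones((6, 1), dtype=int)
        for label in (0, 1, 2):
            assert vs.neighbor_count(img, label, periodic=True) == 2

    def test_two_half_volumes_nonperiodic(self):
        img = np.zeros((8, 8), dtype=int)
        img[4:] = 1
        assert vs.neighbor_count(img, 0) == 1
        assert vs.neighbor_count(img, 1) == 1

    def test_matches_brute_force_adjacency(self, rng):
        L = 12
        S = vs.SeedPointPattern(rng.random((8, 3)) * L, float(L))
        vol = vs.voxelize(S)
        adj = vs.adjacency_sets(vol, periodic=True)
        # brute force: scan all voxel pairs within the 26-neighborhood
        offs = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        expected = {int(l): set() for l in np.unique(vol)}
        for x in range(L):
            for y in range(L):
                for z in range(L):
                    a = int(vol[x, y, z])
                    for dx, dy, dz in offs:
                        b = int(vol[(x + dx) % L, (y + dy) % L, (z + dz) % L])
                        if b != a:
                            expected[a].add(b)
        assert adj == expected

    def test_neighbor_symmetry(self, tiny_pattern):
        vol = vs.voxelize(tiny_pattern)
        adj = vs.adjacency_sets(vol, periodic=True)
        for i, nbrs in adj.items():
            for j in nbrs:
                assert i in adj[j]


class TestWasserstein:
    def test_identical_samples(self, rng):
        x = rng.random(50)
        assert vs.wasserstein_1d(x, x) == 0.0

    def test_closed_form_pairing(self):
        assert vs.wasserstein_1d([0.0, 1.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_reduces_to_sorted_mean_difference(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        expected = np.abs(np.sort(x) - np.sort(y)).mean()
        assert vs.wasserstein_1d(x, y) == pytest.approx(expected)

    @given(st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_translation_property(self, c):
        x = np.array([0.3, 1.7, 2.2, 5.0])
        assert vs.wasserstein_1d(x, x + c) == pytest.approx(abs(c), abs=1e-9)

    def test_metric_spot_checks(self, rng):
        x, y, z = (rng.normal(size=30) for _ in range(3))
        dxy = vs.wasserstein_1d(x, y)
        assert dxy == pytest.approx(vs.wasserstein_1d(y, x))
        assert dxy <= vs.wasserstein_1d(x, z) + vs.wasserstein_1d(z, y) + 1e-12

    def test_unequal_sample_sizes_cdf_integral(self):
        # F_x steps at 0 (height 1); F_y steps at 0.5 (2/3) and 1 (1/3)
        assert vs.wasserstein_1d([0.0], [0.5, 0.5, 1.0]) == pytest.approx(
            0.5 + 1 / 3 * 0.5
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            vs.wasserstein_1d([], [1.0])


class TestDescriptorTable:
    def test_columns_and_partition(self, tiny_pattern):
        vol = vs.voxelize(tiny_pattern)
        sl = vs.extract_all_slices(vol)[5]
        table = vs.descriptor_table(sl, periodic=True)
        assert list(table.columns) == ["label", "V", "d_V", "S_A", "E", "gamma"]
        assert table["V"].sum() == sl.size
        assert (table["E"] >= 0).all() and (table["E"] <= 1).all()
        assert (table["gamma"] <= len(table) - 1).all()


class TestCompareStructures:
    def _table(self, rng, n=30):
        return pd.DataFrame(
            {
                "V": rng.integers(1, 100, n),
                "d_V": rng.random(n) * 10,
                "S_A": rng.random(n) * 50,
                "E": rng.random(n),
                "gamma": rng.integers(1, 12, n),
            }
        )

    def test_identity_gives_zero_errors(self, rng):
        t = self._table(rng)
        cmp = vs.compare_structures(t, t)
        assert np.allclose(cmp["rel_mean_error_pct"], 0)
        assert np.allclose(cmp["wasserstein"], 0)

    def test_doubled_descriptor_gives_100pct(self, rng):
        t = self._table(rng)
        t2 = t.copy()
        t2["E"] = t2["E"] * 2
        cmp = vs.compare_structures(t, t2).set_index("descriptor")
        assert cmp.loc["E", "rel_mean_error_pct"] == pytest.approx(100.0)

    def test_matches_independent_recomputation(self, rng):
        a, b = self._table(rng), self._table(np.random.default_rng(99))
        cmp = vs.compare_structures(a, b).set_index("descriptor")
        for col in ("d_V", "gamma"):
            assert cmp.loc[col, "rel_mean_error_pct"] == pytest.approx(
                abs(b[col].mean() - a[col].mean()) / a[col].mean() * 100
            )
            assert cmp.loc[col, "wasserstein"] == pytest.approx(
                vs.wasserstein_1d(a[col], b[col])
            )

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            vs.compare_structures(self._table(rng).iloc[:0], self._table(rng))
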