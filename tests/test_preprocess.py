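import numpy as np
import pytest

from yieldstab import Crop
from yieldstab.preprocess import (
    PointSet,
    VariogramModel,
    aggregate_blocks,
    dissolve_duplicates,
    filter_outlier_points,
    fit_variogram,
    krige_spherical,
    read_points,
    write_points,
)
from yieldstab.raster_core import GridTransform

from conftest import make_map


def points_from(xs, ys, zs, crop=Crop.MAIZE):
    return PointSet(np.asarray(xs, float), np.asarray(ys, float), np.asarray(zs, float), crop)


def random_cloud(rng, n=200, extent=100.0, level=8.0):
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    z = level + rng.normal(0, 1.0, n)
    return points_from(x, y, z)


class TestOutlierFilter:
    def test_median_bounds(self):
        pts = points_from(range(5), range(5), [0.5, 9, 10, 12, 35])
        kept, removed = filter_outlier_points(pts)
        # median 10 -> bounds (1, 30)
        assert sorted(kept.yields.tolist()) == [9, 10, 12]
        assert removed == 2

    def test_all_equal_all_kept(self):
        pts = points_from(range(4), range(4), [5.0] * 4)
        kept, removed = filter_outlier_points(pts)
        assert len(kept) == 4 and removed == 0

    def test_single_point_is_its_own_median(self):
        kept, removed = filter_outlier_points(points_from([0], [0], [3.0]))
        assert len(kept) == 1 and removed == 0

    def test_removed_plus_retained_is_input(self, rng):
        pts = random_cloud(rng, n=80)
        kept, removed = filter_outlier_points(pts)
        assert len(kept) + removed == 80

    def test_idempotent_when_median_stable(self):
        pts = points_from(range(5), range(5), [0.5, 9, 10, 12, 35])
        once, _ = filter_outlier_points(pts)
        twice, removed = filter_outlier_points(once)
        assert removed == 0
        assert np.array_equal(once.yields, twice.yields)


class TestDissolveDuplicates:
    def test_mean_of_two(self):
        pts = points_from([10, 10], [10, 10], [4.0, 6.0])
        out = dissolve_duplicates(pts)
        assert len(out) == 1 and out.yields[0] == 5.0

    def test_mean_of_three(self):
        pts = points_from([1, 1, 1, 2], [1, 1, 1, 2], [2.0, 2.0, 8.0, 7.0])
        out = dissolve_duplicates(pts)
        assert sorted(out.yields.tolist()) == [4.0, 7.0]

    def test_no_duplicates_identity(self, rng):
        pts = random_cloud(rng, n=30)
        out = dissolve_duplicates(pts)
        assert len(out) == 30


class TestVariogram:
    def test_semivariance_shape(self):
        v = VariogramModel(nugget=0.2, partial_sill=1.0, range_m=50.0)
        assert v(np.array([0.0]))[0] == 0.0  # exact interpolation limit
        assert v(np.array([50.0]))[0] == pytest.approx(1.2)
        assert v(np.array([500.0]))[0] == pytest.approx(1.2)  # sill beyond range

    def test_pure_nugget_process(self, rng):
        pts = random_cloud(rng, n=300)
        v = fit_variogram(pts, max_dist_m=80.0)
        # white noise: structure-free, partial sill small relative to nugget
        assert v.partial_sill / max(v.nugget, 1e-12) < 0.2 or v.range_m < 5.0

    def test_recovers_range_of_spherical_field(self):
        # simulate a Gaussian field with spherical covariance, range 50 m
        rng_ = np.random.default_rng(42)
        n = 400
        x = rng_.uniform(0, 200, n)
        y = rng_.uniform(0, 200, n)
        coords = np.column_stack([x, y])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        true = VariogramModel(nugget=0.0, partial_sill=1.0, range_m=50.0)
        cov = 1.0 - true(d)
        np.fill_diagonal(cov, 1.0)
        z = np.linalg.cholesky(cov + 1e-8 * np.eye(n)) @ rng_.standard_normal(n)
        v = fit_variogram(points_from(x, y, z + 8.0), max_dist_m=150.0)
        assert 30.0 <= v.range_m <= 80.0

    def test_constant_yield_zero_variance(self, rng):
        pts = points_from(rng.uniform(0, 50, 40), rng.uniform(0, 50, 40), [5.0] * 40)
        v = fit_variogram(pts)
        assert v.nugget == 0.0 and v.partial_sill == 0.0


class TestKriging:
    VARIO = VariogramModel(nugget=0.0, partial_sill=1.0, range_m=50.0)

    def test_constant_field_exactness(self, rng):
        x = rng.uniform(0, 20, 40)
        y = rng.uniform(0, 20, 40)
        pts = points_from(x, y, np.full(40, 7.5))
        ymap = krige_spherical(pts, variogram=self.VARIO, pixel_m=5.0)
        assert np.allclose(ymap.values[ymap.valid_mask], 7.5, atol=1e-8)

    def test_translation_equivariance(self, rng):
        pts = random_cloud(rng, n=60, extent=30.0)
        a = krige_spherical(pts, variogram=self.VARIO, pixel_m=5.0)
        shifted = PointSet(pts.x, pts.y, pts.yields + 3.0, pts.crop)
        b = krige_spherical(shifted, variogram=self.VARIO, pixel_m=5.0)
        assert np.array_equal(a.valid_mask, b.valid_mask)
        assert np.allclose(b.values[b.valid_mask] - a.values[a.valid_mask], 3.0, atol=1e-8)

    def test_exact_interpolation_at_data_point(self):
        # 13 points: 12 on a circle, one exactly on a cell center
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        x = np.append(5.0 + 8.0 * np.cos(angles), 5.0)
        y = np.append(5.0 + 8.0 * np.sin(angles), 5.0)
        z = np.append(np.linspace(4, 9, 12), 6.3)
        grid = GridTransform(x_ll=0.0, y_ll=0.0, pixel_size=10.0)
        ymap = krige_spherical(
            points_from(x, y, z), grid=grid, variogram=self.VARIO, shape=(1, 1)
        )
        # cell center (5, 5) coincides with the 13th point; nugget 0 -> exact
        assert ymap.valid_mask[0, 0]
        assert ymap.values[0, 0] == pytest.approx(6.3, abs=1e-8)

    def test_below_min_points_is_nodata(self, rng):
        # 11 points only -> every cell below the 12-neighbor minimum
        x = rng.uniform(0, 10, 11)
        y = rng.uniform(0, 10, 11)
        pts = points_from(x, y, rng.uniform(5, 9, 11))
        with pytest.warns(UserWarning, match="empty map"):
            ymap = krige_spherical(pts, variogram=self.VARIO, pixel_m=5.0)
        assert not ymap.valid_mask.any()


class TestAggregateBlocks:
    def test_constant_field(self):
        m = make_map(np.ones((4, 4)), pixel=2.0)
        out = aggregate_blocks(m, factor=2)
        assert out.shape == (2, 2)
        assert np.allclose(out.values, 1.0)
        assert out.transform.pixel_size == 4.0

    def test_block_mean(self):
        m = make_map(np.array([[1.0, 2.0], [3.0, 4.0]]), pixel=2.0)
        out = aggregate_blocks(m, factor=2)
        assert out.values[0, 0] == 2.5

    def test_mostly_nodata_block_is_nodata(self):
        mask = np.array([[True, False], [False, False]])
        m = make_map(np.ones((2, 2)), mask, pixel=2.0)
        out = aggregate_blocks(m, factor=2)
        assert not out.valid_mask[0, 0]  # 25% valid < 50% rule

    def test_half_valid_block_is_kept(self):
        mask = np.array([[True, True], [False, False]])
        m = make_map(np.array([[1.0, 3.0], [9.0, 9.0]]), mask, pixel=2.0)
        out = aggregate_blocks(m, factor=2)
        assert out.valid_mask[0, 0] and out.values[0, 0] == 2.0


class TestPointsIO:
    def test_round_trip(self, tmp_path, rng):
        pts = random_cloud(rng, n=25)
        write_points(tmp_path / "p.csv", pts)
        back = read_points(tmp_path / "p.csv")
        assert np.allclose(back.x, pts.x) and np.allclose(back.yields, pts.yields)

    def test_tab_dialect_detected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("x\ty\tyield\n1\t2\t8.5\n3\t4\t9.5\n")
        pts = read_points(tmp_path / "p.tsv")
        assert len(pts) == 2 and pts.yields[1] == 9.5

    def test_missing_columns_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="columns"):
            read_points(tmp_path / "bad.csv")
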