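"""Moran machinery, the Dutilleul-corrected correlation test, the
autocovariate and residualization, against brute-force oracles and small
simulations."""

import numpy as np
import pytest

from macrodiv import simulate, spatial
from macrodiv.spatial import SpatialField


def brute_force_moran(values, w):
    """Double-loop Moran's I."""
    z = np.asarray(values, float)
    z = z - z.mean()
    n = len(z)
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
            s0 += w[i, j]
    return n / s0 * num / (z @ z).item()


def grid_field(values_2d, cell_m=200_000.0):
    ny, nx = values_2d.shape
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ids = np.array([f"c{x}_{y}" for x, y in zip(ix.ravel(), iy.ravel())])
    coords = np.column_stack([(ix.ravel() + 0.5) * cell_m, (iy.ravel() + 0.5) * cell_m])
    return SpatialField(ids, coords, np.asarray(values_2d, float).ravel())


def rook_weights(ny, nx):
    n = ny * nx
    w = np.zeros((n, n))
    for y in range(ny):
        for x in range(nx):
            i = y * nx + x
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx:
                    w[i, yy * nx + xx] = 1.0
    return w


class TestMoranI:
    def test_smooth_gradient_positive(self):
        vals = np.arange(1.0, 11.0)
        w = np.zeros((10, 10))
        for i in range(9):
            w[i, i + 1] = w[i + 1, i] = 1.0
        assert spatial.moran_i(vals, w) > 0

    def test_checkerboard_is_minus_one(self):
        ny = nx = 6
        vals = np.indices((ny, nx)).sum(axis=0) % 2
        i = spatial.moran_i(vals.ravel().astype(float), rook_weights(ny, nx))
        assert i == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 15))
            vals = rng.normal(size=n)
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            np.fill_diagonal(w, 0.0)
            if w.sum() == 0:
                w[0, 1] = 1.0
            assert spatial.moran_i(vals, w) == pytest.approx(
                brute_force_moran(vals, w), abs=1e-12
            )

    def test_permutation_mean_near_expectation(self, rng):
        vals = rng.normal(size=20)
        w = rook_weights(4, 5)
        perms = [spatial.moran_i(rng.permutation(vals), w) for _ in range(1000)]
        assert np.mean(perms) == pytest.approx(-1 / 19, abs=0.01)

    def test_constant_field_signalled(self):
        with pytest.raises(spatial.ConstantFieldError):
            spatial.moran_i(np.ones(5), rook_weights(1, 5))


class TestCorrelogram:
    def test_single_class_degenerates_to_global_i(self, rng):
        field = grid_field(rng.normal(size=(4, 5)))
        out = spatial.correlogram(field, n_classes=1, n_perm=49, seed=1)
        d, _ = spatial.distance_classes(field.coords, 1)
        w = (d > 0).astype(float)
        assert out[0]["i"] == pytest.approx(spatial.moran_i(field.values, w))

    def test_autocorrelated_field_first_class_positive(self, rng):
        vals = simulate.simulate_env_field((12, 12), 1000.0, 200.0, rng)
        field = grid_field(vals)
        out = spatial.correlogram(field, n_classes=8, n_perm=99, seed=2)
        assert out[0]["i"] > 0
        assert out[0]["p"] < 0.05

    def test_white_noise_usually_inside_envelope(self, rng):
        hits = 0
        for _ in range(20):
            field = grid_field(rng.normal(size=(6, 6)))
            out = spatial.correlogram(field, n_classes=4, n_perm=99, seed=3)
            hits += out[0]["p"] < 0.05
        assert hits <= 4  # ~1 expected at the 5% level


class TestModifiedTTest:
    def test_identical_fields_r_is_one(self, rng):
        field = grid_field(rng.normal(size=(5, 6)))
        res = spatial.modified_ttest(field, field.with_values(field.values.copy()))
        assert res.r == pytest.approx(1.0)

    def test_r_equals_plain_pearson(self, rng):
        x = grid_field(rng.normal(size=(6, 6)))
        y = x.with_values(rng.normal(size=36))
        res = spatial.modified_ttest(x, y)
        assert res.r == pytest.approx(np.corrcoef(x.values, y.values)[0, 1])

    def test_iid_fields_keep_ess_near_n(self, rng):
        # With no autocorrelation the correction should cost little: the
        # effective sample size stays within 10% of n on average.
        esses = []
        for _ in range(30):
            x = grid_field(rng.normal(size=(10, 20)))
            y = x.with_values(rng.normal(size=200))
            esses.append(spatial.modified_ttest(x, y).ess)
        assert np.mean(esses) > 0.9 * 200

    def test_autocorrelated_fields_shrink_ess(self, rng):
        esses = []
        for _ in range(10):
            x = grid_field(simulate.simulate_env_field((10, 10), 1000.0, 200.0, rng))
            y = x.with_values(
                simulate.simulate_env_field((10, 10), 1000.0, 200.0, rng).ravel()
            )
            esses.append(spatial.modified_ttest(x, y).ess)
        assert np.mean(esses) < 60  # well below n = 100

    def test_constant_field_is_error(self, rng):
        x = grid_field(rng.normal(size=(4, 4)))
        with pytest.raises(spatial.ConstantFieldError):
            spatial.modified_ttest(x, x.with_values(np.ones(16)))

    def test_mismatched_cells_rejected(self, rng):
        x = grid_field(rng.normal(size=(4, 4)))
        y = SpatialField(x.ids[:-1], x.coords[:-1], x.values[:-1])
        with pytest.raises(ValueError):
            spatial.modified_ttest(x, y)


class TestAutocovariate:
    def test_constant_field_reproduced(self, rng):
        field = grid_field(np.full((4, 5), 3.7))
        out = spatial.autocovariate(field, radius_m=250_000.0)
        assert np.allclose(out.values, 3.7)

    def test_three_equidistant_neighbours_equal_weights(self):
        coords = np.array([[0, 0], [1, 0], [-1, 0], [0, 1]], float) * 100_000
        field = SpatialField(np.array(["a", "b", "c", "d"]), coords,
                             np.array([0.0, 1.0, 2.0, 3.0]))
        out = spatial.autocovariate(field, radius_m=100_000.0, weighting="equal")
        assert out.values[0] == pytest.approx(2.0)

    def test_shift_invariance(self, rng):
        field = grid_field(rng.normal(size=(5, 5)))
        a = spatial.autocovariate(field, radius_m=250_000.0)
        b = spatial.autocovariate(field.with_values(field.values + 5.0),
                                  radius_m=250_000.0)
        assert np.allclose(b.values, a.values + 5.0)

    def test_isolated_cell_gets_nan(self):
        coords = np.array([[0, 0], [1, 0], [50, 50]], float) * 100_000
        field = SpatialField(np.array(["a", "b", "c"]), coords, np.arange(3.0))
        out = spatial.autocovariate(field, radius_m=150_000.0)
        assert np.isnan(out.values[2]) and np.isfinite(out.values[0])


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self, rng):
        field = grid_field(rng.normal(size=(4, 5)))
        x = rng.normal(size=(20, 2))
        y = 1.0 + x @ np.array([2.0, -1.0])
        out = spatial.residualize(field.with_values(y), x)
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_predictors(self, rng):
        field = grid_field(rng.normal(size=(5, 8)))
        x = rng.normal(size=(40, 3))
        out = spatial.residualize(field, x)
        assert np.allclose(x.T @ out.values, 0.0, atol=1e-8)
        assert out.values.sum() == pytest.approx(0.0, abs=1e-8)

    def test_rank_deficiency_is_error(self, rng):
        field = grid_field(rng.normal(size=(4, 5)))
        col = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank deficient"):
            spatial.residualize(field, np.column_stack([col, col]))


class TestMoranPermutationTest:
    def test_fixed_seed_deterministic(self, rng):
        field = grid_field(rng.normal(size=(5, 6)))
        a = spatial.moran_permutation_test(field, seed=11, n_perm=199)
        b = spatial.moran_permutation_test(field, seed=11, n_perm=199)
        assert a.p_perm == b.p_perm and a.i == b.i

    def test_clustered_residuals_detected(self, rng):
        detected = 0
        for _ in range(10):
            vals = simulate.simulate_env_field((8, 8), 800.0, 200.0, rng)
            field = grid_field(vals)
            res = spatial.moran_permutation_test(field, seed=5, n_perm=199)
            detected += res.p_perm <= 0.01
        assert detected >= 9

    def test_knn_union_symmetrization(self):
        # three points on a line: the middle is nearest neighbour of both
        # ends, union symmetrization links ends only to the middle.
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0]])
        w = spatial.knn_weights(coords, k=1)
        assert w[0, 1] == w[1, 0] == 1.0
        assert w[2, 1] == w[1, 2] == 1.0
        assert w[0, 2] == 0.0
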