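import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pdmdiff.metrics import (
    chamfer_distance,
    coverage,
    density,
    earth_movers_distance,
    knn_ball_radii,
    l2_distance,
    metric_report,
    mmd,
    pairwise_distance_matrix,
)
from pdmdiff.shape_io import PointSet, ShapeDataset


def brute_force_emd(a, b):
    n = a.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(n)):
        cost = np.linalg.norm(a - b[list(perm)], axis=1).mean()
        best = min(best, cost)
    return best


class TestL2:
    def test_zero_on_identical(self, random_shape):
        assert l2_distance(random_shape, random_shape) == 0.0

    def test_three_four_five(self):
        a = PointSet(np.array([[0.0, 0, 0]]))
        b = PointSet(np.array([[3.0, 4, 0]]))
        assert l2_distance(a, b) == pytest.approx(5.0)

    def test_order_sensitive(self, rng):
        a = rng.standard_normal((6, 3))
        b = rng.standard_normal((6, 3))
        assert l2_distance(a, b) != pytest.approx(l2_distance(a, b[::-1]))

    def test_n_mismatch(self):
        with pytest.raises(ValueError):
            l2_distance(np.zeros((2, 3)), np.zeros((3, 3)))


class TestChamfer:
    def test_zero_on_identical_any_order(self, rng):
        pts = rng.standard_normal((7, 3))
        assert chamfer_distance(pts, rng.permutation(pts)) == pytest.approx(0.0)

    def test_hand_computed_instance(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        # nearest sq dists: a->b (0, 1); b->a (0, 1) => 0.5 + 0.5
        assert chamfer_distance(a, b) == pytest.approx(1.0)

    def test_permutation_invariance_both_arguments(self, rng):
        a = rng.standard_normal((9, 3))
        b = rng.standard_normal((5, 3))
        d = chamfer_distance(a, b)
        assert chamfer_distance(rng.permutation(a), rng.permutation(b)) == pytest.approx(d)


class TestEMD:
    def test_zero_on_permuted_copy(self, rng):
        a = rng.standard_normal((8, 3))
        assert earth_movers_distance(a, rng.permutation(a)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_matches_factorial_oracle(self, n, rng):
        for _ in range(5):
            a = rng.standard_normal((n, 3))
            b = rng.standard_normal((n, 3))
            assert earth_movers_distance(a, b) == pytest.approx(
                brute_force_emd(a, b), abs=1e-9
            )

    def test_bounded_by_identity_assignment(self, rng):
        a = rng.standard_normal((10, 3))
        b = rng.standard_normal((10, 3))
        identity_cost = np.linalg.norm(a - b, axis=1).mean()
        assert earth_movers_distance(a, b) <= identity_cost + 1e-12


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("dist_fn", [chamfer_distance, earth_movers_distance, l2_distance])
    def test_simultaneous_rigid_motion(self, dist_fn, rng):
        a = rng.standard_normal((6, 3))
        b = rng.standard_normal((6, 3))
        R = Rotation.random(random_state=0).as_matrix()
        t = rng.standard_normal(3)
        d0 = dist_fn(a, b)
        d1 = dist_fn(a @ R.T + t, b @ R.T + t)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestPairwiseMatrix:
    @pytest.mark.parametrize("kind", ["CD", "EMD", "L2"])
    def test_matches_per_pair_functions(self, kind, rng):
        A = ShapeDataset(rng.standard_normal((5, 12, 3)))
        B = ShapeDataset(rng.standard_normal((4, 12, 3)))
        mat = pairwise_distance_matrix(A, B, kind)
        from pdmdiff.metrics import _PAIR_FUNCS

        for i in range(5):
            for j in range(4):
                # the blocked CD path accumulates in float32
                tol = 1e-5 if kind == "CD" else 1e-9
                assert mat[i, j] == pytest.approx(
                    _PAIR_FUNCS[kind](A.coords[i], B.coords[j]), rel=tol, abs=tol
                )

    def test_blocked_chamfer_path(self, rng):
        # more shapes than the block size, exercising the blocking logic
        A = ShapeDataset(rng.standard_normal((40, 6, 3)))
        mat = pairwise_distance_matrix(A, A, "CD")
        np.testing.assert_allclose(np.diag(mat), 0.0, atol=1e-6)
        assert mat[3, 17] == pytest.approx(
            chamfer_distance(A.coords[3], A.coords[17]), rel=1e-5, abs=1e-5
        )

    def test_unknown_kind(self, random_dataset):
        with pytest.raises(ValueError):
            pairwise_distance_matrix(random_dataset, random_dataset, "hausdorff")


class TestMMD:
    def test_zero_when_gen_contains_real(self, rng):
        real = ShapeDataset(rng.standard_normal((4, 5, 3)))
        gen = ShapeDataset(np.concatenate([real.coords, rng.standard_normal((3, 5, 3))]))
        # the blocked L2 matrix uses the |a|^2+|b|^2-2ab identity, which
        # carries ~1e-9 floating-point noise at zero
        assert mmd(real, gen, "L2") == pytest.approx(0.0, abs=1e-8)

    def test_single_real_takes_min(self, rng):
        r = rng.standard_normal((1, 5, 3))
        g = rng.standard_normal((2, 5, 3))
        expected = min(l2_distance(r[0], g[0]), l2_distance(r[0], g[1]))
        assert mmd(ShapeDataset(r), ShapeDataset(g), "L2") == pytest.approx(expected)

    def test_matches_double_loop_oracle(self, rng):
        real = ShapeDataset(rng.standard_normal((5, 6, 3)))
        gen = ShapeDataset(rng.standard_normal((5, 6, 3)))
        oracle = np.mean(
            [
                min(chamfer_distance(r, g) for g in gen.coords)
                for r in real.coords
            ]
        )
        assert mmd(real, gen, "CD") == pytest.approx(oracle, rel=1e-6)


def three_singleton_shapes():
    # pairwise L2 distances: d(0,1)=1, d(0,2)=3, d(1,2)=2
    return ShapeDataset(np.array([[[0.0, 0, 0]], [[1.0, 0, 0]], [[3.0, 0, 0]]]))


class TestKnnRadii:
    def test_enumerated_nearest_other(self):
        radii = knn_ball_radii(three_singleton_shapes(), 1, "L2")
        np.testing.assert_allclose(radii, [1.0, 1.0, 2.0])

    def test_extreme_k_gives_max_distance(self):
        radii = knn_ball_radii(three_singleton_shapes(), 2, "L2")
        np.testing.assert_allclose(radii, [3.0, 2.0, 3.0])

    def test_nondecreasing_in_k(self, rng):
        real = ShapeDataset(rng.standard_normal((10, 4, 3)))
        r1 = knn_ball_radii(real, 1, "CD")
        for k in range(2, 9):
            rk = knn_ball_radii(real, k, "CD")
            assert np.all(rk >= r1 - 1e-15)
            r1 = rk

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            knn_ball_radii(three_singleton_shapes(), 3, "L2")


class TestCoverageDensity:
    def test_identity_coverage_is_one(self, rng):
        real = ShapeDataset(rng.standard_normal((8, 4, 3)))
        for kind in ("CD", "EMD", "L2"):
            assert coverage(real, real, k=2, dist=kind) == 1.0

    def test_distant_generated_set_scores_zero(self, rng):
        real = ShapeDataset(rng.standard_normal((6, 4, 3)))
        gen = ShapeDataset(real.coords + 1000.0)
        assert coverage(real, gen, k=2, dist="L2") == 0.0
        assert density(real, gen, k=2, dist="L2") == 0.0

    def test_small_instance_hand_enumeration(self):
        # real at 0,1,3,7 on a line (singleton shapes), k=1
        real = ShapeDataset(np.array([[[0.0, 0, 0]], [[1.0, 0, 0]], [[3.0, 0, 0]], [[7.0, 0, 0]]]))
        # radii (nearest other): [1, 1, 2, 4]
        gen = ShapeDataset(np.array([[[0.5, 0, 0]], [[6.0, 0, 0]], [[30.0, 0, 0]]]))
        # containments: gen0 in balls of real0 (0.5<=1), real1 (0.5<=1);
        # gen1 in ball of real3 (1<=4); gen2 in none
        assert coverage(real, gen, k=1, dist="L2") == pytest.approx(3 / 4)
        assert density(real, gen, k=1, dist="L2") == pytest.approx(3 / (1 * 3))

    def test_density_one_when_single_gen_in_exactly_k_balls(self):
        real = three_singleton_shapes()  # radii for k=1: [1,1,2]
        gen = ShapeDataset(np.array([[[2.0, 0, 0]]]))  # within balls of shapes 1,2? d=2,1,1
        # d(gen, real_i) = 2, 1, 1; containment: real1 (1<=1), real2 (1<=2) => 2 hits
        # with k=2, radii = [3,2,3]; hits: 2<=3, 1<=2, 1<=3 => 3 hits? use k=1 example
        assert density(real, gen, k=1, dist="L2") == pytest.approx(2.0)

    def test_matches_containment_table_oracle(self, rng):
        real = ShapeDataset(rng.standard_normal((7, 3, 3)))
        gen = ShapeDataset(rng.standard_normal((5, 3, 3)))
        k = 2
        mat_rr = pairwise_distance_matrix(real, real, "CD")
        mat_rg = pairwise_distance_matrix(real, gen, "CD")
        radii = np.sort(mat_rr + np.diag([np.inf] * 7), axis=1)[:, k - 1]
        table = mat_rg <= radii[:, None]
        assert coverage(real, gen, k=k, dist="CD") == pytest.approx(table.any(axis=1).mean())
        assert density(real, gen, k=k, dist="CD") == pytest.approx(table.sum() / (k * 5))


def test_metric_report_contains_all_fields(rng):
    real = ShapeDataset(rng.standard_normal((9, 4, 3)))
    gen = ShapeDataset(rng.standard_normal((6, 4, 3)))
    rep = metric_report(real, gen, "cd", k=2)
    d = rep.as_dict()
    assert d["dist"] == "CD" and d["n_real"] == 9 and d["n_gen"] == 6
    assert 0 <= d["coverage"] <= 1 and d["density"] >= 0 and d["mmd"] >= 0
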