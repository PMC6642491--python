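import numpy as np
import pytest

import healtheff as h
from conftest import random_technology
from oracles import sbm_fractional_oracle


def tech(X, Y, rts="crs"):
    return h.DEATechnology(np.asarray(X, float), np.asarray(Y, float), rts=rts)


class TestSBM:
    def test_single_dmu_is_efficient(self):
        res = h.sbm_score(0, tech([[2.0]], [[3.0]], rts="vrs"))
        assert res.score == pytest.approx(1.0)
        assert res.max_slack <= 1e-7

    def test_dominant_dmu_is_efficient_vrs(self):
        # DMU 0 has strictly smallest input and strictly largest output
        res = h.sbm_score(0, tech([[1.0, 2.0, 3.0]], [[5.0, 4.0, 1.0]], rts="vrs"))
        assert res.score == pytest.approx(1.0)

    def test_ray_oracle_crs(self):
        # peers A(1,1), B(2,2); C(2,1) projects onto the ray (t, t):
        # objective (t/2)/t is constant 0.5 along the feasible segment
        res = h.sbm_score(2, tech([[1, 2, 2]], [[1, 2, 1]], rts="crs"))
        assert res.score == pytest.approx(0.5, abs=1e-9)

    def test_score_one_iff_zero_slacks(self, rng):
        for _ in range(20):
            t = random_technology(rng, n=6, rts=rng.choice(["crs", "vrs"]))
            for k in range(t.n):
                res = h.sbm_score(k, t)
                assert res.status == "optimal"
                assert (res.score == 1.0) == (res.max_slack <= 1e-7)

    def test_vrs_not_below_crs(self, rng):
        for _ in range(10):
            Xa = rng.uniform(0.5, 5, (2, 6))
            Ya = rng.uniform(0.5, 5, (2, 6))
            for k in range(6):
                crs = h.sbm_score(k, tech(Xa, Ya, "crs")).score
                vrs = h.sbm_score(k, tech(Xa, Ya, "vrs")).score
                assert vrs >= crs - 1e-8

    def test_units_invariance(self, rng):
        for _ in range(10):
            t = random_technology(rng, n=7)
            base = [h.sbm_score(k, t).score for k in range(t.n)]
            X2, Y2 = t.X.copy(), t.Y.copy()
            X2[0] *= 137.0
            Y2[1] *= 0.003
            scaled = [h.sbm_score(k, tech(X2, Y2, t.rts)).score for k in range(t.n)]
            np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_adding_peer_never_raises_score(self, rng):
        for _ in range(10):
            X = rng.uniform(0.5, 5, (2, 6))
            Y = rng.uniform(0.5, 5, (2, 6))
            before = [h.sbm_score(k, tech(X, Y)).score for k in range(5)]
            # peer 5 dropped vs kept: dropping it cannot lower anyone's score
            Xs, Ys = X[:, :5], Y[:, :5]
            smaller = [h.sbm_score(k, tech(Xs, Ys)).score for k in range(5)]
            assert all(s >= b - 1e-8 for s, b in zip(smaller, before))

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            tech([[1.0, 0.0]], [[1.0, 1.0]])

    @pytest.mark.parametrize("rts", ["crs", "vrs"])
    def test_matches_fractional_oracle_on_small_instances(self, rts):
        rng = np.random.default_rng(11)
        cases = []
        for _ in range(8):
            n = rng.integers(2, 5)
            m = rng.integers(1, 3)
            q = rng.integers(1, 3)
            cases.append((rng.uniform(0.5, 4, (m, n)), rng.uniform(0.5, 4, (q, n))))
        cases.append((np.array([[1., 2., 2.]]), np.array([[1., 2., 1.]])))
        for X, Y in cases:
            t = tech(X, Y, rts)
            for k in range(t.n):
                lp = h.sbm_score(k, t).score
                direct = sbm_fractional_oracle(k, X, Y, rts=rts)
                assert lp == pytest.approx(direct, abs=1e-5)


class TestSuperSBM:
    def test_scaled_peer_crs(self):
        # B(2,2) scaled by 0.5 reproduces A(1,1) exactly -> delta = 1
        res = h.super_sbm_score(0, tech([[1, 2]], [[1, 2]], "crs"))
        assert res.score == pytest.approx(1.0, abs=1e-6)

    def test_unique_convex_combination_vrs(self):
        # lambda_B = 1 forced; reference point (2, 2) dominates via (2, 1):
        # delta = (1 + 1/1) / 1 = 2
        res = h.super_sbm_score(0, tech([[1, 2]], [[1, 2]], "vrs"))
        assert res.score == pytest.approx(2.0, abs=1e-6)

    def test_no_peers_is_infeasible(self):
        res = h.super_sbm_score(0, tech([[1.0]], [[1.0]], "crs"))
        assert res.status == "infeasible"

    def test_at_least_one_for_efficient_units(self, rng):
        for _ in range(5):
            t = random_technology(rng, n=6, rts="crs")
            for k in range(t.n):
                if h.sbm_score(k, t).is_efficient:
                    sup = h.super_sbm_score(k, t)
                    if sup.status == "optimal":
                        assert sup.score >= 1.0 - 1e-7

    def test_units_invariance(self, rng):
        t = random_technology(rng, n=6, rts="crs")
        base = [h.super_sbm_score(k, t).score for k in range(t.n)]
        X2, Y2 = t.X * np.array([[10.], [0.2]]), t.Y * np.array([[5.], [40.]])
        scaled = [h.super_sbm_score(k, tech(X2, Y2, t.rts)).score
                  for k in range(t.n)]
        np.testing.assert_allclose(scaled, base, atol=1e-8)


class TestRadialDistance:
    def test_frontier_point_is_one(self):
        t = tech([[1, 2]], [[1, 2]], "crs")
        res = h.radial_distance([1.0], [1.0], t)
        assert res.score == pytest.approx(1.0, abs=1e-9)

    def test_ray_arithmetic(self):
        res = h.radial_distance([2.0], [1.0], tech([[1.0]], [[1.0]], "crs"))
        assert res.score == pytest.approx(0.5, abs=1e-9)

    def test_cross_period_point_can_exceed_one(self):
        res = h.radial_distance([1.0], [2.0], tech([[1.0]], [[1.0]], "crs"))
        assert res.score == pytest.approx(2.0, abs=1e-9)

    def test_vrs_at_least_crs_in_sample(self, rng):
        t = random_technology(rng, n=6, rts="crs")
        tv = h.DEATechnology(t.X, t.Y, rts="vrs")
        for k in range(t.n):
            a = h.radial_distance(t.X[:, k], t.Y[:, k], t).score
            b = h.radial_distance(t.X[:, k], t.Y[:, k], tv).score
            assert b >= a - 1e-9

    def test_vrs_cross_period_infeasible(self):
        # demanded output above anything the VRS hull can produce
        res = h.radial_distance([1.0], [9.0], tech([[1, 2]], [[1, 2]], "vrs"))
        assert res.status == "infeasible"


class TestCrossSection:
    def make_panel(self, X, Y):
        return h.PanelDataset.from_arrays(np.asarray(X, float)[:, None, :],
                                          np.asarray(Y, float)[:, None, :])

    def test_identical_dmus_all_one(self):
        ds = self.make_panel([[1.0]] * 4, [[2.0]] * 4)
        out = h.evaluate_cross_section(ds, 1, rts="vrs")
        np.testing.assert_allclose(out["score"], 1.0, atol=1e-7)

    def test_three_dmu_toy(self):
        ds = self.make_panel([[1.], [2.], [2.]], [[1.], [2.], [1.]])
        out = h.evaluate_cross_section(ds, 1, rts="crs")
        np.testing.assert_allclose(out["score"], [1.0, 1.0, 0.5], atol=1e-6)

    def test_mixed_scores_with_interior_dominator(self, rng):
        n = 8
        X = rng.uniform(1, 3, (n, 1, 2))
        Y = rng.uniform(1, 3, (n, 1, 2))
        # make DMU 0 dominate: smallest inputs, largest outputs
        X[0] = 0.5
        Y[0] = 4.0
        ds = h.PanelDataset.from_arrays(X, Y)
        out = h.evaluate_cross_section(ds, 1, rts="vrs")
        assert (out["score"] > 1.0 + 1e-9).any()
        assert (out["score"] < 1.0 - 1e-9).any()
        assert set(out["status"]) <= {"optimal", "superSBM_infeasible"}
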