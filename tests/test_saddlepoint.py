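"""Double saddlepoint machinery: CGF identities, saddle solves, tail formula."""

import math

import numpy as np
import pytest

from clusaddle import dsa_midp, exact_midp, observed_statistic
from clusaddle.saddlepoint import (CGFModel, SupportBoundaryError, cgf,
                                   denominator_saddle, r_u_statistics,
                                   solve_numerator_saddle, _dsa_upper)
from clusaddle.scores import ScoreSet, assemble_scores
from conftest import random_scoreset


def model_of(scores):
    return CGFModel.from_scores(scores)


class TestCGF:
    def test_value_and_gradient_at_origin(self, rng):
        s = random_scoreset(rng)
        m = model_of(s)
        blocks = cgf(m, 0.0, np.zeros(m.n_active))
        # with p_i = w_i/n_i: K(0,0) = sum n log(1-p) + sum log(1 + p/(1-p))
        # ... per-subject log(1-p+p) = 0, so K vanishes
        assert blocks["K"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(blocks["Ks"], m.w1, atol=1e-12)

    def test_gradient_at_origin_is_n_p_for_general_p(self, rng):
        s = random_scoreset(rng, (2, 4), (3, 5))
        m0 = model_of(s)
        p = np.clip(rng.uniform(0.2, 0.8, size=m0.n_active), 0.2, 0.8)
        m = CGFModel(m0.a, m0.idx, m0.n, m0.w1, p, m0.fixed_offset)
        blocks = cgf(m, 0.0, np.zeros(m.n_active))
        np.testing.assert_allclose(blocks["Ks"], m.n * p, atol=1e-12)

    def test_derivatives_match_finite_differences(self, rng):
        s = random_scoreset(rng, (2, 4), (2, 5))
        m = model_of(s)
        A = m.n_active
        t = float(rng.normal(scale=0.5))
        sv = rng.normal(scale=0.5, size=A)
        h = 1e-5
        blocks = cgf(m, t, sv)
        # dK/dt
        fd_t = (cgf(m, t + h, sv)["K"] - cgf(m, t - h, sv)["K"]) / (2 * h)
        assert blocks["Kt"] == pytest.approx(fd_t, rel=1e-6, abs=1e-8)
        for i in range(A):
            e = np.zeros(A); e[i] = h
            fd_s = (cgf(m, t, sv + e)["K"] - cgf(m, t, sv - e)["K"]) / (2 * h)
            assert blocks["Ks"][i] == pytest.approx(fd_s, rel=1e-6, abs=1e-8)
            fd_ss = (cgf(m, t, sv + e)["Ks"][i] - cgf(m, t, sv - e)["Ks"][i]) / (2 * h)
            assert blocks["Kss"][i] == pytest.approx(fd_ss, rel=1e-6, abs=1e-8)
            fd_ts = (cgf(m, t + h, sv)["Ks"][i] - cgf(m, t - h, sv)["Ks"][i]) / (2 * h)
            assert blocks["Kts"][i] == pytest.approx(fd_ts, rel=1e-6, abs=1e-8)
        fd_tt = (cgf(m, t + h, sv)["Kt"] - cgf(m, t - h, sv)["Kt"]) / (2 * h)
        assert blocks["Ktt"] == pytest.approx(fd_tt, rel=1e-6, abs=1e-8)

    def test_stable_at_large_tilt(self, rng):
        s = random_scoreset(rng)
        m = model_of(s)
        blocks = cgf(m, 50.0, np.full(m.n_active, -30.0))
        assert np.isfinite(blocks["K"])
        assert np.isfinite(blocks["Kss"]).all()

    def test_nonfinite_input_rejected(self, rng):
        m = model_of(random_scoreset(rng))
        with pytest.raises(ValueError, match="non-finite"):
            cgf(m, math.nan, np.zeros(m.n_active))


class TestNumeratorSaddle:
    def test_zero_tilt_at_permutation_mean(self, rng):
        s = random_scoreset(rng, center=True)
        m = model_of(s)
        sol = solve_numerator_saddle(m, 0.0)   # centered: mean of S is 0
        assert abs(sol.t_hat) < 1e-6
        assert np.abs(sol.s_hat).max() < 1e-6

    def test_residual_is_the_oracle(self, rng):
        for _ in range(20):
            s = random_scoreset(rng)
            m = model_of(s)
            lo, hi = m.support()
            s_obs = float(rng.uniform(lo + 0.05 * (hi - lo),
                                      hi - 0.05 * (hi - lo)))
            sol = solve_numerator_saddle(m, s_obs)
            blocks = cgf(m, sol.t_hat, sol.s_hat)
            assert blocks["Kt"] == pytest.approx(s_obs, abs=1e-7)
            np.testing.assert_allclose(blocks["Ks"], m.w1, atol=1e-7)

    def test_t_hat_strictly_increasing_in_s_obs(self, rng):
        s = random_scoreset(rng, (3, 5), (3, 5))
        m = model_of(s)
        lo, hi = m.support()
        grid = np.linspace(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo), 9)
        t_hats = [solve_numerator_saddle(m, x).t_hat for x in grid]
        assert np.all(np.diff(t_hats) > 0)

    def test_boundary_rejected(self, rng):
        s = random_scoreset(rng)
        m = model_of(s)
        _, hi = m.support()
        with pytest.raises(SupportBoundaryError):
            solve_numerator_saddle(m, hi)


class TestDenominatorSaddle:
    def test_zero_for_empirical_nuisance(self, rng):
        for _ in range(10):
            m = model_of(random_scoreset(rng))
            np.testing.assert_array_equal(denominator_saddle(m), 0.0)

    def test_general_p_solves_constraints(self, rng):
        m0 = model_of(random_scoreset(rng, (2, 4), (3, 5)))
        p = rng.uniform(0.2, 0.8, size=m0.n_active)
        m = CGFModel(m0.a, m0.idx, m0.n, m0.w1, p, m0.fixed_offset)
        s0 = denominator_saddle(m)
        blocks = cgf(m, 0.0, s0)
        np.testing.assert_allclose(blocks["Ks"], m.w1, atol=1e-9)

    def test_symmetric_single_cluster(self):
        s = ScoreSet([0, 0], [1.0, -1.0], [1, 0], np.ones(1))
        m = model_of(assemble_scores(s, "unit", True))
        np.testing.assert_array_equal(denominator_saddle(m), 0.0)


class TestRUStatistics:
    def test_vanish_at_zero_tilt(self, rng):
        s = random_scoreset(rng, center=True)
        m = model_of(s)
        sol = solve_numerator_saddle(m, 1e-9)
        r, u = r_u_statistics(m, sol, 1e-9)
        assert abs(r) < 1e-3 and abs(u) < 1e-3

    def test_signs_agree(self, rng):
        for _ in range(15):
            s = random_scoreset(rng)
            m = model_of(s)
            lo, hi = m.support()
            s_obs = float(rng.uniform(lo + 0.15 * (hi - lo),
                                      hi - 0.15 * (hi - lo)))
            sol = solve_numerator_saddle(m, s_obs)
            if abs(sol.t_hat) < 1e-6:
                continue
            r, u = r_u_statistics(m, sol, s_obs)
            assert np.sign(r) == np.sign(sol.t_hat) == np.sign(u)

    def test_log_space_determinants_match_dense(self, rng):
        """Arrow factorization equals the dense (M+1)x(M+1) determinant."""
        for _ in range(10):
            s = random_scoreset(rng, (2, 6), (2, 5))
            m = model_of(s)
            lo, hi = m.support()
            s_obs = float(rng.uniform(lo + 0.2 * (hi - lo),
                                      hi - 0.2 * (hi - lo)))
            sol = solve_numerator_saddle(m, s_obs)
            if abs(sol.t_hat) < 1e-6:
                continue
            r, u = r_u_statistics(m, sol, s_obs)
            A = m.n_active
            H = np.zeros((A + 1, A + 1))
            H[0, 0] = sol.num["Ktt"]
            H[0, 1:] = H[1:, 0] = sol.num["Kts"]
            H[1:, 1:] = np.diag(sol.num["Kss"])
            dense = sol.t_hat * math.sqrt(
                abs(np.linalg.det(H)) / np.prod(sol.den["Kss"]))
            assert u == pytest.approx(dense, rel=1e-8)


class TestDsaMidp:
    def test_degenerate_all_zero_scores(self):
        s = ScoreSet([0, 0], [0.0, 0.0], [1, 0], np.ones(1))
        with pytest.raises(ValueError, match="degenerate"):
            dsa_midp(s)

    def test_oracle_agreement_small_instances(self, rng):
        """DSA tracks exact enumeration; accuracy tightens with lattice size."""
        errs = []
        for _ in range(60):
            s = random_scoreset(rng, (5, 7), (3, 4))
            errs.append(abs(dsa_midp(s, "upper") - exact_midp(s, "upper")))
        errs = np.array(errs)
        assert errs.max() <= 0.06
        assert np.median(errs) <= 0.005

    def test_upper_lower_complementarity(self, rng):
        for _ in range(20):
            s = random_scoreset(rng, (3, 6), (2, 5))
            gap = dsa_midp(s, "upper") + dsa_midp(s, "lower") - 1.0
            assert abs(gap) <= 2e-3

    def test_scale_invariance(self, rng):
        s = random_scoreset(rng, (3, 5), (3, 5))
        p1 = dsa_midp(s, "upper")
        scaled = ScoreSet(s.cluster, 7.3 * s.scores, s.arm, s.v,
                          centered=s.centered)
        assert dsa_midp(scaled, "upper") == pytest.approx(p1, abs=1e-9)

    def test_inactive_clusters_do_not_matter(self, rng):
        s = random_scoreset(rng, (3, 5), (2, 5))
        p1 = dsa_midp(s, "upper")
        # append one all-treated, one all-control and one constant-score cluster
        M = s.n_clusters
        cluster = np.concatenate([s.cluster, [M] * 2, [M + 1] * 2, [M + 2] * 3])
        scores = np.concatenate([s.scores, [1.0, -1.0], [2.0, -2.0], [0, 0, 0]])
        arm = np.concatenate([s.arm, [1, 1], [0, 0], [1, 0, 1]])
        v = np.concatenate([s.v, [1.0, 1.0, 1.0]])
        s2 = ScoreSet(cluster, scores, arm, v)
        assert dsa_midp(s2, "upper") == pytest.approx(p1, abs=1e-9)

    def test_monotone_decreasing_in_s_obs(self, rng):
        s = random_scoreset(rng, (4, 6), (3, 5))
        m = CGFModel.from_scores(s)
        lo, hi = m.support()
        # interior of the attainable range; right at the lattice boundary
        # the continuous tail formula is no longer reliable
        grid = np.linspace(lo + 0.08 * (hi - lo), hi - 0.08 * (hi - lo), 25)
        ps = [_dsa_upper(m, float(x)) for x in grid]
        assert np.all(np.diff(ps) < 1e-12)

    def test_boundary_atom_convention(self):
        # single active pair cluster: S in {-1, +1}; at the max the mid-p
        # is half the boundary atom, 0.25
        s = assemble_scores(ScoreSet([0, 0], [1.0, 2.0], [0, 1], np.ones(1)),
                            "unit", True)
        assert observed_statistic(s) == pytest.approx(0.5)
        assert dsa_midp(s, "upper") == pytest.approx(0.25)
        assert dsa_midp(s, "lower") == pytest.approx(0.75)

    def test_two_sided_rule(self, rng):
        s = random_scoreset(rng, (3, 5), (3, 5))
        vals = dsa_midp(s, "all")
        assert vals["two_sided"] == pytest.approx(
            min(1.0, 2 * min(vals["upper"], vals["lower"])))

    def test_small_t_window_is_smooth(self, rng):
        """Mid-p is continuous across the near-mean interpolation window."""
        s = random_scoreset(rng, (4, 6), (3, 5))
        m = CGFModel.from_scores(s)
        sol = solve_numerator_saddle(m, 0.0)
        sigma2 = sol.den["Ktt"] - float(
            np.sum(sol.den["Kts"] ** 2 / sol.den["Kss"]))
        eps = np.array([-3e-3, -1e-3, -3e-4, 0.0, 3e-4, 1e-3, 3e-3]) * sigma2
        ps = np.array([_dsa_upper(m, float(e)) for e in eps])
        assert np.all(np.diff(ps) <= 1e-12)
        assert np.abs(ps - 0.5).max() < 5e-2
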