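"""Power formulas, sample-size solvers, and the joint interaction test."""

import numpy as np
import pytest

from trihet.power import (
    TestSpec,
    UnattainablePowerError,
    mv_omega4,
    mv_power,
    mv_required_clusters,
    power_contour,
    required_clusters,
    required_clusters_ate,
    required_clusters_hte,
    solve_dimension,
    wald_power,
)
from trihet.variance import (
    DesignSpec,
    ModifierModel,
    OutcomeModel,
    ate_unit_variance,
    hte_unit_variance,
    with_dimensions,
)


class TestWaldPower:
    def test_reference_scenario(self):
        d = DesignSpec(42, 4, 20, "cluster")
        assert wald_power(4.2147, d, TestSpec(effect=0.1)) == pytest.approx(
            0.806, abs=5e-4
        )

    def test_null_effect_gives_size(self):
        d = DesignSpec(10, 4, 20, "cluster")
        pw = wald_power(4.0, d, TestSpec(effect=1e-12, type1=0.05))
        assert pw == pytest.approx(0.05, abs=1e-6)

    def test_t_reference_scenario(self):
        d = DesignSpec(60, 4, 20, "cluster")
        test = TestSpec(effect=0.2, reference="t_betweenwithin")
        assert wald_power(23.6, d, test) == pytest.approx(0.801, abs=5e-4)

    def test_t_power_below_normal_and_vanishing_gap(self):
        test_t = TestSpec(effect=0.2, reference="t_betweenwithin")
        test_n = TestSpec(effect=0.2, reference="normal")
        gaps = []
        for n_c in (6, 30, 300):
            d = DesignSpec(n_c, 4, 20, "cluster")
            pt = wald_power(23.6, d, test_t)
            pn = wald_power(23.6, d, test_n)
            assert pt < pn
            gaps.append(pn - pt)
        assert gaps[-1] < gaps[0] and gaps[-1] < 1e-3

    def test_t_reference_requires_enough_clusters(self):
        with pytest.raises(ValueError, match="n_c > 2"):
            wald_power(4.0, DesignSpec(2, 4, 20), TestSpec(effect=0.2, reference="t_betweenwithin"))

    def test_monotonicities(self):
        base = dict(unit_variance=6.0, test=TestSpec(effect=0.1))
        p_nc = [
            wald_power(6.0, DesignSpec(n, 4, 20), TestSpec(effect=0.1)) for n in (10, 20, 40)
        ]
        assert np.all(np.diff(p_nc) > 0)
        p_eff = [
            wald_power(6.0, DesignSpec(20, 4, 20), TestSpec(effect=e)) for e in (0.05, 0.1, 0.2)
        ]
        assert np.all(np.diff(p_eff) > 0)
        p_alpha = [
            wald_power(6.0, DesignSpec(20, 4, 20), TestSpec(effect=0.1, type1=a))
            for a in (0.01, 0.05, 0.1)
        ]
        assert np.all(np.diff(p_alpha) > 0)
        p_var = [
            wald_power(v, DesignSpec(20, 4, 20), TestSpec(effect=0.1)) for v in (4.0, 6.0, 9.0)
        ]
        assert np.all(np.diff(p_var) < 0)

    def test_balanced_allocation_maximizes_power(self):
        o = OutcomeModel(alpha0=0.05, alpha1=0.02)
        mod = ModifierModel(rho0=0.2, rho1=0.1)
        powers = []
        for alloc in (0.2, 0.35, 0.5, 0.65, 0.8):
            d = DesignSpec(20, 4, 20, "cluster", alloc)
            sigma4 = hte_unit_variance(d, o, mod).unit_variance
            powers.append(wald_power(sigma4, d, TestSpec(effect=0.1)))
        assert int(np.argmax(powers)) == 2


class TestRequiredClusters:
    def test_table_scenario(self):
        d = DesignSpec(2, 4, 20, "cluster")
        o = OutcomeModel(alpha0=0.015, alpha1=0.01)
        mod = ModifierModel(rho0=0.15, rho1=0.1)
        res = required_clusters_hte(d, o, mod, TestSpec(effect=0.1))
        assert res.rounded == 42
        assert res.rounded % 2 == 0 and res.rounded >= res.raw_solution
        assert res.achieved_power >= 0.8

    def test_hali(self):
        d = DesignSpec(2, 4, 25, "cluster")
        o = OutcomeModel(alpha0=0.104, alpha1=0.008)
        mod = ModifierModel(rho0=0.2, rho1=0.1)
        assert required_clusters_hte(d, o, mod, TestSpec(effect=0.12)).rounded == 24

    def test_ate_t_reference_iterates(self):
        d = DesignSpec(2, 4, 20, "cluster")
        o = OutcomeModel(alpha0=0.015, alpha1=0.01)
        res = required_clusters_ate(
            d, o, TestSpec(effect=0.2, reference="t_betweenwithin")
        )
        # normal-reference rounding alone would give 20; the t criterion is
        # stricter and needs one more even step
        assert res.rounded == 22
        normal = required_clusters_ate(d, o, TestSpec(effect=0.2))
        assert normal.rounded == 20

    def test_minimality(self):
        d = DesignSpec(2, 4, 20, "cluster")
        o = OutcomeModel(alpha0=0.015, alpha1=0.01)
        mod = ModifierModel(rho0=0.15, rho1=0.1)
        test = TestSpec(effect=0.1)
        res = required_clusters_hte(d, o, mod, test)
        sigma4 = hte_unit_variance(d, o, mod).unit_variance
        below = wald_power(sigma4, with_dimensions(d, n_c=res.rounded - 2), test)
        assert below < test.target_power <= res.achieved_power

    def test_subcluster_randomization_plain_ceiling(self):
        d = DesignSpec(2, 8, 63, "subcluster")
        o = OutcomeModel(alpha0=0.01, alpha1=0.005)
        mod = ModifierModel(rho0=0.1, rho1=0.05, kind="binary", prevalence=0.8)
        res = required_clusters_hte(d, o, mod, TestSpec(effect=0.2))
        assert res.rounded == 10
        assert res.raw_solution == pytest.approx(9.909, abs=2e-3)


class TestSolveDimension:
    def test_consistency_with_required_clusters(self):
        d = DesignSpec(2, 8, 50, "cluster")
        o = OutcomeModel(alpha0=0.1, alpha1=0.05)
        mod = ModifierModel(rho0=0.5, rho1=0.3)
        test = TestSpec(effect=0.1)
        direct = required_clusters_hte(d, o, mod, test)
        solved = solve_dimension("n_c", d, o, test, modifier=mod)
        assert solved.rounded == direct.rounded == 14

    def test_solve_subcluster_count(self):
        d = DesignSpec(10, 2, 20, "cluster")
        o = OutcomeModel(alpha0=0.015, alpha1=0.01)
        mod = ModifierModel(rho0=0.15, rho1=0.1)
        test = TestSpec(effect=0.1)
        res = solve_dimension("n_s", d, o, test, modifier=mod)
        at = hte_unit_variance(with_dimensions(d, n_s=res.rounded), o, mod).unit_variance
        assert wald_power(at, with_dimensions(d, n_s=res.rounded), test) >= 0.8
        prev = hte_unit_variance(with_dimensions(d, n_s=res.rounded - 1), o, mod).unit_variance
        assert wald_power(prev, with_dimensions(d, n_s=res.rounded - 1), test) < 0.8

    def test_unattainable_ate_plateau(self):
        # ATE under cluster randomization: lambda_3 grows linearly in m, so
        # power plateaus below target for a small fixed number of clusters
        d = DesignSpec(4, 4, 10, "cluster")
        o = OutcomeModel(alpha0=0.1, alpha1=0.05)
        with pytest.raises(UnattainablePowerError):
            solve_dimension(
                "m", d, o, TestSpec(effect=0.05), estimand="ate", cap=10**5
            )

    def test_hte_power_in_m_approaches_limit_bound_shape(self):
        # the HTE design effect is bounded in m, so the per-participant
        # information stabilizes: sigma_4^2 at huge m matches the limit form
        o = OutcomeModel(alpha0=0.1, alpha1=0.05)
        mod = ModifierModel(rho0=0.1, rho1=0.05)
        d = DesignSpec(4, 4, 10**5, "cluster")
        sigma4 = hte_unit_variance(d, o, mod).unit_variance
        limit = 4.0 * (1 - 0.1) / (1 - 0.1)
        assert sigma4 == pytest.approx(limit, rel=1e-3)


class TestMultivariate:
    def setup_method(self):
        self.outcome = OutcomeModel(alpha0=0.05, alpha1=0.02)

    def _scalar_blocks(self, sigma2_x, r0, r1):
        return (
            np.array([[sigma2_x]]),
            np.array([[sigma2_x * r0]]),
            np.array([[sigma2_x * r1]]),
        )

    @pytest.mark.parametrize(
        "level,n_s,m", [("cluster", 3, 4), ("subcluster", 4, 3), ("participant", 3, 4)]
    )
    def test_p1_reduces_to_scalar_formula(self, level, n_s, m):
        d = DesignSpec(2, n_s, m, level)
        mod = ModifierModel(rho0=0.3, rho1=0.1, sigma2_x=2.0)
        omega = mv_omega4(d, self.outcome, [0.5], *self._scalar_blocks(2.0, 0.3, 0.1))
        if level == "cluster":
            scalar = hte_unit_variance(d, self.outcome, mod).unit_variance
            assert omega[0, 0] * d.n_s * d.m == pytest.approx(scalar, abs=1e-10)
        else:
            # exact expected information at lower levels (the scalar closed
            # form is asymptotic there); compare against the dense oracle
            from _oracles import oracle_hte_unit_variance

            orc = oracle_hte_unit_variance(level, n_s, m, 0.5, 0.05, 0.02, 0.3, 0.1,
                                           sigma2_x=2.0, mu_x=0.5)
            assert omega[0, 0] * d.n_s * d.m == pytest.approx(orc, abs=1e-8)

    def test_p2_independent_equals_two_univariate(self):
        d = DesignSpec(2, 3, 4, "cluster")
        s = np.diag([1.0, 1.0])
        b0 = np.diag([0.3, 0.3])
        b1 = np.diag([0.1, 0.1])
        omega = mv_omega4(d, self.outcome, [0.0, 0.0], s, b0, b1)
        uni = mv_omega4(d, self.outcome, [0.0], *self._scalar_blocks(1.0, 0.3, 0.1))
        assert np.allclose(np.diag(omega), uni[0, 0])
        assert abs(omega[0, 1]) < 1e-12

    def test_p2_matches_monte_carlo_information(self):
        """Empirical average per-cluster GLS information over simulated
        modifier draws and balanced allocations matches the closed form."""
        from _oracles import dense_nested_exchangeable

        rng = np.random.default_rng(17)
        n_s, m, p = 2, 3, 2
        d = DesignSpec(2, n_s, m, "cluster")
        s = np.array([[1.0, 0.4], [0.4, 2.0]])
        b0 = 0.3 * s
        b1 = 0.1 * s
        omega = mv_omega4(d, self.outcome, [0.2, -0.1], s, b0, b1)
        n = n_s * m
        rinv = np.linalg.inv(dense_nested_exchangeable(n_s, m, 0.05, 0.02))
        # covariance of stacked per-participant modifier pairs
        from trihet.icc import block_nested_exchangeable

        chol = np.linalg.cholesky(block_nested_exchangeable(n_s, m, s, b0, b1).dense())
        n_sim = 40000
        q = 2 + 2 * p
        info = np.zeros((q, q))
        mu = np.array([0.2, -0.1])
        for _ in range(n_sim):
            x = (chol @ rng.normal(size=n * p)).reshape(n, p) + mu
            wsign = rng.choice([-0.5, 0.5])
            z = np.column_stack([np.ones(n), np.full(n, wsign), x, wsign * x])
            info += z.T @ rinv @ z
        info /= n_sim
        omega_mc = np.linalg.inv(info)[2 + p :, 2 + p :]
        rel = np.abs(omega_mc - omega) / np.abs(omega).max()
        assert rel.max() < 0.05

    def test_mv_power_basics(self):
        omega = np.array([[2.0]])
        d = DesignSpec(30, 4, 20)
        from trihet.power import wald_power as wp

        scalar = wp(2.0 * 80, d, TestSpec(effect=0.1))
        joint = mv_power(omega, 30, [0.1], 0.05)
        assert joint == pytest.approx(scalar, abs=1e-10)
        assert mv_power(np.eye(2), 30, [0.0, 0.0], 0.05) == pytest.approx(0.05)

    def test_noncentrality_quadratic_in_effect(self):
        from scipy import stats

        omega = np.array([[1.0, 0.2], [0.2, 2.0]])
        eff = np.array([0.1, 0.05])
        ncp1 = 30 * eff @ np.linalg.solve(omega, eff)
        ncp2 = 30 * (2 * eff) @ np.linalg.solve(omega, 2 * eff)
        assert ncp2 == pytest.approx(4 * ncp1)
        assert mv_power(omega, 30, 2 * eff) > mv_power(omega, 30, eff)

    def test_mv_required_clusters_minimality_and_joint_cost(self):
        d = DesignSpec(2, 4, 20, "cluster")
        s = np.eye(2)
        b0 = 0.15 * np.eye(2)
        b1 = 0.1 * np.eye(2)

        def omega_fn(n_c):
            return mv_omega4(d, OutcomeModel(alpha0=0.015, alpha1=0.01),
                             [0.0, 0.0], s, b0, b1)

        # a single-coordinate alternative tested jointly: same noncentrality,
        # one extra degree of freedom, hence more clusters than the scalar test
        test = TestSpec(effect=[0.1, 0.0], target_power=0.8)
        res = mv_required_clusters(omega_fn, [0.1, 0.0], test, d)
        assert mv_power(omega_fn(res.rounded), res.rounded, [0.1, 0.0]) >= 0.8
        prev = res.rounded - 2
        assert mv_power(omega_fn(prev), prev, [0.1, 0.0]) < 0.8

        def omega_uni(n_c):
            return mv_omega4(d, OutcomeModel(alpha0=0.015, alpha1=0.01),
                             [0.0], np.eye(1), 0.15 * np.eye(1), 0.1 * np.eye(1))

        uni = mv_required_clusters(omega_uni, [0.1], TestSpec(effect=0.1), d)
        assert res.rounded > uni.rounded  # joint test needs more clusters
        # p = 1 chi-square route agrees with the normal-reference solver
        direct = required_clusters_hte(
            d,
            OutcomeModel(alpha0=0.015, alpha1=0.01),
            ModifierModel(rho0=0.15, rho1=0.1),
            TestSpec(effect=0.1),
        )
        assert abs(uni.rounded - direct.rounded) <= 2


class TestPowerContour:
    def setup_method(self):
        self.design = DesignSpec(24, 4, 25, "cluster")
        self.outcome = OutcomeModel(alpha0=0.104, alpha1=0.008)
        self.modifier = ModifierModel(rho0=0.2, rho1=0.1)
        self.test = TestSpec(effect=0.12)

    def test_power_decreases_in_rho0(self):
        table = power_contour(
            self.design, self.outcome, self.modifier, self.test,
            primary_values=np.linspace(0.0, 0.5, 6),
            ratio_values=[0.5],
            vary="covariate",
        )
        assert table.feasible.all()
        assert np.all(np.diff(table.power.to_numpy()) <= 1e-12)

    def test_subcluster_randomization_flat_in_rho1(self):
        d = DesignSpec(10, 8, 63, "subcluster")
        o = OutcomeModel(alpha0=0.01, alpha1=0.005)
        mod = ModifierModel(rho0=0.1, rho1=0.05, kind="binary", prevalence=0.8)
        table = power_contour(
            d, o, mod, TestSpec(effect=0.2),
            primary_values=[0.1], ratio_values=np.linspace(0, 1, 6),
            vary="covariate",
        )
        assert table.power.nunique() == 1

    def test_degenerate_grid_equals_wald_power(self):
        table = power_contour(
            self.design, self.outcome, self.modifier, self.test,
            primary_values=[0.2], ratio_values=[0.5], vary="covariate",
        )
        sigma4 = hte_unit_variance(self.design, self.outcome, self.modifier).unit_variance
        assert table.power.iloc[0] == pytest.approx(
            wald_power(sigma4, self.design, self.test)
        )

    def test_infeasible_points_flagged_not_dropped(self):
        table = power_contour(
            self.design, OutcomeModel(alpha0=0.0, alpha1=0.0), self.modifier,
            self.test, primary_values=[0.3], ratio_values=[-5.0, 0.5],
            vary="outcome",
        )
        assert len(table) == 2
        assert not table.feasible.iloc[0] and np.isnan(table.power.iloc[0])
        assert table.feasible.iloc[1]
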