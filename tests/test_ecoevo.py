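"""Reaction norms, equilibria, stability, invasion analysis and G×E decomposition."""

import math
import warnings

import numpy as np
import pytest

from traitweb import (
    CRParams,
    Genotype,
    ReactionNorm,
    ResourceEnvironment,
    crossing_temperature,
    decompose_variance,
    equilibrium,
    evaluate_norm,
    favoured_genotype,
    invasion_fitness,
    jacobian,
    params_at,
    rhs,
    simulate_trajectory,
    stability,
    temperature_sweep,
)
from traitweb.errors import (
    InfeasibleEquilibriumError,
    InfeasibleResidentError,
    InsufficientDesignError,
    InvalidStateError,
    OutOfRangeError,
    ParameterFloorWarning,
)
from traitweb.synthetic import random_feasible_params


def _genotype(gid, a=(1.0, 0.0), m=(0.6, 0.0), e=(0.5, 0.0)):
    return Genotype(
        id=gid,
        norm_a=ReactionNorm(value_at_ref=a[0], slope=a[1]),
        norm_m=ReactionNorm(value_at_ref=m[0], slope=m[1]),
        norm_e=ReactionNorm(value_at_ref=e[0], slope=e[1]),
    )


class TestReactionNorm:
    def test_flat_norm_constant(self):
        n = ReactionNorm(value_at_ref=0.7)
        assert all(evaluate_norm(n, T) == 0.7 for T in (-5.0, 15.0, 40.0))

    def test_linear_arithmetic(self):
        n = ReactionNorm(value_at_ref=0.5, slope=0.01)
        assert evaluate_norm(n, 25.0) == pytest.approx(0.6, abs=1e-14)

    def test_equal_at_reference_regardless_of_slope(self):
        """Genotypes sharing value_at_ref share the phenotype at T_ref."""
        for slope in (-0.2, 0.0, 0.3):
            n = ReactionNorm(value_at_ref=1.2, slope=slope)
            assert evaluate_norm(n, 15.0) == pytest.approx(1.2, abs=1e-14)

    def test_quadratic_peak_anchored_and_humped(self):
        n = ReactionNorm(
            value_at_ref=1.0, form="quadratic-peak", peak_temperature=25.0, curvature=-0.01
        )
        assert evaluate_norm(n, 15.0) == pytest.approx(1.0, abs=1e-14)
        assert evaluate_norm(n, 25.0) > evaluate_norm(n, 15.0)
        assert evaluate_norm(n, 25.0) > evaluate_norm(n, 35.0)
        # symmetric about the peak
        assert evaluate_norm(n, 20.0) == pytest.approx(evaluate_norm(n, 30.0), rel=1e-12)

    def test_flooring_warns(self):
        n = ReactionNorm(value_at_ref=0.1, slope=-0.05)
        with pytest.warns(ParameterFloorWarning):
            v = evaluate_norm(n, 40.0)
        assert v == pytest.approx(1e-6)


class TestParamsAt:
    ENV = ResourceEnvironment()

    def test_flat_norms_temperature_independent(self):
        g = _genotype("A")
        env = ResourceEnvironment(
            norm_r=ReactionNorm(value_at_ref=1.0), norm_K=ReactionNorm(value_at_ref=10.0)
        )
        p15, p35 = params_at(g, env, 15.0), params_at(g, env, 35.0)
        assert (p15.r, p15.K, p15.a, p15.e, p15.m) == (p35.r, p35.K, p35.a, p35.e, p35.m)

    def test_mortality_increases_with_temperature(self):
        g = _genotype("A", m=(0.6, 0.02))
        assert params_at(g, self.ENV, 35.0).m > params_at(g, self.ENV, 15.0).m

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(OutOfRangeError):
            params_at(_genotype("A"), self.ENV, 60.0)

    def test_floored_parameter_flagged(self):
        g = _genotype("A", m=(0.1, -0.05))
        with pytest.warns(ParameterFloorWarning):
            p = params_at(g, self.ENV, 40.0)
        assert p.floored and p.m == pytest.approx(1e-6)


class TestEquilibrium:
    def test_worked_closed_form(self, worked_params):
        eq = equilibrium(worked_params)
        assert eq.R_star == pytest.approx(2.0, abs=1e-15)
        assert eq.C_star == pytest.approx(0.8, abs=1e-15)
        assert eq.feasible

    def test_feasibility_boundary(self):
        p = CRParams(r=1.0, K=1.0, a=1.0, e=0.5, m=1.0)  # R* = 2 >= K
        eq = equilibrium(p)
        assert not eq.feasible and eq.C_star <= 0

    def test_rhs_vanishes_at_equilibrium(self):
        for p in random_feasible_params(50, seed=11):
            eq = equilibrium(p)
            dR, dC = rhs((eq.R_star, eq.C_star), p)
            assert abs(dR) < 1e-12 and abs(dC) < 1e-12


class TestRhs:
    def test_extinction_fixed_point(self, worked_params):
        assert rhs((0.0, 0.0), worked_params) == (0.0, 0.0)

    def test_resource_only_fixed_point(self, worked_params):
        dR, dC = rhs((worked_params.K, 0.0), worked_params)
        assert dR == pytest.approx(0.0, abs=1e-14) and dC == 0.0

    def test_negative_densities_rejected(self, worked_params):
        with pytest.raises(InvalidStateError):
            rhs((-1.0, 0.5), worked_params)


class TestJacobianStability:
    def test_worked_jacobian_entries(self, worked_params):
        J = jacobian(worked_params)
        assert np.allclose(J, [[-0.2, -2.0], [0.4, 0.0]], atol=1e-14)

    def test_matches_finite_differences(self):
        """Analytic Jacobian vs central differences of the vector field."""
        h = 1e-6
        for p in random_feasible_params(100, seed=21):
            eq = equilibrium(p)
            J = jacobian(p, eq)
            num = np.empty((2, 2))
            state = np.array([eq.R_star, eq.C_star])
            for j in range(2):
                dp = np.zeros(2)
                dp[j] = h * max(1.0, abs(state[j]))
                up = np.array(rhs(state + dp, p))
                dn = np.array(rhs(state - dp, p))
                num[:, j] = (up - dn) / (2 * dp[j])
            assert np.allclose(J, num, atol=1e-6, rtol=1e-6)

    def test_trace_negative_when_feasible(self):
        for p in random_feasible_params(100, seed=31):
            J = jacobian(p)
            assert np.trace(J) < 0
            assert J[1, 1] == 0.0

    def test_worked_eigenvalues_and_resilience(self, worked_params):
        """λ² + 0.2λ + 0.8 = 0 ⇒ λ = −0.1 ± i√0.79, resilience 0.1."""
        st = stability(worked_params)
        lam = sorted(st.eigenvalues, key=lambda z: z.imag)
        assert lam[1].real == pytest.approx(-0.1, abs=1e-12)
        assert lam[1].imag == pytest.approx(math.sqrt(0.79), abs=1e-12)
        assert st.resilience == pytest.approx(0.1, abs=1e-12)
        assert st.stable

    def test_eigensolver_matches_quadratic_formula(self, worked_params):
        """Generic eigensolver vs the characteristic-polynomial roots."""
        J = jacobian(worked_params)
        tr, det = np.trace(J), np.linalg.det(J)
        disc = complex(tr * tr - 4 * det) ** 0.5
        roots = sorted([(tr + disc) / 2, (tr - disc) / 2], key=lambda z: z.imag)
        eig = sorted(stability(worked_params).eigenvalues, key=lambda z: z.imag)
        for a, b in zip(roots, eig):
            assert abs(a - b) < 1e-10

    def test_universal_stability(self):
        """Every feasible coexistence equilibrium of this model is locally stable."""
        for p in random_feasible_params(1000, seed=41):
            assert stability(p).lambda_max_real < 0

    def test_infeasible_equilibrium_rejected(self):
        p = CRParams(r=1.0, K=1.0, a=1.0, e=0.5, m=1.0)
        with pytest.raises(InfeasibleEquilibriumError):
            jacobian(p)


class TestInvasion:
    ENV = ResourceEnvironment()

    def test_self_invasion_neutral(self):
        g = _genotype("A", a=(1.0, 0.02))
        for T in (5.0, 15.0, 30.0):
            assert abs(invasion_fitness(g, g, self.ENV, T)) < 1e-12

    def test_lower_mortality_invades(self):
        res = _genotype("A", m=(0.6, 0.0))
        inv = _genotype("B", m=(0.5, 0.0))
        assert invasion_fitness(res, inv, self.ENV, 15.0) > 0

    def test_sign_matches_r_star_ordering(self):
        """sign(s) = sign(R*_res − R*_inv) on random genotype pairs."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            a1, a2 = rng.uniform(0.5, 2.0, 2)
            m1, m2 = rng.uniform(0.1, 0.5, 2)
            e1, e2 = rng.uniform(0.3, 0.8, 2)
            g1 = _genotype("A", a=(a1, 0.0), m=(m1, 0.0), e=(e1, 0.0))
            g2 = _genotype("B", a=(a2, 0.0), m=(m2, 0.0), e=(e2, 0.0))
            r1, r2 = m1 / (e1 * a1), m2 / (e2 * a2)
            if r1 >= 10.0 or abs(r1 - r2) < 1e-9:
                continue
            s = invasion_fitness(g1, g2, self.ENV, 15.0)
            assert np.sign(s) == np.sign(r1 - r2)
            # antisymmetry of invasion signs
            s_back = invasion_fitness(g2, g1, self.ENV, 15.0)
            assert np.sign(s_back) == -np.sign(s)
            checked += 1

    def test_infeasible_resident_rejected(self):
        res = _genotype("A", m=(20.0, 0.0))  # R* = 20/(0.5·1) = 40 > K
        with pytest.raises(InfeasibleResidentError):
            invasion_fitness(res, _genotype("B"), self.ENV, 15.0)


class TestFavouredGenotype:
    ENV = ResourceEnvironment()

    def test_identical_genotypes_neutral_lexicographic(self):
        panel = [_genotype("B"), _genotype("A")]
        res = favoured_genotype(panel, self.ENV, 20.0)
        assert res.neutral and res.favoured_genotype == "A"

    def test_winner_equals_r_star_rule(self):
        """Pairwise-invasibility winner = argmin m/(ea) on random panels."""
        rng = np.random.default_rng(19)
        for _ in range(200):
            panel = [
                _genotype(
                    f"g{k}",
                    a=(float(rng.uniform(0.5, 2.0)), 0.0),
                    m=(float(rng.uniform(0.1, 0.5)), 0.0),
                    e=(float(rng.uniform(0.3, 0.8)), 0.0),
                )
                for k in range(5)
            ]
            res = favoured_genotype(panel, self.ENV, 15.0)
            r_star = {g.id: g.norm_m.value_at_ref / (g.norm_e.value_at_ref * g.norm_a.value_at_ref)
                      for g in panel}
            assert res.favoured_genotype == min(r_star, key=lambda k: (r_star[k], k))
            # uninvadable: no other genotype has positive fitness in its equilibrium
            i = res.genotype_ids.index(res.favoured_genotype)
            assert np.all(res.fitness_matrix[i, :] <= 1e-12)

    def test_steeper_attack_slope_wins_when_warm(self):
        """Equal phenotype at 15 °C; larger a at high T ⇒ smaller R* ⇒ favoured."""
        shallow = _genotype("A", a=(1.0, 0.01))
        steep = _genotype("B", a=(1.0, 0.03))
        assert favoured_genotype([shallow, steep], self.ENV, 30.0).favoured_genotype == "B"
        res15 = favoured_genotype([shallow, steep], self.ENV, 15.0)
        assert res15.neutral


class TestCrossingTemperature:
    ENV = ResourceEnvironment()

    def test_constructed_intersection_at_reference(self):
        gA = _genotype("A", a=(1.0, 0.01))
        gB = _genotype("B", a=(1.0, 0.03))
        roots = crossing_temperature(gA, gB, self.ENV, (5.0, 35.0))
        assert len(roots) == 1
        assert roots[0] == pytest.approx(15.0, abs=1e-9)

    def test_identical_genotypes_degenerate(self):
        g = _genotype("A", a=(1.0, 0.02))
        assert crossing_temperature(g, g, self.ENV, (5.0, 35.0)) == []

    def test_residual_at_root_small(self):
        rng = np.random.default_rng(23)
        found = 0
        while found < 20:
            gA = _genotype("A", a=(1.0, float(rng.uniform(-0.02, 0.02))),
                           m=(0.4, float(rng.uniform(-0.005, 0.01))))
            gB = _genotype("B", a=(1.0, float(rng.uniform(-0.02, 0.02))),
                           m=(0.4, float(rng.uniform(-0.005, 0.01))))
            roots = crossing_temperature(gA, gB, self.ENV, (5.0, 35.0))
            for t in roots:
                pa = params_at(gA, self.ENV, t)
                pb = params_at(gB, self.ENV, t)
                assert abs(equilibrium(pa).R_star - equilibrium(pb).R_star) < 1e-10
                found += 1


class TestTemperatureSweep:
    ENV = ResourceEnvironment(
        norm_r=ReactionNorm(value_at_ref=1.0), norm_K=ReactionNorm(value_at_ref=10.0)
    )

    def test_flat_single_genotype_constant_resilience(self):
        table = temperature_sweep([_genotype("A")], self.ENV, [5.0, 15.0, 25.0, 35.0])
        assert table.resilience.nunique() == 1
        assert table.favoured_flag.all()

    def test_gxe_panel_switches_winner_and_gap_widens(self):
        """Equal phenotypes at 15 °C, differing a and m slopes: the favoured
        genotype differs between the grid ends and the between-genotype
        resilience gap grows toward the warm end."""
        gA = _genotype("A", a=(1.0, 0.005), m=(0.4, 0.004))
        gB = _genotype("B", a=(1.0, 0.03), m=(0.4, 0.006))
        grid = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0]
        table = temperature_sweep([gA, gB], ResourceEnvironment(), grid)
        winners = table[table.favoured_flag].set_index("T").genotype_id
        assert winners.loc[grid[0]] != winners.loc[grid[-1]]
        gap = (
            table.pivot(index="T", columns="genotype_id", values="resilience")
            .diff(axis=1).iloc[:, -1].abs()
        )
        assert gap.loc[35.0] > gap.loc[20.0]

    def test_switch_cell_brackets_analytic_crossing(self):
        gA = _genotype("A", a=(1.0, 0.005), m=(0.4, 0.004))
        gB = _genotype("B", a=(1.0, 0.03), m=(0.4, 0.006))
        env = ResourceEnvironment()
        grid = list(np.linspace(5.0, 35.0, 31))
        table = temperature_sweep([gA, gB], env, grid)
        winners = table[table.favoured_flag].set_index("T").genotype_id
        switches = [
            (grid[k], grid[k + 1])
            for k in range(len(grid) - 1)
            if winners.loc[grid[k]] != winners.loc[grid[k + 1]]
        ]
        roots = crossing_temperature(gA, gB, env, (5.0, 35.0))
        assert roots, "constructed panel must cross"
        for t_star in roots:
            assert any(lo <= t_star <= hi for lo, hi in switches)


class TestSimulateTrajectory:
    def test_stays_at_equilibrium(self, worked_params):
        eq = equilibrium(worked_params)
        traj = simulate_trajectory(worked_params, (eq.R_star, eq.C_star), 50.0)
        assert np.allclose(traj.R, eq.R_star, atol=1e-6)
        assert np.allclose(traj.C, eq.C_star, atol=1e-6)

    def test_decay_rate_matches_linearization(self, worked_params):
        """Log-decay of the perturbation envelope ≈ −Re(λmax) = 0.1 within 10%."""
        eq = equilibrium(worked_params)
        st = stability(worked_params)
        traj = simulate_trajectory(
            worked_params, (1.05 * eq.R_star, 1.05 * eq.C_star), 200.0, n_points=2001
        )
        dist = np.hypot(traj.R - eq.R_star, traj.C - eq.C_star)
        # spirals oscillate; fit the decay on the log of the envelope via
        # least squares over a late window where linearization holds
        # fit only where linearization holds and before the integrator's
        # error floor dominates the shrinking residual
        t, d = traj.t.values, dist.values
        mask = (t > 30) & (d > 1e-6)
        rate = -np.polyfit(t[mask], np.log(d[mask]), 1)[0]
        assert rate == pytest.approx(-st.lambda_max_real, rel=0.1)

    def test_consumer_free_axis_converges_to_K(self, worked_params):
        traj = simulate_trajectory(worked_params, (0.5, 0.0), 200.0)
        assert traj.C.iloc[-1] == 0.0
        assert traj.R.iloc[-1] == pytest.approx(worked_params.K, rel=1e-4)

    def test_negative_initial_state_rejected(self, worked_params):
        with pytest.raises(InvalidStateError):
            simulate_trajectory(worked_params, (-0.1, 1.0), 1.0)


class TestDecomposeVariance:
    def test_pure_g(self):
        """Two flat genotypes at 1 and 2: V_G = Var{1,2} = 0.25, no E or G×E."""
        panel = [_genotype("A", a=(1.0, 0.0)), _genotype("B", a=(2.0, 0.0))]
        d = decompose_variance(panel, [10.0, 20.0], "a")
        assert d.V_G == pytest.approx(0.25, abs=1e-14)
        assert d.V_E == 0.0 and d.V_GxE == 0.0
        assert d.V_total == pytest.approx(0.25, abs=1e-14)

    def test_parallel_norms_no_gxe(self):
        panel = [_genotype("A", a=(1.0, 0.02)), _genotype("B", a=(1.5, 0.02))]
        d = decompose_variance(panel, [5.0, 15.0, 25.0, 35.0], "a")
        assert d.V_GxE == pytest.approx(0.0, abs=1e-15)
        assert d.V_E > 0 and d.V_G > 0

    def test_components_sum_to_total(self):
        rng = np.random.default_rng(29)
        panel = [
            _genotype(f"g{k}", a=(float(rng.uniform(0.5, 2.0)), float(rng.uniform(-0.05, 0.05))))
            for k in range(4)
        ]
        d = decompose_variance(panel, [0.0, 10.0, 20.0, 30.0], "a")
        assert d.V_G + d.V_E + d.V_GxE == pytest.approx(d.V_total, abs=1e-10)

    def test_insufficient_design_rejected(self):
        panel = [_genotype("A"), _genotype("B")]
        with pytest.raises(InsufficientDesignError):
            decompose_variance(panel, [15.0], "a")
        with pytest.raises(InsufficientDesignError):
            decompose_variance(panel[:1], [5.0, 15.0], "a")
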