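import math
from dataclasses import replace

import numpy as np
import pytest

from txswitch.analytic import (coop_occupancy_distribution, coop_stats,
                               indirect_ff, indirect_stats, indirect_ta,
                               mrna_moments, solver_stats)
from txswitch.models import (CellContext, CooperativeSwitchSpec, DnaStateModel,
                             IndirectSwitchSpec, build_cooperative_model)

from conftest import telegraph_fano


def telegraph_model(kon, koff):
    Q = np.array([[-kon, kon], [koff, -koff]])
    return DnaStateModel(states=("off", "on"), rate_matrix=Q,
                         producing=np.array([False, True]))


class TestMomentSolver:
    @pytest.mark.parametrize("kon,koff,alpha,beta", [
        (0.3, 0.7, 5.0, 0.1),
        (1e-3, 2e-3, 0.07, 7e-4),
        (50.0, 10.0, 1.0, 1.0),
    ])
    def test_matches_telegraph_closed_form(self, kon, koff, alpha, beta):
        st = mrna_moments(telegraph_model(kon, koff), alpha, beta)
        assert st.activity == pytest.approx(kon / (kon + koff), rel=1e-12)
        assert st.mean_mrna == pytest.approx(alpha / beta * st.activity,
                                             rel=1e-10)
        assert st.fano == pytest.approx(telegraph_fano(alpha, beta, kon, koff),
                                        rel=1e-10)

    def test_always_on_limit_is_poisson(self):
        st = mrna_moments(telegraph_model(1.0, 1e-14), 2.0, 0.5)
        assert st.mean_mrna == pytest.approx(4.0, rel=1e-9)
        assert st.fano == pytest.approx(1.0, abs=1e-9)

    def test_reducible_chain_raises(self):
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = 1.0   # two disconnected recurrent pairs
        Q[2, 3] = Q[3, 2] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        m = DnaStateModel(states=("a", "b", "c", "d"), rate_matrix=Q,
                          producing=np.array([True, False, True, False]))
        with pytest.raises(np.linalg.LinAlgError):
            mrna_moments(m, 1.0, 0.1)


class TestCooperative:
    def test_occupancy_edge_cases(self):
        np.testing.assert_allclose(coop_occupancy_distribution(0.0, 0.5),
                                   [1, 0, 0, 0, 0])
        np.testing.assert_allclose(coop_occupancy_distribution(1.0, 1.0),
                                   np.array([1, 4, 6, 4, 1]) / 16.0)

    def test_occupancy_matches_16_state_null_space(self, fig1_spec):
        """Aggregating the 16 labeled states by occupancy recovers the
        birth-death law, including deep in the cooperative regime."""
        spec = replace(fig1_spec, c=1e-2, RT=1e-3 * 1e7 * fig1_spec.Kr)
        model = build_cooperative_model(spec)
        pi = model.stationary()
        agg = np.zeros(5)
        for i, s in enumerate(model.states):
            agg[s.count("1")] += pi[i]
        np.testing.assert_allclose(
            agg, coop_occupancy_distribution(spec.x, spec.c), rtol=1e-8)

    def test_no_repressor_gives_poisson_output(self, fig1_spec):
        st = coop_stats(replace(fig1_spec, RT=0.0))
        assert st.activity == pytest.approx(1.0)
        assert st.mean_mrna == pytest.approx(100.0, rel=1e-9)
        assert st.fano == pytest.approx(1.0, abs=1e-9)

    def test_operating_point_half_activity(self, fig1_spec):
        """RT = c^1.5 * Omega * Kr sits at the steepest part of the curve."""
        st = coop_stats(fig1_spec)
        assert st.activity == pytest.approx(0.5, abs=0.01)

    def test_activity_nonincreasing_in_repressor(self, fig1_spec):
        acts = [coop_stats(replace(fig1_spec, RT=rt)).activity
                for rt in (0, 50, 100, 200, 400)]
        assert np.all(np.diff(acts) < 0)


class TestIndirectClosedForms:
    @pytest.mark.parametrize("mech", ["S", "SB", "SBD"])
    def test_closed_form_equals_moment_solver(self, mech, fig2_spec):
        """Spot equivalence at several repressor levels (the deep random
        sweep lives in the acceptance suite)."""
        for rt_ratio in (0.1, 0.9, 1.0, 1.1, 5.0):
            spec = replace(fig2_spec, mechanisms=mech, RT=rt_ratio * 1e3)
            st = solver_stats(spec)
            assert indirect_ta(spec) == pytest.approx(st.activity, rel=1e-8)
            assert indirect_ff(spec) == pytest.approx(st.fano, rel=1e-8)

    def test_correction_factors_unity_at_detailed_balance(self, fig2_spec):
        from txswitch.analytic import indirect_terms
        t = indirect_terms(replace(fig2_spec, RT=500.0))
        assert t.I == pytest.approx(1.0) and t.J == pytest.approx(1.0)

    def test_activity_limits(self, fig2_spec):
        # RT=0 with AT >> Omega*Ka: activity saturates near its maximum
        assert indirect_ta(replace(fig2_spec, RT=0.0)) > 0.9
        assert indirect_ta(replace(fig2_spec, RT=100 * fig2_spec.AT)) < 1e-3

    def test_fano_poisson_limits(self, fig2_spec):
        fast = replace(fig2_spec, context=CellContext(
            omega=1e7, kf=6e12, alpha=fig2_spec.context.alpha,
            beta=fig2_spec.context.beta), RT=1000.0)
        assert indirect_ff(fast) == pytest.approx(1.0, abs=1e-3)
        quiet = replace(fig2_spec, context=CellContext(
            omega=1e7, kf=600.0, alpha=1e-10,
            beta=fig2_spec.context.beta), RT=1000.0)
        assert indirect_ff(quiet) == pytest.approx(1.0, abs=1e-6)

    def test_fano_at_least_one_across_grid(self, fig2_spec, fig3_spec):
        from txswitch.analytic import fano_curve
        grid = np.geomspace(1e-2, 1e2, 200)
        for spec in (fig2_spec, fig3_spec):
            for mech in ("S", "SB", "SBD"):
                ff = fano_curve(replace(spec, mechanisms=mech), grid)
                assert np.all(ff >= 1.0 - 1e-12)

    def test_activity_nonincreasing_in_repressor(self, fig2_spec):
        from txswitch.analytic import activity_curve
        grid = np.linspace(0.0, 5.0, 300)
        for mech in ("S", "SB", "SBD"):
            ta = activity_curve(replace(fig2_spec, mechanisms=mech), grid)
            assert np.all(np.diff(ta) <= 1e-12)

    def test_normalization_invariance(self, fig2_spec):
        """Rescaling (Omega, kf) -> (lambda*Omega, lambda*kf) at fixed AT,
        RT, Omega*Kx, alpha, beta leaves all stationary statistics fixed."""
        spec = replace(fig2_spec, RT=950.0)
        for lam in (10.0, 0.1):
            ctx = spec.context
            scaled = IndirectSwitchSpec(
                context=CellContext(omega=lam * ctx.omega, kf=lam * ctx.kf,
                                    alpha=ctx.alpha, beta=ctx.beta),
                AT=spec.AT, RT=spec.RT, Ks=spec.Ks / lam, Ka=spec.Ka / lam,
                Kb=spec.Kb / lam, Kd=spec.Kd / lam,
                mechanisms=spec.mechanisms)
            assert indirect_ta(scaled) == pytest.approx(indirect_ta(spec),
                                                        rel=1e-12)
            assert indirect_ff(scaled) == pytest.approx(indirect_ff(spec),
                                                        rel=1e-12)

    def test_stats_consistency(self, fig2_spec):
        spec = replace(fig2_spec, RT=800.0)
        st = indirect_stats(spec)
        ratio = spec.context.alpha / spec.context.beta
        assert st.mean_mrna == pytest.approx(ratio * st.activity, rel=1e-12)
        assert st.var_mrna == pytest.approx(st.fano * st.mean_mrna, rel=1e-12)
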