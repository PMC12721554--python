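import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txswitch.models import (CellContext, CooperativeSwitchSpec,
                             IndirectSwitchSpec, MultiTargetSpec, NflSpec,
                             build_cooperative_model, build_indirect_model,
                             build_multitarget_system, build_nfl_system,
                             dna_mrna_system, qssa_partition,
                             resolve_constant)


class TestQssaPartition:
    def test_conservation_and_mass_action_over_random_sweep(self):
        """Both conservation laws and the binding balance hold to 1e-12
        relative across a million-point random parameter sweep."""
        from txswitch.models import _titration_roots
        rng = np.random.default_rng(0)
        n = 1_000_000
        at = 10 ** rng.uniform(0, 6, n)
        rt = 10 ** rng.uniform(-2, 6, n)
        oks = 10 ** rng.uniform(-8, 6, n)
        a, r, ra = _titration_roots(at, rt, oks)
        assert np.all(a >= 0) and np.all(r >= 0) and np.all(ra >= 0)
        np.testing.assert_allclose(a + ra, at, rtol=1e-12)
        np.testing.assert_allclose(r + ra, rt, rtol=1e-12)
        np.testing.assert_allclose(a * r, oks * ra, rtol=1e-12)

    def test_scalar_agrees_with_vectorized_roots(self):
        from txswitch.models import _titration_roots
        rng = np.random.default_rng(1)
        for _ in range(300):
            at = 10 ** rng.uniform(0, 5)
            rt = 10 ** rng.uniform(-2, 5)
            ks = 10 ** rng.uniform(-10, 1)
            p = qssa_partition(at, rt, ks, 1e7)
            a, r, ra = _titration_roots(at, rt, 1e7 * ks)
            assert p.A == float(a) and p.R == float(r) and p.RA == float(ra)

    @given(st.floats(1, 1e5), st.floats(0.01, 1e5), st.floats(1e-6, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_difference_identity_exact(self, at, rt, oks):
        p = qssa_partition(at, rt, oks, 1.0)
        assert p.A - p.R == pytest.approx(at - rt, rel=1e-12, abs=1e-9)

    def test_matches_bisection_oracle(self):
        """A solves A*(A - AT + RT) = Omega*Ks*(AT - A); root by bisection."""
        at, rt, oks = 1000.0, 500.0, 10.0
        f = lambda a: a * (a - at + rt) - oks * (at - a)
        lo, hi = max(at - rt, 0.0), at
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        p = qssa_partition(at, rt, oks, 1.0)
        assert p.A == pytest.approx(0.5 * (lo + hi), rel=1e-12)

    def test_no_repressor_boundary(self):
        p = qssa_partition(1000, 0, 1.0, 1.0)
        assert (p.A, p.R, p.RA) == (1000, 0, 0)

    def test_symmetric_strong_binding_limit(self):
        p = qssa_partition(1000, 1000, 1e-13, 1.0)
        assert p.RA == pytest.approx(1000, rel=1e-5)
        assert p.A == pytest.approx(p.R, rel=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            qssa_partition(-1, 0, 1, 1)
        with pytest.raises(ValueError):
            qssa_partition(1, 1, -1, 1)


class TestCooperativeModel:
    def test_structure(self, fig1_spec):
        m = build_cooperative_model(fig1_spec)
        assert m.n_states == 16
        off = m.rate_matrix - np.diag(np.diag(m.rate_matrix))
        assert np.count_nonzero(off) == 64
        assert m.producing.sum() == 15  # all but the fully occupied state
        np.testing.assert_allclose(m.rate_matrix.sum(axis=1), 0, atol=1e-12)

    def test_activator_mode_produces_only_when_full(self, fig1_spec):
        m = build_cooperative_model(replace(fig1_spec,
                                            mode="activator_activates"))
        assert m.producing.sum() == 1
        assert m.states[int(np.argmax(m.producing))] == "1111"

    def test_independent_sites_limit_is_binomial(self, fig1_spec):
        """At c=1 each site is independently occupied w.p. x/(1+x)."""
        spec = replace(fig1_spec, c=1.0, RT=2.0 * 1e7 * fig1_spec.Kr)  # x=2
        m = build_cooperative_model(spec)
        pi = m.stationary()
        p = 2.0 / 3.0
        for i, s in enumerate(m.states):
            k = s.count("1")
            assert pi[i] == pytest.approx(p ** k * (1 - p) ** (4 - k),
                                          rel=1e-9)

    def test_rejects_bad_cooperativity(self, fig1_spec):
        with pytest.raises(ValueError):
            replace(fig1_spec, c=1.5)
        with pytest.raises(ValueError):
            replace(fig1_spec, c=0.0)


class TestIndirectModel:
    def test_sole_sequestration_is_two_state(self, fig2_spec):
        m = build_indirect_model(replace(fig2_spec, mechanisms="S", RT=500.0))
        assert m.states == ("EF", "EA")
        assert list(m.producing) == [False, True]

    def test_sbd_without_repressors_reduces_to_s_chain(self, fig2_spec):
        full = build_indirect_model(replace(fig2_spec, RT=0.0))
        sole = build_indirect_model(replace(fig2_spec, mechanisms="S", RT=0.0))
        np.testing.assert_allclose(full.rate_matrix[:2, :2],
                                   sole.rate_matrix, atol=1e-15)
        assert full.rate_matrix[0, 2] == 0 and full.rate_matrix[1, 2] == 0

    def test_sb_stationary_matches_closed_form(self, fig2_spec):
        from txswitch.analytic import indirect_ta
        spec = replace(fig2_spec, mechanisms="SB", RT=900.0)
        pi = build_indirect_model(spec).stationary()
        assert pi[1] == pytest.approx(indirect_ta(spec), rel=1e-10)

    def test_invalid_mechanism_rejected(self, fig2_spec):
        with pytest.raises(ValueError, match="mechanism"):
            replace(fig2_spec, mechanisms="SD")

    def test_sigma_is_one_at_detailed_balance(self, fig2_spec):
        assert fig2_spec.sigma == pytest.approx(1.0, rel=1e-12)


class TestReactionSystems:
    def test_nfl_gene_state_conserved_along_trajectory(self, fig4_spec):
        from txswitch.ssa import simulate
        system = build_nfl_system(fig4_spec)
        traj = simulate(system, 2000.0, seed=3, audit=True)
        gene = traj.counts[:, :3].sum(axis=1)
        assert np.all(gene == 1)

    def test_nfl_without_translation_keeps_repressor_at_zero(self, fig4_spec):
        from txswitch.ssa import simulate
        system = build_nfl_system(replace(fig4_spec, alpha2=1e-30))
        traj = simulate(system, 3000.0, seed=4)
        assert traj.counts[:, system.index("R")].max() == 0
        # activated stationary mean for mRNA is alpha/beta
        m = traj.resample(np.arange(1500.0, 3000.0, 5.0))[:, system.index("M")]
        assert abs(m.mean() - 100) < 25

    def test_nfl_table_literal_variant_runs(self, fig4_spec):
        from txswitch.ssa import simulate
        system = build_nfl_system(replace(fig4_spec, table_literal=True))
        traj = simulate(system, 1000.0, seed=5)
        assert (traj.counts >= 0).all()

    def test_multitarget_conservations_hold(self, fig5_spec):
        from txswitch.ssa import simulate
        spec = replace(fig5_spec, RT=800.0, DT=50)
        system = build_multitarget_system(spec)
        simulate(system, 500.0, seed=6, audit=True)  # audit raises on breach

    def test_multitarget_dt0_has_no_pooled_genes(self, fig5_spec):
        system = build_multitarget_system(fig5_spec)
        assert system.initial[system.index("DF")] == 0


class TestConstantConvention:
    def test_three_conventions(self):
        at, omega, printed = 1e3, 1e7, 4.5e-10
        assert resolve_constant(printed, "per_activator", at, omega) == \
            pytest.approx(4.5e-7)
        assert resolve_constant(printed, "normalized", at, omega) == \
            pytest.approx(4.5e-14)
        assert resolve_constant(printed, "raw", at, omega) == printed

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            resolve_constant(1.0, "other", 1.0, 1.0)

    def test_normalized_constants_are_at_independent(self, fig2_spec):
        """Under the per-activator reading, Omega*Kx/AT does not change
        with AT, so activity curves match across abundance panels."""
        s1 = IndirectSwitchSpec.from_printed(
            fig2_spec.context, 1e3, 0.0, 4.5e-10, 7e-9, 1e-6)
        s2 = IndirectSwitchSpec.from_printed(
            fig2_spec.context, 1e5, 0.0, 4.5e-10, 7e-9, 1e-6)
        n1, n2 = s1.normalized(), s2.normalized()
        for k in ("ks", "ka", "kb", "kd"):
            assert n1[k] == pytest.approx(n2[k], rel=1e-12)
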