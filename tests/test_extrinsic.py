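from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import poisson

from txswitch import extrinsic
from txswitch.analytic import indirect_ff, indirect_ta


class TestCountDistribution:
    def test_poisson_truncation_mass(self):
        d = extrinsic.poisson_counts(1000.0)
        assert abs(d.pmf.sum() - 1.0) < 1e-12
        assert d.mean == pytest.approx(1000.0, rel=1e-6)
        assert d.var == pytest.approx(1000.0, rel=1e-4)

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError):
            extrinsic.CountDistribution(support=np.array([0, 2]),
                                        pmf=np.array([0.5, 0.5]))


class TestRepressorMixture:
    def test_degenerate_mixing_recovers_base_model(self, fig2_spec):
        rt0 = 900
        d = extrinsic.CountDistribution.degenerate(rt0)
        out = extrinsic.repressor_mixture_stats(fig2_spec, d,
                                                mechanisms=("SBD",),
                                                matched_ta=False)
        spec = replace(fig2_spec, RT=float(rt0))
        ratio = spec.context.alpha / spec.context.beta
        assert out["SBD"].total_mean == pytest.approx(
            ratio * indirect_ta(spec), rel=1e-10)
        assert out["SBD"].total_fano == pytest.approx(indirect_ff(spec),
                                                      rel=1e-10)
        assert out["SBD"].between_var == pytest.approx(0.0, abs=1e-9)

    def test_matched_activity_means_identical(self, fig2_spec):
        out = extrinsic.repressor_mixture_stats(fig2_spec, 1000.0)
        means = [out[m].total_mean for m in ("S", "SB", "SBD")]
        assert means[0] == pytest.approx(means[1], rel=1e-12)
        assert means[0] == pytest.approx(means[2], rel=1e-12)

    def test_variance_minimized_by_full_combination(self, fig2_spec):
        out = extrinsic.repressor_mixture_stats(fig2_spec, 1000.0)
        assert out["SBD"].total_var <= out["SB"].total_var <= out["S"].total_var

    def test_total_variance_decomposition_nonnegative(self, fig2_spec):
        out = extrinsic.repressor_mixture_stats(fig2_spec, 900.0)
        for s in out.values():
            assert s.between_var >= 0 and s.within_var >= 0
            assert s.total_var == pytest.approx(s.between_var + s.within_var)

    def test_monte_carlo_agreement_small_case(self, fig2_spec):
        """Brute force: draw RT from the mixing law, then draw the mRNA
        snapshot from the conditional stationary law via SSA."""
        from txswitch.models import build_indirect_model, dna_mrna_system
        from txswitch.ssa import ensemble_stationary
        mean_rt = 900.0
        out = extrinsic.repressor_mixture_stats(
            fig2_spec, mean_rt, mechanisms=("SBD",), matched_ta=False)["SBD"]
        rng = np.random.default_rng(99)
        n = 600
        rts = rng.poisson(mean_rt, size=n)
        samples = np.empty(n)
        t_snap = 10 * fig2_spec.context.halflife
        for i, rt in enumerate(np.sort(rts)):
            spec = replace(fig2_spec, RT=float(rt))
            model = build_indirect_model(spec)
            system = dna_mrna_system(model, spec.context.alpha,
                                     spec.context.beta)
            s = ensemble_stationary(system, 2, t_snap, int(1000 + i),
                                    init_model=model)
            samples[i] = s.counts[0, system.mrna_species]
        se_mean = samples.std(ddof=1) / np.sqrt(n)
        assert abs(samples.mean() - out.total_mean) <= 3 * se_mean


class TestActivatorDistribution:
    def test_equal_degradation_is_exactly_poisson(self):
        d = extrinsic.activator_count_distribution(
            alpha_a=1e-4, beta_a=1.0, beta_ra=1.0, omega=1e6, RT=500.0,
            Ks=1e-6)
        ref = poisson.pmf(d.support, 100.0)
        np.testing.assert_allclose(d.pmf, ref / ref.sum(), rtol=1e-8)

    def test_no_repressor_is_poisson(self):
        d = extrinsic.activator_count_distribution(
            alpha_a=1e-4, beta_a=1.0, beta_ra=10.0, omega=1e6, RT=0.0,
            Ks=1e-6)
        ref = poisson.pmf(d.support, 100.0)
        np.testing.assert_allclose(d.pmf, ref / ref.sum(), rtol=1e-8)

    def test_matches_birth_death_null_space(self):
        """Oracle: stationary law of the truncated birth-death generator."""
        alpha_a, beta_a, beta_ra, omega, rt, ks = 5e-5, 1.0, 10.0, 1e6, 30.0, 1e-6
        d = extrinsic.activator_count_distribution(alpha_a, beta_a, beta_ra,
                                                   omega, rt, ks)
        n_max = int(d.support[-1])
        from txswitch.models import qssa_partition
        death = np.zeros(n_max + 1)
        for n in range(1, n_max + 1):
            p = qssa_partition(float(n), rt, ks, omega)
            death[n] = (beta_a * p.A + beta_ra * p.RA) / omega
        Q = np.zeros((n_max + 1, n_max + 1))
        for n in range(n_max):
            Q[n, n + 1] = alpha_a
            Q[n + 1, n] = death[n + 1]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        full = np.zeros(n_max + 1)
        full[d.support] = d.pmf
        np.testing.assert_allclose(full, pi, atol=1e-8)

    def test_repressor_enhanced_degradation_deviates_from_poisson(self):
        """Above threshold the fast-degrading bound pool is capped at RT, so
        the per-molecule death rate is sub-linear and the stationary law is
        over-dispersed relative to Poisson."""
        d = extrinsic.activator_count_distribution(
            alpha_a=1e-2, beta_a=1.0, beta_ra=10.0, omega=1e6, RT=500.0,
            Ks=1e-6)
        assert d.mean > 500.0
        assert d.var / d.mean > 1.1

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            extrinsic.activator_count_distribution(0.0, 1, 1, 1, 0, 1)


@pytest.fixture(scope="module")
def dist():
    return extrinsic.activator_count_distribution(
        alpha_a=6e-5, beta_a=1.0, beta_ra=10.0, omega=1e7, RT=500.0,
        Ks=4.5e-7)


class TestActivatorMixture:
    def test_matched_activity_means_identical(self, fig2_spec, dist):
        spec = replace(fig2_spec, RT=500.0)
        out = extrinsic.activator_mixture_stats(spec, dist)
        means = [out[m].total_mean for m in ("S", "SB", "SBD")]
        assert means[0] == pytest.approx(means[1], rel=1e-12)
        assert means[0] == pytest.approx(means[2], rel=1e-12)

    def test_fano_minimized_by_full_combination(self, fig2_spec, dist):
        spec = replace(fig2_spec, RT=500.0)
        out = extrinsic.activator_mixture_stats(spec, dist)
        assert out["SBD"].total_fano <= out["SB"].total_fano
        assert out["SBD"].total_fano <= out["S"].total_fano

    def test_degenerate_distribution_recovers_base(self, fig2_spec):
        d = extrinsic.CountDistribution.degenerate(1000)
        spec = replace(fig2_spec, RT=800.0)
        out = extrinsic.activator_mixture_stats(spec, d, mechanisms=("SBD",),
                                                matched_ta=False)
        ratio = spec.context.alpha / spec.context.beta
        assert out["SBD"].total_mean == pytest.approx(
            ratio * indirect_ta(spec), rel=1e-6)
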