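"""Conditional FDR: two-groups fit, empirical cFDR, v-values vs quadrature
oracle, and the iterative procedure."""

import numpy as np
import pytest
from scipy import stats

from pleiokit import (
    CfdrConfig, SimConfig, compute_vvalues, empirical_cfdr, fit_two_groups,
    iterate_cfdr, genomic_control, simulate_trait_pair,
)
from pleiokit.cfdr import TwoGroupsFit, cfdr_levels
from pleiokit.ldtools import r2_matrix


def quadrature_oracle(p, q, fit, n_z=2001, n_p=20001):
    """Independent v-value computation on a fine 2-D grid.

    Levels are uncapped leave-one-out empirical cFDR values computed by
    direct counting; the region integrand is the fraction of a fine uniform
    p'-grid (midpoints) whose raw full-data empirical cFDR lies at or below
    the level, integrated over the auxiliary z-scale against the fitted null
    density with an analytic tail.
    """
    p, q = np.asarray(p, float), np.asarray(q, float)
    n = len(p)
    # leave-one-out levels by direct loops
    c = np.empty(n)
    for i in range(n):
        m = sum(1 for j in range(n) if j != i and q[j] <= q[i])
        k = sum(1 for j in range(n) if j != i and p[j] <= p[i] and q[j] <= q[i])
        c[i] = p[i] * (1.0 + m) / (1.0 + k)

    z_max = stats.norm.isf(q.min() / 2.0) + 1.0
    z_grid = np.linspace(0.0, z_max, n_z)
    q_grid = 2.0 * stats.norm.sf(z_grid)
    p_grid = (np.arange(n_p) + 0.5) / n_p

    order = np.argsort(p)
    p_sorted = p[order]
    q_sorted = q[order]

    f_z = fit.null_z_density(z_grid)
    measure = np.empty((n_z, n))
    for g in range(n_z):
        members = q_sorted <= q_grid[g]
        pm = p_sorted[members]
        m = len(pm)
        k_at = np.searchsorted(pm, p_grid, side="right")
        cf = p_grid * (1.0 + m) / (1.0 + k_at)
        measure[g] = np.mean(cf[None, :] <= c[:, None], axis=1)
    v = np.trapezoid(measure * f_z[:, None], z_grid, axis=0)
    v += measure[-1] * fit.null_z_sf(z_max)
    return np.clip(v, 0.0, 1.0)


class TestFitTwoGroups:
    def test_null_only_recovers_pi0_near_one(self):
        ok = 0
        for seed in range(10):
            q = np.random.default_rng(seed).uniform(size=10_000)
            ok += fit_two_groups(q).pi0 >= 0.95
        assert ok >= 9

    def test_recovers_mixture_parameters(self):
        rng = np.random.default_rng(3)
        ok = 0
        for rep in range(10):
            lab = rng.random(10_000) < 0.8
            z = np.where(lab, np.abs(rng.normal(0, 1, 10_000)),
                         np.abs(rng.normal(0, 3.0, 10_000)))
            q = 2 * stats.norm.sf(z)
            fit = fit_two_groups(q)
            ok += (abs(fit.pi0 - 0.8) <= 0.05) and (abs(fit.sigma - 3.0) <= 0.5)
        assert ok >= 9

    def test_degenerate_spike_warns(self):
        with pytest.warns(UserWarning):
            fit = fit_two_groups(np.full(100, 0.99))
        assert fit.pi0 > 0.99 or fit.sigma < 1.001

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_two_groups(np.random.default_rng(0).uniform(size=10))


class TestEmpiricalCfdr:
    PAIRS = np.array([[.01, .02], [.5, .6], [.9, .9], [.2, .05], [.7, .3]])

    def test_five_pair_hand_count(self):
        # #{q_j <= .02} = 1, #{p_j <= .01 and q_j <= .02} = 1
        # -> .01 * (1+1) / (1+1) = .01
        val = empirical_cfdr(self.PAIRS[:, 0], self.PAIRS[:, 1], at=(.01, .02))
        assert val == pytest.approx(0.01, abs=1e-12)

    def test_vacuous_conditioning_at_q_one(self):
        p_all = self.PAIRS[:, 0]
        val = empirical_cfdr(p_all, self.PAIRS[:, 1], at=(.2, 1.0))
        expect = .2 * (1 + 5) / (1 + np.sum(p_all <= .2))
        assert val == pytest.approx(min(1.0, expect), abs=1e-12)

    def test_p_one_capped(self):
        assert empirical_cfdr(self.PAIRS[:, 0], self.PAIRS[:, 1],
                              at=(1.0, 0.5)) == 1.0

    def test_leave_one_out_drops_self(self):
        p_all, q_all = self.PAIRS[:, 0], self.PAIRS[:, 1]
        # at (.01, .9): all five q <= .9, only p=.01 below -> .01*6/2 = .03
        with_self = empirical_cfdr(p_all, q_all, at=(.01, .9))
        assert with_self == pytest.approx(0.03, abs=1e-12)
        # dropping the (.01, .02) pair: m = 4, k = 0 -> .01*5/1 = .05
        loo = empirical_cfdr(p_all, q_all, at=(.01, .9), leave_out=0)
        assert loo == pytest.approx(0.05, abs=1e-12)

    def test_vectorised_levels_match_pointwise(self, rng):
        p, q = rng.uniform(size=50), rng.uniform(size=50)
        lv = cfdr_levels(p, q)
        for i in range(0, 50, 7):
            assert lv[i] == pytest.approx(
                empirical_cfdr(p, q, at=(p[i], q[i]), leave_out=i), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_cfdr(np.array([]), np.array([]), at=(.5, .5))


class TestComputeVvalues:
    def test_uninformative_auxiliary_reproduces_p(self):
        rng = np.random.default_rng(1)
        n = 10_000
        p = 10 ** (-8 * rng.random(n))
        q = rng.uniform(size=n)
        fit = TwoGroupsFit(pi0=1.0, sigma=1.0, n_fit=n, loglik=0.0)
        v = compute_vvalues(p, q, fit)
        sel = (p >= 1e-6) & (p <= 0.5)
        rel = np.abs(v[sel] - p[sel]) / p[sel]
        assert rel.mean() < 0.02

    def test_joint_null_v_uniform(self):
        rng = np.random.default_rng(7)
        p, q = rng.uniform(size=10_000), rng.uniform(size=10_000)
        fit = TwoGroupsFit(1.0, 1.0, 10_000, 0.0)
        v = compute_vvalues(p, q, fit)
        assert stats.kstest(v, "uniform").pvalue > 0.01

    def test_directional_modulation(self):
        rng = np.random.default_rng(2)
        p = np.r_[0.001, 0.001, rng.uniform(size=500)]
        q = np.r_[1e-6, 1.0, 10 ** (-6 * rng.random(500))]
        fit = TwoGroupsFit(0.7, 3.0, 500, 0.0)
        v = compute_vvalues(p, q, fit)
        assert v[0] < p[0]          # strong auxiliary evidence shrinks
        assert v[1] >= p[1]         # no auxiliary evidence inflates

    @pytest.mark.parametrize("seed,pi0,sigma", [(0, 1.0, 1.0), (1, 0.7, 2.5),
                                                (2, 0.9, 4.0)])
    def test_twenty_snp_toys_match_quadrature_oracle(self, seed, pi0, sigma):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20) ** 2
        q = rng.uniform(size=20)
        fit = TwoGroupsFit(pi0, sigma, 20, 0.0)
        v = compute_vvalues(p, q, fit, grid_size=2001)
        oracle = quadrature_oracle(p, q, fit)
        np.testing.assert_allclose(v, oracle, atol=1e-3)

    def test_grid_doubling_converged(self):
        # once the grid resolves every distinct auxiliary value the
        # q'-integration is exact, so doubling changes nothing; just below
        # that regime the entry-allocation error is already < 1e-4
        rng = np.random.default_rng(5)
        p, q = rng.uniform(size=2000), rng.uniform(size=2000)
        fit = TwoGroupsFit(0.8, 3.0, 2000, 0.0)
        v_exact = compute_vvalues(p, q, fit, grid_size=2500)
        v_exact2 = compute_vvalues(p, q, fit, grid_size=5000)
        np.testing.assert_array_equal(v_exact, v_exact2)
        # below the exact regime the grid error shrinks roughly linearly
        err = [np.max(np.abs(compute_vvalues(p, q, fit, grid_size=G) - v_exact))
               for G in (500, 1000)]
        assert err[1] < err[0] and err[1] < 1e-3

    def test_v_in_unit_interval_and_monotone_in_level(self):
        rng = np.random.default_rng(9)
        p, q = rng.uniform(size=2000), rng.uniform(size=2000)
        fit = TwoGroupsFit(0.85, 2.0, 2000, 0.0)
        v = compute_vvalues(p, q, fit)
        assert ((v > 0) & (v <= 1)).all()
        # v is a monotone transform of the cFDR level (nested regions)
        c = cfdr_levels(p, q, cap=False)
        order = np.argsort(c)
        assert np.all(np.diff(v[order]) >= -1e-12)

    def test_invalid_inputs_rejected(self):
        fit = TwoGroupsFit(1.0, 1.0, 0, 0.0)
        with pytest.raises(ValueError):
            compute_vvalues(np.array([0.5]), np.array([0.5, 0.1]), fit)
        with pytest.raises(ValueError):
            compute_vvalues(np.array([0.0]), np.array([0.5]), fit)


@pytest.fixture(scope="module")
def cfdr_world():
    cfg = SimConfig(n_snps=4000, n_blocks=200, n_genes=20,
                    n_special_genes=4, pi_causal=0.0, seed=31)
    from pleiokit import simulate_genome
    g = simulate_genome(cfg)
    return cfg, g, r2_matrix(g)


class TestIterateCfdr:
    def test_zero_auxiliaries_returns_gc_corrected_p(self, cfdr_world):
        cfg, g, ld = cfdr_world
        prin, _ = simulate_trait_pair(g, cfg, seed=41)
        run = iterate_cfdr(prin, [], ld)
        gc_p, _ = genomic_control(prin)
        np.testing.assert_array_equal(run.final["V"], gc_p.df["P"])

    def test_missing_auxiliary_carries_value_forward(self, cfdr_world):
        cfg, g, ld = cfdr_world
        prin, _ = simulate_trait_pair(g, cfg, seed=43)
        a1, a2 = simulate_trait_pair(g, cfg, seed=44)
        # second auxiliary misses half the SNPs
        a2 = a2.copy(a2.df.iloc[::2].reset_index(drop=True))
        run = iterate_cfdr(prin, [a1, a2], ld)
        it1, it2 = run.iterations
        carried = it2.per_snp["CARRIED"].to_numpy()
        assert carried.sum() == len(prin) - len(a2)
        v1 = it1.per_snp["V"].to_numpy()
        v2 = it2.per_snp["V"].to_numpy()
        np.testing.assert_array_equal(v2[carried], v1[carried])
        assert not np.array_equal(v2[~carried], v1[~carried])

    def test_more_auxiliaries_than_max_iterations_refused(self, cfdr_world):
        cfg, g, ld = cfdr_world
        prin, aux = simulate_trait_pair(g, cfg, seed=45)
        with pytest.raises(ValueError, match="auxiliary"):
            iterate_cfdr(prin, [aux] * 4, ld)

    def test_power_gain_with_shared_effects(self, cfdr_world):
        cfg, g, ld = cfdr_world
        shared_cfg = SimConfig(**{**cfg.__dict__, "pi_causal": 0.01,
                                  "rho_shared": 0.9, "h2_a": 0.1,
                                  "h2_b": 0.4})
        gain_v, gain_p = 0, 0
        for seed in range(10):
            prin, aux1 = simulate_trait_pair(g, shared_cfg, seed=600 + seed)
            _, aux2 = simulate_trait_pair(g, shared_cfg, seed=700 + seed)
            run = iterate_cfdr(prin, [aux1, aux2], ld)
            base = run.iterations[0].per_snp["P_IN"].to_numpy()
            gain_p += int(np.sum(base < 5e-8))
            gain_v += int(np.sum(run.final["V"].to_numpy() < 5e-8))
        assert gain_v >= gain_p

    def test_carried_values_bit_equal_and_v_in_range(self, cfdr_world):
        cfg, g, ld = cfdr_world
        prin, aux = simulate_trait_pair(g, cfg, seed=47)
        run = iterate_cfdr(prin, [aux], ld)
        v = run.final["V"].to_numpy()
        assert ((v > 0) & (v <= 1)).all()
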