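"""Free-energy estimators: TI quadrature, BAR recovery, cycle, block SE, dipole."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdtraj import synthetic
from cdtraj.energetics import (
    E_NM_TO_DEBYE, LambdaWindowSamples, bar_estimate, bar_from_lambda_samples,
    binding_cycle, block_average, dipole_moment, exp_estimate, ti_integrate,
)

KT_310 = 2.577  # kJ/mol at 310 K


def samples_from_function(fn, lams, n_per=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    dhdl = [np.full(n_per, fn(l)) + rng.normal(0, noise, n_per) for l in lams]
    return LambdaWindowSamples(lambdas=np.asarray(lams), dhdl=dhdl)


class TestTI:
    def test_constant_integrand(self):
        s = samples_from_function(lambda l: 4.2, [0.0, 0.3, 0.7, 1.0])
        assert ti_integrate(s, n_boot=10).delta_g == pytest.approx(4.2, abs=1e-12)

    def test_linear_integrand_exact_on_three_points(self):
        a, b = 2.0, -6.0
        s = samples_from_function(lambda l: a + b * l, [0.0, 0.5, 1.0])
        assert ti_integrate(s, n_boot=10).delta_g == pytest.approx(a + b / 2, abs=1e-12)

    def test_quadratic_on_25_point_grid(self):
        """Trapezoid on a 25-point uniform grid: within 0.1% of the analytic integral."""
        lams = np.linspace(0, 1, 25)
        s = samples_from_function(lambda l: 30.0 * l ** 2, lams)
        exact = 30.0 / 3
        assert ti_integrate(s, n_boot=10).delta_g == pytest.approx(exact, rel=1e-3)

    @given(seed=st.integers(0, 1000), n=st.integers(2, 12))
    @settings(max_examples=40, deadline=None)
    def test_trapezoid_exact_for_affine_on_random_grids(self, seed, n):
        rng = np.random.default_rng(seed)
        lams = np.sort(rng.uniform(0, 1, n))
        lams[0], lams[-1] = 0.0, 1.0
        if len(np.unique(lams)) < n:
            lams = np.linspace(0, 1, n)
        a, b = rng.uniform(-50, 50, 2)
        s = samples_from_function(lambda l: a + b * l, lams)
        assert ti_integrate(s, n_boot=0).delta_g == pytest.approx(a + b / 2, abs=1e-9)

    def test_single_lambda_rejected(self):
        s = LambdaWindowSamples(lambdas=[0.0], dhdl=[np.ones(5)])
        with pytest.raises(ValueError):
            ti_integrate(s)

    def test_bootstrap_se_shrinks_with_samples(self):
        small = samples_from_function(lambda l: 1.0, [0.0, 1.0], n_per=10,
                                      noise=2.0, seed=1)
        big = samples_from_function(lambda l: 1.0, [0.0, 1.0], n_per=1000,
                                    noise=2.0, seed=1)
        assert ti_integrate(big, seed=0).se < ti_integrate(small, seed=0).se


class TestBAR:
    def test_degenerate_crooks_pair(self):
        c = 12.5
        res = bar_estimate(np.full(40, c), np.full(40, -c), KT_310, n_boot=0)
        assert res.delta_g == pytest.approx(c, abs=1e-9)

    def test_symmetric_samples_give_zero(self):
        rng = np.random.default_rng(0)
        w = rng.normal(3.0, 2.0, size=500)
        res = bar_estimate(np.concatenate([w, -w]), np.concatenate([w, -w]),
                           KT_310, n_boot=0)
        assert res.delta_g == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_free_energy(self):
        """Crooks-consistent Gaussians at the binding-energy scale: within 3 SE."""
        spec = synthetic.WorkSampleSpec(delta_g_true=-70.0, sigma_w=5.0,
                                        kT=KT_310, seed=21)
        s = synthetic.make_bar_samples(spec)
        res = bar_estimate(s.forward[0], s.reverse[0], KT_310, seed=1)
        assert res.se > 0
        assert abs(res.delta_g - (-70.0)) < 3 * res.se

    def test_label_swap_antisymmetry(self):
        """Swapping forward and reverse sample sets negates the estimate."""
        rng = np.random.default_rng(5)
        w_f = rng.normal(-60.0, 6.0, size=800)
        w_r = rng.normal(70.0, 6.0, size=500)   # unequal n exercises M
        a = bar_estimate(w_f, w_r, KT_310, n_boot=0).delta_g
        b = bar_estimate(w_r, w_f, KT_310, n_boot=0).delta_g
        assert a + b == pytest.approx(0.0, abs=1e-8)

    def test_one_sided_limit_approaches_exp(self):
        """With a single dummy reverse sample BAR sits near exponential averaging."""
        rng = np.random.default_rng(9)
        w_f = rng.normal(10.0, 1.0, size=5000)
        exp = exp_estimate(w_f, KT_310)
        near = bar_estimate(w_f, np.array([-exp]), KT_310, n_boot=0).delta_g
        assert near == pytest.approx(exp, abs=0.5)

    def test_windowed_sum_is_exact(self):
        s = synthetic.make_bar_samples(
            synthetic.WorkSampleSpec(n_forward=300, n_reverse=300, seed=2))
        res = bar_from_lambda_samples(s, n_boot=5, seed=0)
        assert res.delta_g == pytest.approx(res.windows["delta_g"].sum(), abs=1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            bar_estimate(np.array([]), np.ones(5), KT_310)

    def test_parameter_recovery_coverage(self):
        """Over seeded replicates the +/-2 SE interval covers dG_true >= 90%."""
        hits = 0
        errs = []
        n_rep = 40
        for seed in range(n_rep):
            s = synthetic.make_bar_samples(synthetic.WorkSampleSpec(
                delta_g_true=-70.0, sigma_w=5.0, kT=KT_310,
                n_forward=2000, n_reverse=2000, seed=seed))
            res = bar_estimate(s.forward[0], s.reverse[0], KT_310,
                               n_boot=100, seed=seed)
            errs.append(res.delta_g + 70.0)
            if abs(res.delta_g + 70.0) <= 2 * res.se:
                hits += 1
        assert hits / n_rep >= 0.90
        assert abs(np.mean(errs)) < 0.005 * 70.0  # bias below 0.5%


class TestCycle:
    def test_equal_legs_cancel(self):
        assert binding_cycle(10.0, 10.0).delta_g == 0.0

    def test_harder_decoupling_from_complex_means_favourable_binding(self):
        res = binding_cycle(decouple_in_water=11.18,
                            decouple_in_complex=11.18 + 77.49)
        assert res.delta_g == pytest.approx(-77.49)
        assert "negative" in res.convention

    def test_compositionality_with_bar_legs(self):
        water = synthetic.make_bar_samples(
            synthetic.WorkSampleSpec(delta_g_true=11.18, n_forward=400,
                                     n_reverse=400, seed=3))
        complx = synthetic.make_bar_samples(
            synthetic.WorkSampleSpec(delta_g_true=88.67, n_forward=400,
                                     n_reverse=400, seed=4))
        leg_w = bar_estimate(water.forward[0], water.reverse[0], KT_310, n_boot=5)
        leg_c = bar_estimate(complx.forward[0], complx.reverse[0], KT_310, n_boot=5)
        res = binding_cycle(leg_w, leg_c)
        assert res.delta_g == pytest.approx(leg_w.delta_g - leg_c.delta_g, abs=1e-12)


class TestBlockAverage:
    def test_constant_series(self):
        mean, se = block_average(np.full(100, 3.3), 5)
        assert mean == pytest.approx(3.3)
        assert se == 0.0

    def test_alternating_series(self):
        s = np.tile([1.0, -1.0], 50)
        mean, se = block_average(s, 5)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_ar1_se_matches_analytic(self):
        """Block SE of an AR(1) mean agrees with the analytic formula."""
        phi, sigma = 0.5, 1.0
        n = 10_000
        rng = np.random.default_rng(12)
        x = np.empty(n)
        x[0] = rng.normal(0, sigma / np.sqrt(1 - phi ** 2))
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal(0, sigma)
        var_x = sigma ** 2 / (1 - phi ** 2)
        analytic_se = np.sqrt(var_x * (1 + phi) / (1 - phi) / n)
        _, se = block_average(x, n_blocks=50)
        assert se == pytest.approx(analytic_se, rel=0.20)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            block_average(np.ones(3), 5)


class TestDipole:
    def test_unit_debye_pair(self):
        pos = np.array([[0.0, 0, 0], [1.0 / E_NM_TO_DEBYE, 0, 0]])
        assert dipole_moment(pos, np.array([-1.0, 1.0])) == pytest.approx(1.0, rel=1e-6)

    def test_zero_charges(self):
        rng = np.random.default_rng(0)
        assert dipole_moment(rng.normal(size=(5, 3)), np.zeros(5)) == 0.0

    def test_neutral_group_translation_invariant_and_matches_oracle(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(8, 3))
        q = rng.normal(size=8)
        q -= q.mean()  # neutral
        oracle = np.linalg.norm(sum(qi * ri for qi, ri in zip(q, pos))) * E_NM_TO_DEBYE
        assert dipole_moment(pos, q) == pytest.approx(oracle, abs=1e-10)
        shifted = dipole_moment(pos + [5.0, -2.0, 7.0], q)
        assert shifted == pytest.approx(dipole_moment(pos, q), abs=1e-10)

    def test_no_charges_rejected(self):
        with pytest.raises(ValueError):
            dipole_moment(np.empty((0, 3)), np.array([]))
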