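"""Skyline likelihood, calibration, ESS and MCMC against analytic oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from mitopop.genealogy import Genealogy, GenealogyNode
from mitopop.simulate import DemographicModel, simulate_genealogy
from mitopop.skyline import (
    RatePrior,
    SkylineModel,
    calibrate_tree,
    coalescent_loglik,
    default_group_sizes,
    ess,
    fit_skyline,
    skyline_summary,
    _interval_stats,
)


def two_tip_tree(t2, age_a=0.0, age_b=0.0):
    root = GenealogyNode(time=t2)
    root.add_child(GenealogyNode(time=age_a, label="a"))
    root.add_child(GenealogyNode(time=age_b, label="b"))
    return Genealogy(root)


def oracle_loglik(gen, group_sizes, thetas):
    """Independent evaluation of the heterochronous skyline density.

    k(t) and theta(t) are evaluated pointwise from raw tip ages and
    event times; the waiting-time integral is computed by adaptive
    quadrature with breakpoints, not by the implementation's interval
    bookkeeping.
    """
    tip_ages = sorted(gen.tip_ages().values())
    coal = gen.coalescent_times()
    group_of = np.repeat(np.arange(len(group_sizes)), group_sizes)

    def k(t):
        return sum(a <= t for a in tip_ages) - sum(c <= t for c in coal)

    def theta(t):
        i = sum(c < t for c in coal)  # index of next event
        return thetas[group_of[min(i, len(coal) - 1)]]

    def hazard(t):
        kk = k(t)
        return kk * (kk - 1) / (2.0 * theta(t))

    t0, t1 = min(tip_ages), max(coal)
    breaks = sorted(set(tip_ages + coal))
    total = 0.0
    for lo, hi in zip(breaks, breaks[1:]):
        val, _ = integrate.quad(hazard, lo, hi, epsabs=1e-13, epsrel=1e-13, limit=200)
        total += val
    ll = -total
    for i, c in enumerate(coal):
        kk = k(c - 1e-9)  # lineage count just before the event
        ll += math.log(kk * (kk - 1) / (2.0 * thetas[group_of[i]]))
    return ll


class TestCalibrateTree:
    def test_rate_reproduces_known_times(self):
        tree = two_tip_tree(1e-4).scaled(1.0, units="subs")
        out = calibrate_tree(tree, RatePrior(mean=1e-8, sd=0.0))
        assert out.tmrca == pytest.approx(1e4)
        assert out.units == "years"

    def test_doubling_rate_halves_times(self):
        tree = two_tip_tree(1e-4).scaled(1.0, units="subs")
        a = calibrate_tree(tree, RatePrior(mean=1e-8))
        b = calibrate_tree(tree, RatePrior(mean=2e-8))
        assert b.tmrca == pytest.approx(a.tmrca / 2)

    def test_rejects_tree_already_in_years(self):
        with pytest.raises(ValueError):
            calibrate_tree(two_tip_tree(100.0), RatePrior(mean=1e-8))

    def test_tip_age_violation_lists_offenders(self):
        tree = two_tip_tree(1e-4, age_a=0.0, age_b=5e-5).scaled(1.0, units="subs")
        with pytest.raises(ValueError, match="b"):
            calibrate_tree(tree, RatePrior(mean=1e-8),
                           expected_tip_ages={"a": 0.0, "b": 100.0})

    def test_roundtrip_through_simulated_clock(self):
        """A tree scaled to subs/site at a known clock rate calibrates
        back to the simulation's true node times."""
        demog = DemographicModel(epochs=[(0.0, 2000.0)], generation_time=1.0)
        gen = simulate_genealogy(demog, [(f"t{i}", 0.0) for i in range(8)], seed=42)
        rate = 1.0e-8
        subs_tree = gen.scaled(rate, units="subs")
        back = calibrate_tree(subs_tree, RatePrior(mean=rate, sd=1e-9))
        assert back.tmrca == pytest.approx(gen.tmrca, rel=1e-2)

    def test_resample_mode_uses_prior_spread(self):
        tree = two_tip_tree(1e-4).scaled(1.0, units="subs")
        rng = np.random.default_rng(0)
        prior = RatePrior(mean=1e-8, sd=2e-9)
        vals = {calibrate_tree(tree, prior, mode="resample", rng=rng).tmrca
                for _ in range(5)}
        assert len(vals) == 5


class TestCoalescentLoglik:
    def test_two_tip_closed_form_and_mle(self):
        t2 = 1234.0
        gen = two_tip_tree(t2)
        thetas = np.linspace(200, 5000, 60)
        lls = [
            coalescent_loglik(gen, SkylineModel(group_sizes=[1], thetas=[th]))
            for th in thetas
        ]
        expected = [math.log(1 / th) - t2 / th for th in thetas]
        assert np.allclose(lls, expected)
        assert thetas[int(np.argmax(lls))] == pytest.approx(t2, rel=0.05)

    def test_time_rescaling_jacobian(self):
        """Scaling all times and thetas by c shifts loglik by -(n-1) log c."""
        demog = DemographicModel(epochs=[(0.0, 1000.0)], generation_time=1.0)
        gen = simulate_genealogy(demog, [(f"t{i}", 0.0) for i in range(7)], seed=3)
        thetas = np.array([800.0, 1500.0])
        model = SkylineModel(group_sizes=[3, 3], thetas=thetas)
        base = coalescent_loglik(gen, model)
        c = 3.7
        scaled_model = SkylineModel(group_sizes=[3, 3], thetas=thetas * c)
        scaled = coalescent_loglik(gen.scaled(c), scaled_model)
        assert scaled == pytest.approx(base - (gen.n_tips - 1) * math.log(c))

    def test_matches_independent_quadrature_oracle(self):
        """Implementation equals a brute-force integrator on random
        heterochronous trees (n <= 6), to 1e-9."""
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(2, 7))
            ages = rng.uniform(0, 50, size=n)
            ages[0] = 0.0
            demog = DemographicModel(epochs=[(0.0, float(rng.uniform(50, 500)))],
                                     generation_time=1.0)
            gen = simulate_genealogy(
                demog, [(f"t{i}", float(a)) for i, a in enumerate(ages)],
                seed=int(rng.integers(2**31 - 1)),
            )
            m = int(rng.integers(1, n))
            sizes = default_group_sizes(n - 1, m)
            thetas = rng.uniform(50, 2000, size=m)
            ours = coalescent_loglik(gen, SkylineModel(group_sizes=sizes, thetas=thetas))
            ref = oracle_loglik(gen, sizes, thetas)
            assert ours == pytest.approx(ref, abs=1e-7 * max(1, abs(ref)))

    def test_single_group_mle_recovers_theta(self):
        """MLE theta-hat = A/(n-1) over simulated trees averages to truth."""
        theta_star = 700.0
        demog = DemographicModel(epochs=[(0.0, theta_star)], generation_time=1.0)
        tips = [(f"t{i}", 0.0) for i in range(20)]
        mles = []
        for seed in range(200):
            gen = simulate_genealogy(demog, tips, seed=seed)
            st = _interval_stats(gen, [gen.n_tips - 1])
            mles.append(st.a[0] / st.c[0])
        assert abs(np.mean(mles) - theta_star) / theta_star < 0.05

    def test_rejects_bad_groupings_and_thetas(self):
        gen = two_tip_tree(100.0)
        with pytest.raises(ValueError):
            coalescent_loglik(gen, SkylineModel(group_sizes=[2], thetas=[1.0, 1.0]))
        with pytest.raises(ValueError):
            SkylineModel(group_sizes=[1], thetas=[-5.0])


class TestESS:
    def test_iid_trace(self):
        x = np.random.default_rng(1).standard_normal(10000)
        assert abs(ess(x) - 10000) / 10000 < 0.2

    def test_alternating_trace_capped_at_n(self):
        x = np.tile([1.0, -1.0], 5000)
        assert ess(x) == 10000

    def test_ar1_closed_form(self):
        """AR(1) with rho=0.9 has ESS = N(1-rho)/(1+rho) ~ N/19."""
        rho, n = 0.9, 10000
        rng = np.random.default_rng(3)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + math.sqrt(1 - rho**2) * rng.standard_normal()
        expected = n * (1 - rho) / (1 + rho)
        assert abs(ess(x) - expected) / expected < 0.3

    def test_constant_trace_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert ess(np.ones(100)) == 0.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestFitSkyline:
    def test_two_tip_posterior_matches_conjugate_form(self):
        """Under the 1/theta prior the 2-tip posterior is inverse-gamma
        with shape 1 and scale t2; compare thinned MCMC draws by KS."""
        t2 = 500.0
        gen = two_tip_tree(t2)
        post = fit_skyline(gen, m=1, chain_length=60000, seed=4,
                           joint_scale_move=False)
        draws = post.thetas[::60, 0]
        res = stats.kstest(draws, stats.invgamma(a=1, scale=t2).cdf)
        assert res.pvalue > 0.01

    def test_deterministic_trace_given_seed(self):
        gen = simulate_genealogy(
            DemographicModel(epochs=[(0.0, 500.0)], generation_time=1.0),
            [(f"t{i}", 0.0) for i in range(12)], seed=5,
        )
        a = fit_skyline(gen, m=3, chain_length=2000, seed=11)
        b = fit_skyline(gen, m=3, chain_length=2000, seed=11)
        assert np.array_equal(a.thetas, b.thetas)

    def test_acceptance_rates_in_tuned_window(self):
        gen = simulate_genealogy(
            DemographicModel(epochs=[(0.0, 500.0)], generation_time=1.0),
            [(f"t{i}", 0.0) for i in range(30)], seed=6,
        )
        post = fit_skyline(gen, m=5, chain_length=12000, seed=2)
        assert np.all(post.acceptance > 0.10) and np.all(post.acceptance < 0.55)
        assert np.all(post.ess() > 200)  # pipeline convergence gate

    def test_m_exceeding_events_rejected(self):
        gen = two_tip_tree(100.0)
        with pytest.raises(ValueError):
            fit_skyline(gen, m=5, chain_length=2000, seed=1)

    def test_too_short_chain_rejected(self):
        gen = two_tip_tree(100.0)
        with pytest.raises(ValueError):
            fit_skyline(gen, m=1, chain_length=80, seed=1)


class TestSkylineSummary:
    @staticmethod
    def _post():
        gen = simulate_genealogy(
            DemographicModel(epochs=[(0.0, 800.0)], generation_time=1.0),
            [(f"t{i}", 0.0) for i in range(20)], seed=8,
        )
        return fit_skyline(gen, m=4, chain_length=4000, seed=9)

    def test_gen_time_unit_law(self):
        post = self._post()
        a = skyline_summary(post, gen_time=1.0)
        b = skyline_summary(post, gen_time=2.0)
        assert np.allclose(a.ne_median.values, 2 * b.ne_median.values)

    def test_grid_beyond_root_truncated_with_warning(self):
        post = self._post()
        root = post.boundaries[-1]
        with pytest.warns(UserWarning, match="root"):
            traj = skyline_summary(post, grid=np.array([0.0, root * 10]))
        assert len(traj) == 1

    def test_single_sample_posterior_degenerate_band(self):
        post = self._post()
        post.thetas = post.thetas[:1]
        post.loglik = post.loglik[:1]
        traj = skyline_summary(post, gen_time=1.0)
        assert np.allclose(traj.ne_low, traj.ne_median)
        assert np.allclose(traj.ne_high, traj.ne_median)

    def test_constant_truth_trajectory_flat_within_band(self):
        """Posterior band should bracket a constant truth across the grid
        in most recovery runs."""
        theta_star = 800.0
        hits = 0
        for seed in range(10):
            gen = simulate_genealogy(
                DemographicModel(epochs=[(0.0, theta_star)], generation_time=1.0),
                [(f"t{i}", 0.0) for i in range(20)], seed=seed,
            )
            post = fit_skyline(gen, m=4, chain_length=8000, seed=seed + 100)
            traj = skyline_summary(post, gen_time=1.0)
            if np.all((traj.ne_low <= theta_star) & (theta_star <= traj.ne_high)):
                hits += 1
        assert hits >= 8
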