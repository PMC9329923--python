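import dataclasses

import numpy as np
import pytest

from follisim import (
    BiphasicParams,
    DegenerateCohortError,
    ParameterError,
    SimulationConfig,
    classify_ovulating,
    growth_rhs,
    integrate_cohort,
    normalize_time,
    phi,
    sample_initial_sizes,
    simulate_continual_entry,
    symmetric_velocity,
    twin_scenario,
)
from follisim.simulate import CONTINUAL_ENTRY

from conftest import integrate_rk4


class TestSampling:
    def test_deterministic_per_seed(self):
        cfg = SimulationConfig(n_follicles=8, seed=42)
        np.testing.assert_array_equal(sample_initial_sizes(cfg), sample_initial_sizes(cfg))

    def test_uniform_moments(self):
        cfg = SimulationConfig(n_follicles=1000, seed=7)
        x = sample_initial_sizes(cfg)
        assert x.min() >= 0.05 and x.max() <= 0.15
        se = (0.1 / np.sqrt(12)) / np.sqrt(1000)
        assert abs(x.mean() - 0.10) < 3 * se

    def test_explicit_sizes_passthrough(self):
        sizes = (0.1, 0.0999, 0.07, 0.06, 0.05)
        cfg = SimulationConfig(n_follicles=5, explicit_initial_sizes=sizes)
        np.testing.assert_array_equal(sample_initial_sizes(cfg), sizes)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(init_low=0.2, init_high=0.1)


class TestIntegrateCohort:
    def test_symmetric_cohort_grows_linearly(self, params_triple):
        # M equal follicles: x_i(t) = x_i(0) + v*t exactly
        M, x0 = 3, 0.4
        v = symmetric_velocity(M, params_triple)
        cfg = SimulationConfig(
            n_follicles=M, surge_multiplier=None, t_max=50.0,
            explicit_initial_sizes=(x0,) * M,
        )
        traj = integrate_cohort([x0] * M, params_triple, cfg)
        expected = x0 + v * traj.times
        np.testing.assert_allclose(
            traj.sizes, np.tile(expected[:, None], (1, M)), rtol=1e-6
        )

    def test_scaling_symmetry(self, params_single):
        # x^(c)(t) = c * x(t/c): rescaling sizes rescales time
        c = 3.0
        x0 = np.array([0.12, 0.10, 0.07, 0.06, 0.09])
        cfg = SimulationConfig(n_follicles=5, surge_multiplier=None, t_max=30.0)
        cfg_scaled = dataclasses.replace(cfg, t_max=30.0 * c, n_report=400)
        base = integrate_cohort(x0, params_single, cfg)
        scaled = integrate_cohort(c * x0, params_single, cfg_scaled)
        # scaled trajectory sampled at c*t must equal c * base at t
        np.testing.assert_allclose(scaled.sizes, c * base.sizes, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(scaled.times, c * base.times, rtol=1e-12)

    def test_surge_event_accuracy(self, params_single, five_follicle_config):
        traj = integrate_cohort(
            sample_initial_sizes(five_follicle_config), params_single, five_follicle_config
        )
        assert traj.surge_time is not None
        ratio = traj.total_size[-1] / traj.total_size[0]
        assert ratio == pytest.approx(4.6, rel=1e-6)

    def test_ranking_preserved(self, params_single, five_follicle_config):
        x0 = sample_initial_sizes(five_follicle_config)
        assert len(np.unique(x0)) == len(x0)
        traj = integrate_cohort(x0, params_single, five_follicle_config)
        order0 = np.argsort(x0)
        for row in traj.sizes:
            # ranking identical wherever sizes remain distinct
            np.testing.assert_array_equal(np.argsort(row, kind="stable"), order0)

    def test_agrees_with_fixed_step_reference(self, params_single, five_follicle_config):
        x0 = sample_initial_sizes(five_follicle_config)
        cfg = dataclasses.replace(five_follicle_config, surge_multiplier=None, t_max=2.0)
        traj = integrate_cohort(x0, params_single, cfg)
        _, x_ref = integrate_rk4(
            lambda x: growth_rhs(np.maximum(x, 0.0), params_single), x0, 2.0, 1e-4
        )
        np.testing.assert_allclose(traj.final_sizes, x_ref, rtol=1e-5)

    def test_all_zero_cohort_rejected(self, params_single, five_follicle_config):
        with pytest.raises(DegenerateCohortError):
            integrate_cohort([0.0] * 5, params_single, five_follicle_config)

    def test_total_extinction_terminates_cleanly(self):
        # a cohort entirely below the growth window shrinks to nothing
        p = BiphasicParams(5.9, 13.0)
        cfg = SimulationConfig(
            n_follicles=5, surge_multiplier=4.6, t_max=500.0,
            explicit_initial_sizes=(0.1,) * 5,
        )
        traj = integrate_cohort([0.1] * 5, p, cfg)
        assert traj.surge_time is None
        assert traj.total_size[-1] < 1e-5 * traj.total_size[0]
        assert classify_ovulating(traj, p).count == 0

    def test_no_growth_arrest_plateaus(self, params_single, five_follicle_config):
        # any competing follicle with a (relatively) stalled derivative must
        # be at a zero of phi or at size ~ 0
        traj = integrate_cohort(
            sample_initial_sizes(five_follicle_config), params_single, five_follicle_config
        )
        for row in traj.sizes[traj.times > 0.5 * traj.times[-1]]:
            tot = row.sum()
            d = growth_rhs(row, params_single)
            stalled = np.abs(d) < 1e-8 * tot
            u = row / tot
            near_zero_size = u < 1e-6
            near_phi_zero = np.minimum(
                np.abs(u - 1 / params_single.m1), np.abs(u - 1 / params_single.m2)
            ) < 1e-6
            assert np.all(~stalled | near_zero_size | near_phi_zero)


class TestClassification:
    def test_race_selects_single_winner(self, params_single, five_follicle_config):
        traj = integrate_cohort(
            sample_initial_sizes(five_follicle_config), params_single, five_follicle_config
        )
        out = classify_ovulating(traj, params_single)
        assert out.count == 1
        assert out.classification_rule == "growth+size"

    def test_all_shrinking_counts_zero(self):
        # equal follicles with phi(1/N + A_ex) < 0: everything shrinking
        p = BiphasicParams(0.9, 10.0, a_ex=5.0)
        cfg = SimulationConfig(
            n_follicles=4, surge_multiplier=None, t_max=5.0,
            explicit_initial_sizes=(0.5,) * 4,
        )
        traj = integrate_cohort([0.5] * 4, p, cfg)
        assert classify_ovulating(traj, p).count == 0

    def test_alternative_rules(self, params_single, five_follicle_config):
        traj = integrate_cohort(
            sample_initial_sizes(five_follicle_config), params_single, five_follicle_config
        )
        for rule in ("growth", "fraction", "growth+size"):
            out = classify_ovulating(traj, params_single, rule=rule)
            assert out.count >= 1
            assert out.classification_rule == rule
        with pytest.raises(ParameterError):
            classify_ovulating(traj, params_single, rule="nope")


class TestTwins:
    def test_near_identical_leaders_ovulate_together(self):
        p = BiphasicParams(0.5, 4.0)
        cfg = SimulationConfig(n_follicles=5, seed=0, t_max=400.0)
        out = twin_scenario(0.001, p, cfg)
        assert out.count == 2
        assert out.ovulating_indices == frozenset({0, 1})

    def test_smaller_twin_eventually_shrinks(self):
        p = BiphasicParams(0.5, 4.0)
        cfg = SimulationConfig(n_follicles=5, seed=0, t_max=300.0)
        out = twin_scenario(0.001, p, cfg, surge=False)
        assert out.count == 1
        assert out.ovulating_indices == frozenset({0})

    def test_exactly_equal_twins_never_separate(self):
        p = BiphasicParams(0.5, 4.0)
        cfg = SimulationConfig(n_follicles=5, seed=0, t_max=300.0)
        out, traj = twin_scenario(0.0, p, cfg, surge=False, return_trajectory=True)
        np.testing.assert_allclose(traj.sizes[:, 0], traj.sizes[:, 1], rtol=1e-9)
        assert out.count == 2

    def test_rejects_bad_delta(self):
        p = BiphasicParams(0.5, 4.0)
        cfg = SimulationConfig(n_follicles=5)
        with pytest.raises(ParameterError):
            twin_scenario(-0.01, p, cfg)
        with pytest.raises(ParameterError):
            twin_scenario(0.2, p, cfg)


class TestContinualEntry:
    def _config(self, **kw):
        base = dict(
            mode=CONTINUAL_ENTRY, n_entries=6, entry_window=10.0,
            t_max=20.0, surge_multiplier=None, seed=3,
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_pre_switch_growth_is_exponential(self):
        p = BiphasicParams(0.9, 10.0)
        cfg = self._config()
        traj = simulate_continual_entry(p, cfg)
        for i, t_entry in enumerate(traj.entry_times):
            pre = traj.times < t_entry - 1e-9
            if pre.sum() < 3:
                continue
            expected = traj.sizes[0, i] * np.exp(cfg.gamma * traj.times[pre])
            np.testing.assert_allclose(traj.sizes[pre, i], expected, rtol=1e-6)

    def test_entry_at_critical_size(self):
        p = BiphasicParams(0.9, 10.0)
        cfg = self._config()
        traj = simulate_continual_entry(p, cfg)
        # size at the switch equals x_c (closed form: x_c e^{-g t_i} e^{g t_i})
        for i, t_entry in enumerate(traj.entry_times):
            k = np.searchsorted(traj.times, t_entry)
            if 0 < k < len(traj.times):
                lo, hi = traj.sizes[k - 1, i], traj.sizes[k, i]
                assert min(lo, hi) < cfg.x_c * 1.05

    def test_high_androgen_all_competing_follicles_decline(self):
        p = BiphasicParams(0.9, 10.0, alpha=0.005, a_ex=5.0)
        cfg = self._config(n_entries=10, entry_window=10.0, t_max=30.0)
        traj = simulate_continual_entry(p, cfg)
        assert classify_ovulating(traj, p).count == 0
        for i, t_entry in enumerate(traj.entry_times):
            post = traj.times >= t_entry
            s = traj.sizes[post, i]
            if len(s) < 5:
                continue
            # rises to a peak near x_c, then declines monotonically (to tolerance)
            assert s.max() <= cfg.x_c * 1.01
            peak = int(np.argmax(s))
            tail = s[peak:]
            assert np.all(np.diff(tail) <= 1e-9)

    def test_ovulatory_single_dominant_constant_velocity(self):
        p = BiphasicParams(0.9, 10.0)
        cfg = self._config(n_entries=7, entry_window=40.0, t_max=60.0, seed=0)
        traj = simulate_continual_entry(p, cfg)
        out = classify_ovulating(traj, p)
        assert out.count == 1
        dom = int(np.argmax(traj.final_sizes))
        # dominant velocity approaches alpha*phi(1): compare two late windows
        late = traj.times > 0.6 * traj.times[-1]
        t_l, x_l = traj.times[late], traj.sizes[late, dom]
        v = np.gradient(x_l, t_l)
        assert np.std(v[-20:]) / np.mean(v[-20:]) < 0.05

    def test_mode_mismatch_rejected(self):
        p = BiphasicParams(0.9, 10.0)
        with pytest.raises(ParameterError):
            simulate_continual_entry(p, SimulationConfig(mode="fixed-cohort"))


class TestPcosShutdown:
    def test_growth_window_closed_pointwise(self):
        # A_ex >= 1/M1 makes phi(u + A_ex) < 0 on all of [0, 1]
        p = BiphasicParams(0.9, 10.0, a_ex=5.0)
        assert 5.0 >= 1 / p.m1
        u = np.linspace(0.0, 1.0, 501)
        assert np.all(phi(u + p.a_ex, p) < 0)
        d = growth_rhs(np.array([0.3, 0.5, 0.2]), p)
        assert np.all(d < 0)


class TestNormalizeTime:
    def test_rescale_to_target(self, params_single, five_follicle_config):
        traj = integrate_cohort(
            sample_initial_sizes(five_follicle_config), params_single, five_follicle_config
        )
        day14 = normalize_time(traj, 14.0)
        assert day14.surge_time == pytest.approx(14.0)
        np.testing.assert_array_equal(day14.sizes, traj.sizes)
        np.testing.assert_allclose(day14.times, traj.times * 14.0 / traj.surge_time)

    def test_idempotent(self, params_single, five_follicle_config):
        traj = integrate_cohort(
            sample_initial_sizes(five_follicle_config), params_single, five_follicle_config
        )
        once = normalize_time(traj, 14.0)
        twice = normalize_time(once, 14.0)
        np.testing.assert_allclose(twice.times, once.times, rtol=1e-12)

    def test_velocity_chain_rule(self, params_single, five_follicle_config):
        traj = integrate_cohort(
            sample_initial_sizes(five_follicle_config), params_single, five_follicle_config
        )
        day14 = normalize_time(traj, 14.0)
        dom = int(np.argmax(traj.final_sizes))
        k = len(traj.times) // 2
        v_model = np.gradient(traj.sizes[k:, dom], traj.times[k:])[-1]
        v_day = np.gradient(day14.sizes[k:, dom], day14.times[k:])[-1]
        assert v_day == pytest.approx(v_model * traj.surge_time / 14.0, rel=1e-9)
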