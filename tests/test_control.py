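"""PI and bang-bang laws, closed-loop behaviour, periodic forcing."""

import numpy as np
import pytest

from togglectl import (CellState, ControllerConfig, InducerSchedule,
                       bangbang_law, pi_law)
from togglectl.control import commitment_label, release_schedule


@pytest.fixture()
def cfg():
    return ControllerConfig(mode="pi", target_LacI=500.0, target_TetR=300.0)


class TestPiLaw:
    def test_zero_error_returns_basal(self, cfg):
        u = pi_law(200.0, 500.0, 300.0, 0.0, 0.0, cfg)
        assert u == (20.0, 0.25)

    def test_saturation_at_bounds(self, cfg):
        # large positive LacI error pushes aTc to its max, negative to 0
        big = ControllerConfig(mode="pi", target_LacI=2000.0,
                               target_TetR=300.0)
        assert pi_law(0.0, 0.0, 300.0, 0.0, 0.0, big)[0] == 50.0
        assert pi_law(0.0, 5000.0, 300.0, 0.0, 0.0, cfg)[0] == 0.0
        assert pi_law(0.0, 500.0, 0.0, 0.0, 0.0, cfg)[1] == 0.5
        assert pi_law(0.0, 500.0, 5000.0, 0.0, 0.0, cfg)[1] == 0.0

    def test_integral_ignored_before_window_opens(self, cfg):
        # nonzero accumulated error contributes nothing while t <= t_d
        u_before = pi_law(cfg.t_d, 500.0, 300.0, 1e4, 1e4, cfg)
        assert u_before == (20.0, 0.25)
        u_after = pi_law(cfg.t_d + 1.0, 500.0, 300.0, 1e4, 1e4, cfg)
        assert u_after != u_before

    def test_integral_gain_direction(self, cfg):
        u_pos = pi_law(500.0, 500.0, 300.0, 1000.0, 0.0, cfg)
        u_neg = pi_law(500.0, 500.0, 300.0, -1000.0, 0.0, cfg)
        assert u_pos[0] > 20.0 > u_neg[0]


class TestBangBangLaw:
    def test_below_target_applies_max(self, cfg):
        cfg2 = ControllerConfig(mode="bangbang", target_LacI=500.0,
                                target_TetR=300.0)
        assert bangbang_law(100.0, 100.0, cfg2) == (50.0, 0.5)

    def test_at_target_takes_min_branch(self, cfg):
        cfg2 = ControllerConfig(mode="bangbang", target_LacI=500.0,
                                target_TetR=300.0)
        assert bangbang_law(500.0, 300.0, cfg2) == (0.0, 0.0)

    def test_independent_of_gains(self):
        a = ControllerConfig(mode="bangbang", target_LacI=500.0,
                             target_TetR=300.0)
        b = ControllerConfig(mode="bangbang", target_LacI=500.0,
                             target_TetR=300.0, K_P_L=99.0, K_I_L=99.0,
                             K_P_T=99.0, K_I_T=99.0)
        for meas in [(0, 0), (600, 200), (500, 300)]:
            assert bangbang_law(*meas, a) == bangbang_law(*meas, b)


class TestConfigValidation:
    def test_bad_mode(self):
        with pytest.raises(ValueError):
            ControllerConfig(mode="pid")

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            ControllerConfig(u_max_aTc=0.0)

    def test_bad_timing(self):
        with pytest.raises(ValueError):
            ControllerConfig(t_d=-1.0)
        with pytest.raises(ValueError):
            ControllerConfig(dt_meas=0.0)


class TestClosedLoop:
    def test_pi_holds_state_near_saddle_while_open_loop_commits(
            self, model, saddle_state, reference_u):
        """The dual PI loop keeps a deterministic cell in the unstable region.

        From a perturbed near-saddle start the controlled cell keeps a
        moderate time-averaged tracking error and never approaches either
        stable attractor, while the same cell under constant basal inputs
        commits to one of them.
        """
        report = model.equilibria(reference_u)
        y = saddle_state.as_array() * np.array([1, 1, 1.1, 1 / 1.1, 1, 1])
        s0 = CellState.from_array(y)
        cfg = ControllerConfig(mode="pi")
        rec = model.control("ode", cfg, t_end=1500.0, state0=s0)
        L = rec.measured[:, 0]
        T = rec.measured[:, 1]
        mask = rec.times >= cfg.t_d
        rel_err = np.mean(np.abs(L[mask] - rec.config.target_LacI)) \
            / rec.config.target_LacI
        assert rel_err < 0.5
        X = np.column_stack([L, T])
        for eq in report.stable:
            q = np.array([eq.LacI, eq.TetR])
            d = np.linalg.norm(X - q, axis=1) / np.linalg.norm(q)
            assert d.min() > 0.2

        # open loop: basal inputs, same start -> commitment
        traj = model.simulate(s0, InducerSchedule.reference(), 1500.0)
        final = traj.final_state()
        dists = [np.linalg.norm(np.array([final.LacI, final.TetR])
                                - np.array([eq.LacI, eq.TetR]))
                 / np.linalg.norm([eq.LacI, eq.TetR])
                 for eq in report.stable]
        assert min(dists) < 0.1

    def test_bangbang_inputs_take_only_extreme_values(self, model,
                                                      saddle_state):
        cfg = ControllerConfig(mode="bangbang")
        rec = model.control("ode", cfg, t_end=400.0, state0=saddle_state)
        assert set(np.unique(rec.applied[:, 0])) <= {0.0, 50.0}
        assert set(np.unique(rec.applied[:, 1])) <= {0.0, 0.5}

    def test_inputs_always_within_bounds(self, model, saddle_state):
        for mode in ("pi", "bangbang"):
            cfg = ControllerConfig(mode=mode)
            rec = model.control("ssa", cfg, t_end=400.0, state0=saddle_state,
                                seed=2)
            assert np.all(rec.applied[:, 0] >= 0.0)
            assert np.all(rec.applied[:, 0] <= 50.0)
            assert np.all(rec.applied[:, 1] >= 0.0)
            assert np.all(rec.applied[:, 1] <= 0.5)

    def test_windup_window_only_affects_integral_before_td(self, model,
                                                           saddle_state):
        """t_d = 0 and t_d = 120 runs coincide until the errors first differ
        through the integral term."""
        y = saddle_state.as_array() * np.array([1, 1, 1.05, 1, 1, 1])
        s0 = CellState.from_array(y)
        rec_a = model.control("ode", ControllerConfig(mode="pi", t_d=0.0),
                              t_end=300.0, state0=s0)
        rec_b = model.control("ode", ControllerConfig(mode="pi", t_d=120.0),
                              t_end=300.0, state0=s0)
        # integrals accumulate differently...
        assert not np.allclose(rec_a.integrals, rec_b.integrals)
        # ...but the proportional path is identical at t = 0
        assert np.allclose(rec_a.applied[0], rec_b.applied[0])

    def test_ssa_plant_seeded_reproducibly(self, model, saddle_state):
        cfg = ControllerConfig(mode="pi")
        a = model.control("ssa", cfg, t_end=200.0, state0=saddle_state, seed=9)
        b = model.control("ssa", cfg, t_end=200.0, state0=saddle_state, seed=9)
        assert np.array_equal(a.measured, b.measured)
        assert np.array_equal(a.applied, b.applied)

    def test_unknown_plant_rejected(self, model, saddle_state):
        with pytest.raises(ValueError):
            model.control("pde", ControllerConfig(), t_end=10.0,
                          state0=saddle_state)


class TestReleaseSchedule:
    def test_forcing_then_basal(self):
        forcing = InducerSchedule.periodic_two_phase()
        full = release_schedule(forcing, t_release=450.0)
        assert full.u_at(10.0) == (0.0, 0.5)
        assert full.u_at(130.0) == (50.0, 0.0)
        assert full.u_at(160.0) == (0.0, 0.5)
        assert full.u_at(451.0) == (20.0, 0.25)
        assert full.period is None


@pytest.fixture(scope="module")
def forcing_result(model):
    return model.forcing(InducerSchedule.periodic_two_phase(),
                         t_end=1500.0, t_release=900.0, seed=7, n_cells=16)


class TestPeriodicForcing:

    def test_no_commitment_during_forcing(self, forcing_result):
        """Every cell's log-ratio stays in a bounded band while forced."""
        for lo, hi in forcing_result.logratio_bands:
            assert hi - lo < 2.0
            assert -1.8 < lo and hi < 1.8

    def test_all_cells_rfp_dominant_after_release(self, forcing_result):
        assert forcing_result.labels == ["rfp"] * 16

    def test_slower_protocol_splits_population(self, model):
        res = model.forcing(InducerSchedule.periodic_two_phase(t_IPTG=180.0),
                            t_end=1700.0, t_release=1050.0, seed=7,
                            n_cells=16)
        assert set(res.labels) == {"rfp", "gfp"}

    def test_very_slow_forcing_commits_during_stimulation(self, model):
        """A single multi-hour phase lets cells commit while still forced."""
        sched = InducerSchedule.periodic_two_phase(t_IPTG=900.0, t_aTc=30.0)
        res = model.forcing(sched, t_end=1860.0, t_release=1860.0, seed=11,
                            n_cells=8, t_burn=930.0)
        # during the long IPTG phase every cell dives deep into TetR
        # dominance (log-ratio below -2) and ends GFP-labelled
        assert all(lo < -2.0 for lo, _hi in res.logratio_bands)
        assert res.labels == ["gfp"] * 8

    def test_release_time_validation(self, model):
        with pytest.raises(ValueError):
            model.forcing(InducerSchedule.periodic_two_phase(), t_end=100.0,
                          t_release=200.0, seed=0)


class TestCommitmentLabel:
    def test_labels_at_the_attractors(self, model, reference_u):
        report = model.equilibria(reference_u)
        for eq in report.stable:
            lab, com = commitment_label(eq.LacI, eq.TetR, report)
            assert com
            assert lab == ("rfp" if eq.LacI > eq.TetR else "gfp")

    def test_saddle_not_committed(self, model, reference_u):
        report = model.equilibria(reference_u)
        sad = report.saddle()
        _, com = commitment_label(sad.LacI, sad.TetR, report)
        assert not com
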