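"""Integration, phase portraits, equilibria, separatrix, averaged fields."""

import numpy as np
import pytest
from scipy.optimize import brentq

from togglectl import (CellState, InducerSchedule, find_equilibria, integrate,
                       separatrix)
from togglectl.deterministic import BistabilityError, periodic_inducer_orbit
from togglectl.dynamics import reduced_rhs


def brute_force_equilibria(u, p, ex, n_scan=400):
    """Independent oracle: dense 1-D sign-change scan.

    On either nullcline the system reduces to the scalar fixed-point problem
    T = Tss(Lss(T)); scanning a dense log grid and bisecting each bracket
    finds every equilibrium at grid resolution.
    """
    from togglectl.deterministic import (_lacI_nullcline_level,
                                         _tetR_nullcline_level)

    def g(T):
        L = _lacI_nullcline_level(T, u, p)
        return _tetR_nullcline_level(L, u, p) - T

    Ts = np.logspace(-3, 4.5, n_scan)
    gs = np.array([g(T) for T in Ts])
    roots = []
    for i in range(n_scan - 1):
        if gs[i] * gs[i + 1] < 0:
            T = brentq(g, Ts[i], Ts[i + 1], xtol=1e-12)
            roots.append((float(_lacI_nullcline_level(T, u, p)), float(T)))
    return roots


class TestIntegrate:
    def test_stays_at_stable_equilibrium(self, model, reference_u):
        eq = model.equilibria(reference_u).stable[0]
        traj = model.simulate(eq.state, InducerSchedule.reference(), 500.0)
        assert np.allclose(traj.states[-1], eq.state.as_array(), rtol=1e-4)

    def test_sustained_IPTG_switches_to_TetR_dominance(self, model):
        # start in the low-TetR (RFP-dominant) state, drive with 1 mM IPTG
        rfp = max(model.equilibria((20.0, 0.25)).stable, key=lambda e: e.LacI)
        traj = model.simulate(rfp.state, InducerSchedule.constant(0.0, 1.0),
                              1500.0)
        final = traj.final_state()
        assert final.TetR > final.LacI

    def test_all_transcription_off_gives_linear_decay(self, params, exchange):
        p = params.replace(k_m0_L=1e-12, k_m0_T=1e-12, k_m_L=1e-12,
                           k_m_T=1e-12)
        s0 = CellState(mRNA_L=50.0, LacI=800.0, aTc_in=20.0, IPTG_in=0.25)
        traj = integrate(s0, InducerSchedule.reference(), p, exchange, 120.0,
                         rtol=1e-10, atol=1e-12)
        t = traj.times
        m_expected = 50.0 * np.exp(-p.g_m_L * t)
        # protein: decay plus translation of the decaying mRNA pool
        a, g1, g2 = p.k_p_L * 50.0, p.g_m_L, p.g_p_L
        L_expected = (800.0 * np.exp(-g2 * t)
                      + a / (g1 - g2) * (np.exp(-g2 * t) - np.exp(-g1 * t)))
        assert np.allclose(traj.states[:, 0], m_expected, rtol=1e-6, atol=1e-8)
        assert np.allclose(traj.LacI, L_expected, rtol=1e-6)

    def test_restarts_at_schedule_breakpoints(self, model):
        sched = InducerSchedule([0.0, 100.0], [0.0, 50.0], [1.0, 0.0])
        traj = model.simulate(CellState(), sched, 200.0)
        assert 100.0 in traj.times
        i = np.searchsorted(traj.times, 100.0)
        assert tuple(traj.inputs[i]) == (50.0, 0.0)

    def test_t_end_must_exceed_start(self, model):
        with pytest.raises(ValueError):
            model.simulate(CellState(), InducerSchedule.reference(), -5.0)


class TestNullclines:
    def test_vertices_are_zeros_of_their_component(self, model, reference_u):
        nc = model.nullclines(reference_u)
        for L, T in nc["LacI"][::20]:
            dL, _ = reduced_rhs(L, T, reference_u, model.params,
                                model.exchange)
            assert abs(dL) < 1e-8 * max(1.0, L)
        for L, T in nc["TetR"][::20]:
            _, dT = reduced_rhs(L, T, reference_u, model.params,
                                model.exchange)
            assert abs(dT) < 1e-8 * max(1.0, T)

    def test_intersections_match_equilibria(self, model, reference_u):
        """Nullcline crossings and multistart-Newton roots agree."""
        eqs = model.equilibria(reference_u)
        oracle = brute_force_equilibria(reference_u, model.params,
                                        model.exchange)
        assert len(oracle) == len(eqs.points)
        found = sorted((e.LacI, e.TetR) for e in eqs.points)
        for (L1, T1), (L2, T2) in zip(found, sorted(oracle)):
            assert L1 == pytest.approx(L2, rel=1e-6)
            assert T1 == pytest.approx(T2, rel=1e-6)

    def test_saturating_aTc_flattens_LacI_nullcline(self, model):
        nc = model.nullclines((1e6, 0.25))
        levels = nc["LacI"][:, 0]
        p = model.params
        expected = p.k_p_L * (p.k_m0_L + p.k_m_L) / (p.g_m_L * p.g_p_L)
        assert np.allclose(levels, expected, rtol=1e-6)


class TestFindEquilibria:
    def test_reference_conditions_bistable(self, model, reference_u):
        report = model.equilibria(reference_u)
        assert report.n_stable == 2 and report.n_unstable == 1

    def test_saturating_IPTG_monostable_TetR_dominant(self, model):
        report = model.equilibria((0.0, 1.0))
        assert report.n_stable == 1 and report.n_unstable == 0
        eq = report.stable[0]
        assert eq.TetR > eq.LacI

    def test_matches_brute_force_scan(self, model):
        for u in [(20.0, 0.25), (0.0, 1.0), (50.0, 0.0), (10.0, 0.1)]:
            oracle = brute_force_equilibria(u, model.params, model.exchange)
            found = model.equilibria(u)
            assert len(found.points) == len(oracle)

    def test_symmetric_circuit_has_symmetric_equilibria(
            self, symmetric_params, exchange):
        # equal effective induction on both branches
        report = find_equilibria((20.0, 20.0), symmetric_params, exchange)
        pts = sorted((e.LacI, e.TetR) for e in report.points)
        mirrored = sorted((T, L) for L, T in pts)
        for (L1, T1), (L2, T2) in zip(pts, mirrored):
            assert L1 == pytest.approx(L2, rel=1e-4)
            assert T1 == pytest.approx(T2, rel=1e-4)

    def test_minimum_starts_enforced(self, model, reference_u):
        with pytest.raises(ValueError):
            model.equilibria(reference_u, n_starts=10)

    def test_stability_consistent_with_flow(self, model, reference_u):
        """Perturbed stable points return; the saddle departs."""
        report = model.equilibria(reference_u)
        for eq in report.stable:
            y = eq.state.as_array() * np.array([1, 1, 1.02, 0.98, 1, 1])
            traj = integrate(CellState.from_array(y),
                             InducerSchedule.reference(), model.params,
                             model.exchange, 800.0)
            assert np.allclose(traj.states[-1, 2:4],
                               eq.state.as_array()[2:4], rtol=1e-3)
        sad = report.saddle()
        y = sad.state.as_array() * np.array([1, 1, 1.05, 0.95, 1, 1])
        traj = integrate(CellState.from_array(y), InducerSchedule.reference(),
                         model.params, model.exchange, 2000.0)
        dist = np.linalg.norm(traj.states[-1, 2:4]
                              - sad.state.as_array()[2:4])
        assert dist > 0.5 * np.linalg.norm(sad.state.as_array()[2:4])


class TestHysteresis:
    def test_aTc_sweep_up_then_down_retains_state(self, model):
        """Memory: the committed state at intermediate aTc depends on history."""
        u_mid = (20.0, 0.25)
        # committed low-LacI cell stays low at intermediate aTc...
        gfp = min(model.equilibria(u_mid).stable, key=lambda e: e.LacI)
        up = model.simulate(gfp.state, InducerSchedule.constant(*u_mid),
                            1000.0).final_state()
        # ...while a cell driven through saturating aTc stays high afterwards
        driven = model.simulate(gfp.state, InducerSchedule.constant(100.0, 0.0),
                                2500.0).final_state()
        driven = CellState.from_array(driven.as_array())  # reset the clock
        down = model.simulate(driven, InducerSchedule.constant(*u_mid),
                              1000.0).final_state()
        assert up.LacI < up.TetR
        assert down.LacI > down.TetR


class TestSeparatrix:
    def test_saddle_on_curve(self, model, reference_u):
        sep = model.separatrix(reference_u)
        sad = model.equilibria(reference_u).saddle()
        d = np.min(np.linalg.norm(sep - [sad.LacI, sad.TetR], axis=1))
        assert d < 1e-6 * max(sad.LacI, sad.TetR)

    def test_sides_flow_to_different_attractors(self, model, reference_u):
        """Basin-bisection oracle at sample points along the curve."""
        sep = model.separatrix(reference_u)
        report = model.equilibria(reference_u)
        stable = sorted(report.stable, key=lambda e: e.LacI)
        idx = np.linspace(5, len(sep) - 6, 10).astype(int)
        for i in idx:
            pt = sep[i]
            if not (1.0 < pt[0] < 1e4 and 1.0 < pt[1] < 1e4):
                continue
            outcomes = []
            for fac in (1.25, 0.8):
                s0 = CellState(LacI=pt[0] * fac, TetR=pt[1] / fac,
                               aTc_in=reference_u[0], IPTG_in=reference_u[1])
                mL, mT = pt[0] * 0, pt[1] * 0
                traj = model.simulate(s0, InducerSchedule.reference(), 4000.0)
                final = traj.final_state()
                d = [np.linalg.norm(np.log10([final.LacI + 1e-9, final.TetR + 1e-9])
                                    - np.log10([e.LacI, e.TetR]))
                     for e in stable]
                outcomes.append(int(np.argmin(d)))
            assert outcomes[0] != outcomes[1]

    def test_symmetric_circuit_separatrix_is_diagonal(
            self, symmetric_params, exchange):
        sep = separatrix((20.0, 20.0), symmetric_params, exchange)
        core = sep[(sep[:, 0] > 1) & (sep[:, 0] < 1e4)]
        assert np.allclose(core[:, 0], core[:, 1], rtol=1e-3)

    def test_monostable_input_raises(self, model):
        with pytest.raises(BistabilityError, match="1 stable"):
            model.separatrix((0.0, 1.0))


class TestTimeAveragedField:
    def test_constant_schedule_equals_reduced_field(self, model, reference_u):
        sched = InducerSchedule([0.0], [reference_u[0]], [reference_u[1]],
                                period=150.0)
        field = model.averaged_field(sched, n_grid=40)
        LL, TT = np.meshgrid(field.grid_L, field.grid_T)
        dL, dT = reduced_rhs(LL, TT, reference_u, model.params,
                             model.exchange)
        assert np.allclose(field.U, dL, rtol=1e-9)
        assert np.allclose(field.V, dT, rtol=1e-9)

    def test_120_30_protocol_single_null_point(self, model):
        field = model.averaged_field(InducerSchedule.periodic_two_phase(),
                                     n_grid=60)
        assert len(field.null_points) == 1

    def test_null_point_is_a_zero_of_the_field(self, model):
        field = model.averaged_field(InducerSchedule.periodic_two_phase(),
                                     n_grid=40)
        L, T = field.null_points[0]
        dL, dT = field.field_at(L, T)
        assert abs(dL) < 1e-6 and abs(dT) < 1e-6

    def test_null_point_shifts_with_duty_ratio(self, model):
        """More IPTG share moves the effective attractor toward TetR dominance."""
        ratios = [2.0, 3.0, 4.0, 5.0, 6.0]
        logratios = []
        for r in ratios:
            sched = InducerSchedule.periodic_two_phase(t_IPTG=30.0 * r,
                                                       t_aTc=30.0)
            field = model.averaged_field(sched, n_grid=40)
            assert len(field.null_points) == 1
            L, T = field.null_points[0]
            logratios.append(np.log10(L / T))
        assert np.all(np.diff(logratios) < 0)

    def test_non_periodic_schedule_rejected(self, model):
        with pytest.raises(ValueError):
            model.averaged_field(InducerSchedule.reference())

    def test_inducer_orbit_is_periodic(self, exchange):
        sched = InducerSchedule.periodic_two_phase()
        ts, aa, ii = periodic_inducer_orbit(sched, exchange, n_t=300)
        from togglectl.dynamics import inducer_step

        # propagating the first sample across one full period returns to it
        a, i = aa[0], ii[0]
        for t0, t1, ua, ui in sched.segments(sched.period):
            a, i = inducer_step(a, i, ua, ui, t1 - t0, exchange)
        assert a == pytest.approx(aa[0], rel=1e-5)
        assert i == pytest.approx(ii[0], rel=1e-5)
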