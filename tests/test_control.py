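"""STOP/KICK signals, open-loop induction, threshold feedback control."""

import numpy as np
import pytest

from repressilator import control, model, simulate, ssa
from repressilator.control import (
    ControllerConfig,
    Signal,
    StopKickSettings,
    apply_signals,
    closed_loop,
    stop_kick,
)
from repressilator.equilibria import dimerized_fixed_points


@pytest.fixture(scope="module")
def fig3_settings():
    # quasi-stable period of the fig3 ring, frozen from the transient
    # measurement (see test_orbits.test_transient_period_close_to_shooting)
    return StopKickSettings(reference_period=577.4, post_periods=8)


class TestSignals:
    def test_overlap_rejected(self):
        sigs = [
            Signal("KICK", 1, 0.0, 10.0, 1.0),
            Signal("KICK", 1, 5.0, 10.0, 1.0),
        ]
        with pytest.raises(ValueError):
            apply_signals(model.preset("table1", n=6), sigs)

    def test_different_genes_may_overlap(self):
        sigs = [
            Signal("KICK", 1, 0.0, 10.0, 1.0),
            Signal("KICK", 2, 5.0, 10.0, 1.0),
        ]
        sched = apply_signals(model.preset("table1", n=6), sigs)
        assert sched.drive(7.0).tolist() == [1.0, 1.0, 0, 0, 0, 0]

    def test_zero_amplitude_signal_is_identity(self, table1_n6):
        y0 = np.linspace(0.1, 1.2, 12)
        sched = apply_signals(table1_n6, [Signal("KICK", 3, 10.0, 20.0, 0.0)])
        a = simulate.integrate(table1_n6, y0, (0.0, 100.0), tol=1e-10, sample_dt=5.0)
        b = simulate.integrate(
            table1_n6, y0, (0.0, 100.0), tol=1e-10, sample_dt=5.0,
            drive=sched.drive, drive_boundaries=sched.boundaries,
        )
        assert np.allclose(a.y, b.y, atol=1e-9)

    def test_production_bookkeeping_event_exact(self):
        """Extra mRNA produced by a pulse equals amplitude x duration (c2=o(1) removed)."""
        # with degradation switched off analytically: dm = (c1 H + A 1_pulse) dt;
        # compare driven minus free m_3 at a time after the pulse, corrected
        # for decay using the linearity of the added term
        p = model.RingParameters(n=6, c1=0.0, c2=1e-9, c3=0.0, c4=0.06)
        amp, dur = 0.37, 21.0
        sched = apply_signals(p, [Signal("KICK", 3, 10.0, dur, amp)])
        y0 = np.zeros(12)
        traj = simulate.integrate(
            p, y0, (0.0, 40.0), tol=1e-12, drive=sched.drive,
            drive_boundaries=sched.boundaries,
        )
        assert traj.final_state()[2] == pytest.approx(amp * dur, rel=1e-7)
        assert np.allclose(np.delete(traj.final_state()[:6], 2), 0.0)

    def test_permanent_stop_reaches_dimerized_fixed_point(self):
        p = model.preset("table1", n=8).with_c(6.0)
        sched = apply_signals(p, [Signal("STOP", 3, 0.0, 4000.0, float(p.c1))])
        y0 = np.full(16, 0.5)
        traj = simulate.integrate(
            p, y0, (0.0, 4000.0), tol=1e-8, drive=sched.drive,
            drive_boundaries=sched.boundaries,
        )
        # under sustained induction of gene 3, protein 3 is pinned high and
        # the rest of the ring settles into the alternating pattern with
        # gene 3 up: release the signal and verify relaxation onto the
        # odd-up/even-up state with gene 3 up (gene 3 odd -> "odd_up")
        relax = simulate.integrate(p, traj.final_state(), (0.0, 3000.0), tol=1e-10)
        fp = next(f for f in dimerized_fixed_points(p) if f.assignment == "odd_up")
        assert np.max(np.abs(relax.final_state() - fp.state(8))) < 1e-6


class TestStopKick:
    def test_induces_and_terminates_fig3(self, fig3_params, fig3_settings):
        traj, summary = stop_kick(
            fig3_params, stop_gene=1, settings=fig3_settings, final_stop=True
        )
        assert summary.sustained
        assert summary.min_peak_count >= 5
        fps = dimerized_fixed_points(fig3_params)
        dist = min(np.linalg.norm(traj.final_state() - fp.state(18)) for fp in fps)
        assert dist < 1e-4

    def test_reliable_over_random_prior_states(self, fig3_params, fig3_settings):
        """Induction succeeds regardless of the pre-STOP state (20 seeds)."""
        induced = [
            stop_kick(fig3_params, 1, fig3_settings, seed=seed)[1].sustained
            for seed in range(20)
        ]
        assert all(induced)

    def test_odd_ring_rejected(self):
        with pytest.raises(ValueError):
            stop_kick(
                model.preset("table1", n=7),
                1,
                StopKickSettings(reference_period=100.0),
            )

    def test_induced_wave_ring_order(self, fig3_params, fig3_settings):
        """After a KICK on gene 2, upregulation sweeps the ring in order
        2, 4, 6, ... (the two kink trains serve alternating genes)."""
        traj, summary = stop_kick(fig3_params, 1, fig3_settings)
        sigs = fig3_settings.build_signals(fig3_params, 1)
        t_kick = sigs[1].t_start
        window = traj.after(t_kick)
        firsts = {}
        for g in (2, 4, 6, 8):
            pk = simulate.detect_peaks(window.t, window.protein(g))
            firsts[g] = pk[0]
        assert firsts[2] < firsts[4] < firsts[6] < firsts[8]


class TestClosedLoop:
    def test_controller_off_reproduces_free_ssa(self):
        p = model.preset("table1", n=6, c=5.0)
        cfg = ControllerConfig.for_period(130.0, mode="off")
        fp = dimerized_fixed_points(p)[0]
        trace, events = closed_loop(p, cfg, 400.0, simulator="ssa", omega=30, seed=9)
        assert events == []
        free = ssa.gillespie(
            p, 30, ssa.counts_from_state(fp.state(6), 30), 400.0, seed=9,
            record_dt=cfg.check_dt,
        )
        # same seed, same chunking-free dynamics: identical jump statistics at
        # the recorded grid resolution
        assert np.array_equal(trace.counts[0], free.counts[0])
        assert abs(trace.counts[-1].sum() - free.counts[-1].sum()) < 0.5 * free.counts[-1].sum()

    def test_switch_on_sustain_switch_off_n10(self):
        p = model.preset("table1", n=10, c=5.0)
        T = 243.0
        cfg = ControllerConfig.for_period(T)
        stop = [control.Signal("STOP", 1, 4000.0, 1.5 * T, float(p.c1))]
        trace, events = closed_loop(
            p, cfg, 5200.0, simulator="ssa", omega=50, seed=3, extra_signals=stop
        )
        assert len(events) > 5  # controller actively kicks
        x = trace.protein_counts(5).astype(float)
        mask = (trace.t > 500) & (trace.t < 4000)
        sm = np.convolve(x[mask], np.ones(10) / 10, mode="same")
        pk = simulate.detect_peaks(trace.t[mask], sm, prominence_frac=0.3)
        assert pk.size >= 8  # sustained while on
        iv = ssa.detect_switching(trace)
        dwell_after = sum(
            max(0.0, min(b, 5200.0) - max(a, 4600.0)) for _, a, b in iv
        )
        assert dwell_after > 0.4 * (5200.0 - 4600.0)  # parked in a basin after STOP

    def test_applicable_down_to_n6(self):
        p = model.preset("table1", n=6, c=5.0)
        cfg = ControllerConfig.for_period(133.0)
        trace, events = closed_loop(p, cfg, 2500.0, simulator="ssa", omega=50, seed=2)
        assert len(events) >= 5
        x = trace.protein_counts(3).astype(float)
        sm = np.convolve(x, np.ones(10) / 10, mode="same")
        pk = simulate.detect_peaks(trace.t[200:], sm[200:], prominence_frac=0.3)
        assert pk.size >= 5

    def test_on_phase_kicks_preserve_period(self, table1_n6):
        """Controller entrainment changes the deterministic period < 5%."""
        from repressilator import orbits
        from repressilator.equilibria import find_hopf_points

        p = model.preset("table1", n=10, c=5.0)
        hb = find_hopf_points(p)[0]
        pc = p.with_c(hb.c_star * 1.05)
        y0, T0 = orbits.initial_guess_from_hopf(hb, pc)
        orb = orbits.continue_branch(orbits.shoot(y0, T0, pc), 5.0, step=0.25)[-1]
        cfg = ControllerConfig.for_period(orb.period)
        trace, events = closed_loop(
            p, cfg, 12 * orb.period, simulator="ode", init=orb.anchor
        )
        pk = simulate.detect_peaks(trace.t, trace.y[:, 10 + 2], prominence_frac=0.2)
        T_meas = np.mean(np.diff(pk))
        assert abs(T_meas / orb.period - 1.0) < 0.05
        assert len(events) > 0
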