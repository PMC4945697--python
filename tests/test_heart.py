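import numpy as np
import pytest

from dissectflow.heart import (ConvergenceError, ElastanceParams, HeartRun,
                               HeartState, TuningError, elastance, heart_step,
                               load_heart_params, lv_pressure, pv_loop,
                               simulate_heart, stroke_work,
                               stroke_work_joules, tune_elastance,
                               viscous_loss)
from dissectflow.synthetic import single_rcr_afterload
from dissectflow.units import canonical_to_mmhg, mmhg_to_canonical


@pytest.fixture(scope="module")
def ep(heart_params):
    return heart_params.elastance


class TestElastance:
    def test_knot_values(self, ep):
        assert elastance(0.0, ep) == pytest.approx(ep.E_min, rel=1e-12)
        assert elastance(ep.t_max, ep) == pytest.approx(ep.E_max, rel=1e-12)
        assert elastance(ep.t_max + ep.t_relax, ep) == pytest.approx(
            ep.E_min, abs=1e-12)

    def test_half_rise_value(self, ep):
        # cosine rise passes through the midpoint at t_max / 2
        expected = 0.5 * (0.460 + 4.102e-3)
        assert elastance(0.205, ep) == pytest.approx(expected, rel=1e-6)

    def test_bounds_and_periodicity(self, ep):
        t = np.linspace(0.0, 3 * ep.T, 4001)
        e = elastance(t, ep)
        assert np.all(e >= ep.E_min - 1e-15)
        assert np.all(e <= ep.E_max + 1e-15)
        np.testing.assert_allclose(elastance(t, ep), elastance(t + ep.T, ep),
                                   atol=1e-12)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            ElastanceParams(T=1.0, t_max=0.8, t_relax=0.3, E_max=0.4,
                            E_min=0.004)


class TestPressureRelations:
    def test_unstressed_volume_gives_zero(self, heart_params):
        ep, vp = heart_params.elastance, heart_params.ventricle
        assert lv_pressure(vp.V_u + 1e-9, 0.0, ep, vp) == pytest.approx(
            0.0, abs=1e-9)

    def test_diastolic_equilibrium_matches_preload(self, heart_params):
        # E_min * V_ed reproduces the printed preload (4 mmHg)
        ep, vp = heart_params.elastance, heart_params.ventricle
        p = lv_pressure(130_000.0, 0.0, ep, vp)
        assert p == pytest.approx(533.3, abs=0.1)
        assert p == pytest.approx(vp.P_LA, rel=1.5e-4)

    def test_end_systolic_pressure_example(self, heart_params):
        ep, vp = heart_params.elastance, heart_params.ventricle
        p = lv_pressure(36_000.0, ep.t_max, ep, vp)
        assert p == pytest.approx(16_560.0, rel=1e-6)
        assert canonical_to_mmhg(p) == pytest.approx(124.2, abs=0.05)

    def test_below_unstressed_volume_rejected(self, heart_params):
        ep, vp = heart_params.elastance, heart_params.ventricle
        with pytest.raises(ValueError):
            lv_pressure(vp.V_u, 0.0, ep, vp)

    def test_viscous_loss(self):
        assert viscous_loss(16_000.0, 0.0, 5e-7) == 0.0
        assert viscous_loss(16_000.0, 300_000.0, 5e-7) == pytest.approx(2400.0)
        assert viscous_loss(16_000.0, 600_000.0, 5e-7) == pytest.approx(4800.0)


class TestHeartStep:
    def test_filling_raises_volume(self, heart_params):
        vp = heart_params.ventricle
        state = HeartState(V=0.6 * vp.V_ed, P_LV=0.0)
        downstream = mmhg_to_canonical(80.0)
        for k in range(50):
            state = heart_step(state, 0.8 + k * 1e-3, 1e-3, heart_params,
                               downstream)
        assert state.V > 0.6 * vp.V_ed
        assert state.Q_mv >= 0.0
        assert state.Q_av == 0.0

    def test_adverse_gradient_precludes_backflow(self, heart_params):
        # late diastole, low chamber pressure, high aortic pressure
        state = HeartState(V=heart_params.ventricle.V_ed, P_LV=533.0)
        new = heart_step(state, 0.8, 1e-3, heart_params,
                         mmhg_to_canonical(100.0))
        assert new.Q_av == 0.0


class TestReferenceRun:
    def test_physiological_envelope(self, reference_heart_run):
        run = reference_heart_run
        assert 60_000.0 <= run.stroke_volume <= 130_000.0
        assert 90.0 <= canonical_to_mmhg(run.P_LV.max()) <= 200.0

    def test_no_backflow_anywhere(self, reference_heart_run):
        assert np.all(reference_heart_run.Q_av >= 0.0)
        assert np.all(reference_heart_run.Q_mv >= 0.0)

    def test_volume_periodicity(self, reference_heart_run):
        run = reference_heart_run
        assert abs(run.V[0] - run.V[-1]) < 0.005 * run.stroke_volume

    def test_energy_bookkeeping(self, reference_heart_run, heart_params):
        """Loop area balances boundary work plus internal dissipation."""
        run = reference_heart_run
        vv, vp = heart_params.valves, heart_params.ventricle
        w_loop = stroke_work(pv_loop(run))
        t = run.times
        w_out = np.trapezoid(run.P_ao * run.Q_av, t)
        w_in = np.trapezoid(vp.P_LA * run.Q_mv, t)
        d_valves = np.trapezoid(vv.R_av * run.Q_av ** 2
                                + vv.R_mv * run.Q_mv ** 2, t)
        d_visc = np.trapezoid(vp.k_LV * run.P_LV
                              * (run.Q_av ** 2 + run.Q_mv ** 2), t)
        assert w_loop == pytest.approx(w_out - w_in + d_valves + d_visc,
                                       rel=0.02)


class TestPvLoopAndStrokeWork:
    def test_isochoric_cycle_zero_area(self):
        n = 100
        t = np.linspace(0.0, 1.0, n)
        run = HeartRun(times=t, V=np.full(n, 1e5),
                       P_LV=1000 + 500 * np.sin(2 * np.pi * t),
                       Q_av=np.zeros(n), Q_mv=np.zeros(n),
                       P_ao=np.zeros(n), period=1.0, n_cycles=1,
                       converged=True)
        assert stroke_work(pv_loop(run)) == pytest.approx(0.0, abs=1e-6)

    def test_loop_width_equals_ejected_volume(self, reference_heart_run):
        run = reference_heart_run
        ejected = np.trapezoid(run.Q_av, run.times)
        assert run.stroke_volume == pytest.approx(ejected, rel=0.01)

    def test_two_isovolumetric_segments(self, reference_heart_run):
        """The loop has exactly two near-vertical phases (|dV| small while
        |dP| large): isovolumetric contraction and relaxation."""
        run = reference_heart_run
        sv = run.stroke_volume
        dv, dp = np.diff(run.V), np.diff(run.P_LV)
        iso = (np.abs(dv) < 1e-4 * sv) & (np.abs(dp) > 1e-4 * run.P_LV.max())
        # count contiguous isovolumetric phases
        edges = np.flatnonzero(np.diff(iso.astype(int)) == 1).size + int(iso[0])
        assert edges == 2
        phase_dv = [abs(run.V[b] - run.V[a]) for a, b in
                    zip(*_phase_bounds(iso))]
        assert all(d < 0.02 * sv for d in phase_dv)

    def test_nonperiodic_cycle_rejected(self, reference_heart_run):
        run = reference_heart_run
        broken = HeartRun(times=run.times, V=run.V + np.linspace(0, 5000, run.V.size),
                          P_LV=run.P_LV, Q_av=run.Q_av, Q_mv=run.Q_mv,
                          P_ao=run.P_ao, period=run.period, n_cycles=1,
                          converged=True)
        with pytest.raises(ConvergenceError):
            pv_loop(broken)

    def test_rectangle_area(self):
        v = np.array([0.0, 94_000.0, 94_000.0, 0.0])
        p = np.array([0.0, 0.0, mmhg_to_canonical(100.0),
                      mmhg_to_canonical(100.0)])
        loop = np.column_stack([v, p])
        assert stroke_work_joules(loop) == pytest.approx(1.2532, rel=1e-3)

    def test_headline_relative_change(self):
        w = 1.55
        assert 100.0 * (1.137 * w - w) / w == pytest.approx(13.7, abs=1e-9)

    def test_clockwise_loop_warns_and_returns_abs(self):
        square = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            assert stroke_work(square) == pytest.approx(1.0)


def _phase_bounds(mask):
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return [], []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[splits + 1]]
    ends = np.r_[idx[splits], idx[-1]] + 1
    return starts, ends


class TestTuning:
    def test_fixed_point_returns_after_one_evaluation(self, heart_params,
                                                      reference_heart_run):
        run = reference_heart_run
        result = tune_elastance(run.mean_co, run.peak_co,
                                single_rcr_afterload(), heart_params)
        assert result.n_evaluations == 1
        assert result.params.elastance == heart_params.elastance

    def test_mean_output_monotone_in_emax(self, heart_params):
        from dataclasses import replace
        means = []
        for e_max in (0.35, 0.46, 0.60):
            ep = replace(heart_params.elastance, E_max=e_max)
            run = simulate_heart(heart_params.with_elastance(ep),
                                 single_rcr_afterload())
            means.append(run.mean_co)
        assert means[0] < means[1] < means[2]

    def test_tuning_reaches_five_percent(self, tuned_baseline):
        assert tuned_baseline.converged
        assert abs(tuned_baseline.mean_error_pct) <= 5.0
        assert abs(tuned_baseline.peak_error_pct) <= 5.0

    def test_unreachable_target_raises_with_log(self, heart_params):
        with pytest.raises(TuningError) as exc:
            tune_elastance(5e5, 6e5, single_rcr_afterload(), heart_params,
                           max_iter=4)
        assert len(exc.value.log) >= 3
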