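"""Lumped-parameter left heart: time-varying elastance, valve diodes, tuning.

The left ventricle is a time-varying elastance chamber,

    P_LV(t) = E_LV(t) * (V_LV(t) - V_u),

filled from a constant-pressure left atrium (preload ``P_LA``) through a
mitral resistance/inductance pair and ejecting through an aortic
resistance/inductance pair into an afterload (a Windkessel or a network).
Both valves are ideal diodes: flow is clamped to zero the instant an adverse
gradient would drive it backwards, so ``Q_av >= 0`` and ``Q_mv >= 0`` always.
A ventricular viscous loss ``dP = k_LV * P_LV * Q`` (resistance
``k_LV * P_LV``) acts on whichever valve flow is active.

The elastance waveform is a C0 piecewise cosine: half-cosine rise from
``E_min`` to ``E_max`` over ``t_max`` seconds, half-cosine fall back over
``t_relax`` seconds, then flat at ``E_min`` for the rest of the cycle.

The module also provides the pressure-volume loop, stroke work (shoelace
area) and the cardiac-output tuning loop that adjusts ``(E_max, t_max)`` by
damped secant steps until mean and peak aortic flow match their targets
within 5 %.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .units import canonical_to_joules
from .windkessel import WindkesselParams

__all__ = [
    "ElastanceParams",
    "ValveParams",
    "VentricleParams",
    "HeartParams",
    "HeartState",
    "elastance",
    "lv_pressure",
    "viscous_loss",
    "heart_step",
    "RCRAfterload",
    "simulate_heart",
    "HeartRun",
    "pv_loop",
    "stroke_work",
    "stroke_work_joules",
    "tune_elastance",
    "TuningResult",
    "TuningError",
    "ConvergenceError",
    "load_heart_params",
]


class ConvergenceError(RuntimeError):
    """Raised when a simulation fails to reach a periodic state."""


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElastanceParams:
    """Elastance timing and bounds: period T, rise t_max, fall t_relax (s);
    E_max, E_min in g mm^-4 s^-2."""

    T: float
    t_max: float
    t_relax: float
    E_max: float
    E_min: float

    def __post_init__(self) -> None:
        if self.t_max <= 0 or self.t_relax <= 0:
            raise ValueError("t_max and t_relax must be positive")
        if self.t_max + self.t_relax > self.T:
            raise ValueError(
                f"t_max + t_relax = {self.t_max + self.t_relax} exceeds period {self.T}"
            )
        if not (0 < self.E_min < self.E_max):
            raise ValueError("need 0 < E_min < E_max")


@dataclass(frozen=True)
class ValveParams:
    """Valve resistances g/(mm^4 s) and inductances g/mm^4."""

    R_av: float
    L_av: float
    R_mv: float
    L_mv: float

    def __post_init__(self) -> None:
        if min(self.R_av, self.L_av, self.R_mv, self.L_mv) < 0:
            raise ValueError("valve parameters must be non-negative")


@dataclass(frozen=True)
class VentricleParams:
    """Chamber constants: unstressed and end-diastolic volume (mm^3),
    viscous-loss constant k_LV (s/mm^3), atrial preload P_LA (canonical)."""

    V_u: float
    k_LV: float
    V_ed: float
    P_LA: float

    def __post_init__(self) -> None:
        if not (self.V_ed > self.V_u >= 0):
            raise ValueError("need V_ed > V_u >= 0")
        if self.k_LV < 0:
            raise ValueError("k_LV must be non-negative")
        if self.P_LA <= 0:
            raise ValueError("P_LA must be positive")


@dataclass(frozen=True)
class HeartParams:
    elastance: ElastanceParams
    valves: ValveParams
    ventricle: VentricleParams

    def with_elastance(self, ep: ElastanceParams) -> "HeartParams":
        return replace(self, elastance=ep)


@dataclass
class HeartState:
    """Instantaneous ventricular state."""

    V: float
    P_LV: float
    Q_av: float = 0.0
    Q_mv: float = 0.0
    av_open: bool = False
    mv_open: bool = False


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------

def elastance(t, p: ElastanceParams):
    """Piecewise-cosine elastance, periodic in ``p.T``; accepts arrays.

    Rise on [0, t_max], fall on (t_max, t_max + t_relax], flat at E_min after.
    ``E(0) = E_min`` and ``E(t_max) = E_max`` exactly.
    """
    tt = np.mod(np.asarray(t, dtype=float), p.T)
    half = 0.5 * (p.E_max - p.E_min)
    rise = p.E_min + half * (1.0 - np.cos(np.pi * tt / p.t_max))
    fall = p.E_min + half * (1.0 + np.cos(np.pi * (tt - p.t_max) / p.t_relax))
    out = np.where(
        tt <= p.t_max, rise, np.where(tt <= p.t_max + p.t_relax, fall, p.E_min)
    )
    return out if out.ndim else float(out)


def lv_pressure(V: float, t: float, ep: ElastanceParams,
                vp: VentricleParams) -> float:
    """Chamber pressure ``E(t) (V - V_u)``; requires ``V > V_u``."""
    if V <= vp.V_u:
        raise ValueError(f"V = {V} must exceed unstressed volume {vp.V_u}")
    return elastance(t, ep) * (V - vp.V_u)


def viscous_loss(P_LV: float, Q_LV: float, k_LV: float) -> float:
    """Ventricular viscous pressure drop ``k_LV P_LV Q_LV``."""
    return k_LV * P_LV * Q_LV


# ---------------------------------------------------------------------------
# one implicit step
# ---------------------------------------------------------------------------

def _down_coeffs(downstream) -> tuple[float, float]:
    """Downstream pressure contract: a float, or ``(a, b)`` with P = a + b*Q."""
    if isinstance(downstream, (int, float)):
        return float(downstream), 0.0
    a, b = downstream
    return float(a), float(b)


def _solve_valve_flows(state: HeartState, t_new: float, dt: float,
                       p: HeartParams, pa: float, pb: float,
                       av_open: bool, mv_open: bool):
    """Backward-Euler solve for (V', Q_av, Q_mv) with frozen valve states."""
    ep, vv, vp = p.elastance, p.valves, p.ventricle
    E = float(elastance(t_new, ep))
    k = vp.k_LV
    V0, qa0, qm0 = state.V, state.Q_av, state.Q_mv

    if not av_open and not mv_open:
        return V0, 0.0, 0.0

    if mv_open and not av_open:
        # V' = V0 + dt q;  L/dt (q - qm0) + E(V'-Vu)(1 + k q) + R q - P_LA = 0
        q = max(qm0, 0.0)
        for _ in range(50):
            Vn = V0 + dt * q
            ew = E * (Vn - vp.V_u)
            f = (vv.L_mv / dt) * (q - qm0) + ew * (1 + k * q) + vv.R_mv * q - vp.P_LA
            df = vv.L_mv / dt + E * dt * (1 + k * q) + ew * k + vv.R_mv
            step = f / df
            q -= step
            if abs(step) < 1e-10 * max(1.0, abs(q)):
                break
        return V0 + dt * q, 0.0, q

    if av_open and not mv_open:
        # V' = V0 - dt q;  L/dt (q - qa0) - E(V'-Vu)(1 - k q) + pa + pb q + R q = 0
        q = max(qa0, 0.0)
        for _ in range(50):
            Vn = V0 - dt * q
            ew = E * (Vn - vp.V_u)
            f = ((vv.L_av / dt) * (q - qa0) - ew * (1 - k * q)
                 + pa + pb * q + vv.R_av * q)
            df = (vv.L_av / dt + E * dt * (1 - k * q) + ew * k
                  + pb + vv.R_av)
            step = f / df
            q -= step
            if abs(step) < 1e-10 * max(1.0, abs(q)):
                break
        return V0 - dt * q, q, 0.0

    # both open (transient): 2x2 Newton on (qa, qm)
    qa, qm = max(qa0, 0.0), max(qm0, 0.0)
    for _ in range(50):
        Vn = V0 + dt * (qm - qa)
        ew = E * (Vn - vp.V_u)
        fa = ((vv.L_av / dt) * (qa - qa0) - ew * (1 - k * qa)
              + pa + pb * qa + vv.R_av * qa)
        fm = (vv.L_mv / dt) * (qm - qm0) + ew * (1 + k * qm) + vv.R_mv * qm - vp.P_LA
        daa = vv.L_av / dt + E * dt * (1 - k * qa) + ew * k + pb + vv.R_av
        dam = -E * dt * (1 - k * qa)
        dma = -E * dt * (1 + k * qm)
        dmm = vv.L_mv / dt + E * dt * (1 + k * qm) + ew * k + vv.R_mv
        det = daa * dmm - dam * dma
        dqa = (fa * dmm - dam * fm) / det
        dqm = (daa * fm - fa * dma) / det
        qa -= dqa
        qm -= dqm
        if max(abs(dqa), abs(dqm)) < 1e-10 * max(1.0, abs(qa), abs(qm)):
            break
    return V0 + dt * (qm - qa), qa, qm


def heart_step(state: HeartState, t: float, dt: float, params: HeartParams,
               downstream_pressure) -> HeartState:
    """Advance the heart by one implicit step against a downstream pressure.

    ``downstream_pressure`` is either a number (pressure at the aortic side,
    held fixed over the step) or a pair ``(a, b)`` describing the implicit
    linear response ``P_down = a + b * Q_av`` of the afterload over the step.
    Valve states are frozen during the nonlinear solve and re-evaluated
    afterwards; a flow crossing zero is clamped to zero within the step.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    ep, vp = params.elastance, params.ventricle
    pa, pb = _down_coeffs(downstream_pressure)
    t_new = t + dt
    E = float(elastance(t_new, ep))

    av, mv = state.av_open, state.mv_open
    # opening checks from the current state
    p_lv_now = E * (state.V - vp.V_u)
    if not av and p_lv_now > pa:
        av = True
    if not mv and vp.P_LA > p_lv_now:
        mv = True

    for _ in range(3):
        V, qa, qm = _solve_valve_flows(state, t_new, dt, params, pa, pb, av, mv)
        changed = False
        if av and qa < 0.0:
            av, changed = False, True
        if mv and qm < 0.0:
            mv, changed = False, True
        if not changed:
            p_lv = E * (V - vp.V_u)
            if not av and not state.av_open and p_lv > pa + pb * 0.0 + 1e-12:
                pass  # opening already attempted above; avoid chatter
            break
    qa, qm = max(qa, 0.0), max(qm, 0.0)
    V = state.V + dt * (qm - qa)
    return HeartState(V=V, P_LV=E * (V - vp.V_u), Q_av=qa, Q_mv=qm,
                      av_open=av and qa >= 0.0, mv_open=mv and qm >= 0.0)


# ---------------------------------------------------------------------------
# afterload coupling
# ---------------------------------------------------------------------------

class RCRAfterload:
    """Three-element Windkessel exposing the downstream-pressure contract.

    Over one backward-Euler step the Windkessel responds linearly to the
    inflow: ``P_down = a + b Q`` with coefficients derived from the implicit
    capacitor update, so the heart/afterload coupling is solved monolithically
    within each step.
    """

    def __init__(self, params: WindkesselParams, q_mean_guess: float = 0.0):
        self.params = params
        self.Pc = params.Pd + q_mean_guess * params.Rd

    def pressure_coeffs(self, dt: float) -> tuple[float, float]:
        p = self.params
        alpha = dt / (p.Rd * p.C)
        denom = 1.0 + alpha
        # Pc' = (Pc + (dt/C) Q + alpha Pd) / (1 + alpha);  P = Rp Q + Pc'
        a = (self.Pc + alpha * p.Pd) / denom
        b = p.Rp + (dt / p.C) / denom
        return a, b

    def commit(self, Q: float, dt: float) -> None:
        p = self.params
        alpha = dt / (p.Rd * p.C)
        self.Pc = (self.Pc + (dt / p.C) * Q + alpha * p.Pd) / (1.0 + alpha)


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

@dataclass
class HeartRun:
    """One converged cardiac cycle of the coupled heart-afterload system."""

    times: np.ndarray          # 0 .. T inclusive
    V: np.ndarray
    P_LV: np.ndarray
    Q_av: np.ndarray
    Q_mv: np.ndarray
    P_ao: np.ndarray           # afterload interface pressure
    period: float
    n_cycles: int
    converged: bool
    trace: list = field(default_factory=list)

    @property
    def mean_co(self) -> float:
        """Cycle-mean aortic flow (cardiac output), mm^3/s."""
        return float(np.trapezoid(self.Q_av, self.times)) / self.period

    @property
    def peak_co(self) -> float:
        """Peak aortic flow, mm^3/s."""
        return float(self.Q_av.max())

    @property
    def stroke_volume(self) -> float:
        return float(self.V.max() - self.V.min())


def simulate_heart(params: HeartParams, afterload, dt: float = 1e-3,
                   max_cycles: int = 20, tol: float = 1e-3,
                   q_mean_guess: float | None = None) -> HeartRun:
    """Run the heart against an afterload until cyclic convergence.

    ``afterload`` is Windkessel parameters (wrapped internally) or any object
    with the ``pressure_coeffs(dt)/commit(Q, dt)`` contract.  The afterload
    state is initialised at its steady mean-flow value (ejection-fraction
    based guess unless ``q_mean_guess`` is given), which places the start of
    the run close to the periodic orbit.
    """
    ep, vp = params.elastance, params.ventricle
    if q_mean_guess is None:
        q_mean_guess = 0.6 * (vp.V_ed - vp.V_u) / ep.T  # ~60 % ejection fraction
    if isinstance(afterload, WindkesselParams):
        afterload = RCRAfterload(afterload, q_mean_guess=q_mean_guess)

    n_steps = max(2, round(ep.T / dt))
    dt = ep.T / n_steps
    state = HeartState(V=vp.V_ed, P_LV=float(elastance(0.0, ep)) * (vp.V_ed - vp.V_u))

    prev_metrics = None
    trace: list[dict] = []
    for cycle in range(1, max_cycles + 1):
        ts = np.empty(n_steps + 1)
        V = np.empty(n_steps + 1)
        plv = np.empty(n_steps + 1)
        qav = np.empty(n_steps + 1)
        qmv = np.empty(n_steps + 1)
        pao = np.empty(n_steps + 1)
        ts[0], V[0], plv[0] = 0.0, state.V, state.P_LV
        qav[0], qmv[0] = state.Q_av, state.Q_mv
        a0, b0 = afterload.pressure_coeffs(dt)
        pao[0] = a0 + b0 * state.Q_av
        for k in range(n_steps):
            t = k * dt
            coeffs = afterload.pressure_coeffs(dt)
            state = heart_step(state, t, dt, params, coeffs)
            afterload.commit(state.Q_av, dt)
            ts[k + 1] = t + dt
            V[k + 1] = state.V
            plv[k + 1] = state.P_LV
            qav[k + 1] = state.Q_av
            qmv[k + 1] = state.Q_mv
            pao[k + 1] = coeffs[0] + coeffs[1] * state.Q_av
        mean_q = float(np.trapezoid(qav, ts)) / ep.T
        mean_p = float(np.trapezoid(pao, ts)) / ep.T
        metrics = np.array([mean_q, mean_p])
        if prev_metrics is not None:
            denom = np.maximum(np.abs(prev_metrics), 1e-9)
            change = float(np.max(np.abs(metrics - prev_metrics) / denom))
            trace.append({"cycle": cycle, "max_rel_change": change})
            if change < tol:
                return HeartRun(ts, V, plv, qav, qmv, pao, ep.T, cycle, True, trace)
        prev_metrics = metrics
    raise ConvergenceError(
        f"no cyclic convergence in {max_cycles} cycles (tol={tol}); "
        f"trace={[t['max_rel_change'] for t in trace]}"
    )


# ---------------------------------------------------------------------------
# PV loop and stroke work
# ---------------------------------------------------------------------------

def pv_loop(run: HeartRun, periodicity_tol: float = 0.01) -> np.ndarray:
    """Ordered (V, P) polygon of one converged cycle.

    Raises :class:`ConvergenceError` when the cycle is not closed, i.e. the
    start/end volume mismatch exceeds ``periodicity_tol`` of stroke volume.
    """
    sv = run.stroke_volume
    if sv > 0 and abs(run.V[0] - run.V[-1]) > periodicity_tol * sv:
        raise ConvergenceError(
            f"non-periodic cycle: |V(0) - V(T)| = {abs(run.V[0] - run.V[-1]):.1f} "
            f"mm^3 exceeds {periodicity_tol:.0%} of stroke volume {sv:.1f}"
        )
    return np.column_stack([run.V[:-1], run.P_LV[:-1]])


def stroke_work(loop: np.ndarray) -> float:
    """Enclosed PV-loop area by the shoelace formula (canonical energy units).

    Physiological loops (counter-clockwise in the (V, P) plane with the
    conventions used here) give positive work; a negative signed area is
    returned as its absolute value with a warning.
    """
    loop = np.asarray(loop, dtype=float)
    x, y = loop[:, 0], loop[:, 1]
    signed = 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )
    if signed < 0:
        warnings.warn("PV loop traversed clockwise or self-intersecting; "
                      "returning absolute area", stacklevel=2)
        return -signed
    return signed


def stroke_work_joules(loop: np.ndarray) -> float:
    return canonical_to_joules(stroke_work(loop))


# ---------------------------------------------------------------------------
# cardiac-output tuning loop
# ---------------------------------------------------------------------------

class TuningError(RuntimeError):
    """Raised when the elastance tuning loop fails to converge; carries the
    iteration log."""

    def __init__(self, message: str, log: list):
        super().__init__(message)
        self.log = log


@dataclass
class TuningResult:
    params: HeartParams
    mean_error: float          # fractional, signed
    peak_error: float
    n_evaluations: int
    converged: bool
    log: list
    run: HeartRun

    @property
    def mean_error_pct(self) -> float:
        return 100.0 * self.mean_error

    @property
    def peak_error_pct(self) -> float:
        return 100.0 * self.peak_error


def tune_elastance(target_mean_q: float, target_peak_q: float, afterload,
                   init: HeartParams, *, tol: float = 0.05,
                   damping: float = 0.5, max_iter: int = 30,
                   dt: float = 1e-3, max_cycles: int = 25) -> TuningResult:
    """Tune ``(E_max, t_max)`` until mean and peak aortic flow match targets.

    Damped two-variable secant (Broyden) iteration in log-parameter space;
    each evaluation runs the coupled heart-afterload simulation to cyclic
    convergence.  Terminates when both fractional errors are within ``tol``
    (default 5 %); raises :class:`TuningError` with the full trace otherwise.
    """
    if target_mean_q <= 0 or target_peak_q <= 0:
        raise ValueError("targets must be positive")
    if isinstance(afterload, WindkesselParams):
        wk = afterload
        def fresh_afterload():
            return RCRAfterload(wk, q_mean_guess=target_mean_q)
    else:
        fresh_afterload = afterload

    ep0 = init.elastance
    t_max_lo, t_max_hi = 0.08, ep0.T - ep0.t_relax - 0.02

    log: list[dict] = []

    def evaluate(e_max: float, t_max: float):
        ep = replace(ep0, E_max=e_max, t_max=t_max)
        params = init.with_elastance(ep)
        run = simulate_heart(params, fresh_afterload(), dt=dt,
                             max_cycles=max_cycles,
                             q_mean_guess=target_mean_q)
        err = np.array([(run.mean_co - target_mean_q) / target_mean_q,
                        (run.peak_co - target_peak_q) / target_peak_q])
        log.append({"E_max": e_max, "t_max": t_max,
                    "mean_co": run.mean_co, "peak_co": run.peak_co,
                    "mean_error": err[0], "peak_error": err[1]})
        return err, run, params

    x = np.log([ep0.E_max, ep0.t_max])
    err, run, params = evaluate(*np.exp(x))
    if np.max(np.abs(err)) <= tol:
        return TuningResult(params, err[0], err[1], 1, True, log, run)

    # heuristic initial sensitivities of (mean, peak) errors to (ln E_max, ln t_max)
    J = np.array([[0.6, -0.25],
                  [0.35, -0.9]])
    for _ in range(1, max_iter):
        dx = -damping * np.linalg.solve(J, err)
        dx = np.clip(dx, -0.25, 0.25)
        x_new = x + dx
        x_new[1] = np.clip(x_new[1], math.log(t_max_lo), math.log(t_max_hi))
        x_new[0] = max(x_new[0], math.log(3.0 * ep0.E_min))
        dx = x_new - x
        if np.max(np.abs(dx)) < 1e-12:
            break
        err_new, run, params = evaluate(*np.exp(x_new))
        de = err_new - err
        J = J + np.outer(de - J @ dx, dx) / float(dx @ dx)
        x, err = x_new, err_new
        if np.max(np.abs(err)) <= tol:
            return TuningResult(params, err[0], err[1], len(log), True, log, run)
    raise TuningError(
        f"tuning did not converge in {len(log)} evaluations; "
        f"last errors mean={err[0]:+.3%}, peak={err[1]:+.3%}", log
    )


# ---------------------------------------------------------------------------
# packaged parameters
# ---------------------------------------------------------------------------

def load_heart_params(model: str = "dissected") -> HeartParams:
    """Load the packaged heart-parameter set (``dissected``/``undissected``)."""
    src = resources.files("dissectflow.data") / "heart_parameters.csv"
    with resources.as_file(src) as p:
        table = pd.read_csv(p).set_index("parameter")
    if model not in table.columns:
        raise ValueError(f"unknown model {model!r}; choose from {list(table.columns)}")
    col = table[model].astype(float)
    ep = ElastanceParams(
        T=col["period_s"],
        t_max=col["time_to_max_elastance_s"],
        t_relax=col["time_to_relaxation_s"],
        E_max=col["max_elastance_g_per_mm4_s2"],
        E_min=col["min_elastance_g_per_mm4_s2"],
    )
    vv = ValveParams(
        R_av=col["aortic_valve_resistance_g_per_mm4_s"],
        L_av=col["aortic_valve_inductance_g_per_mm4"],
        R_mv=col["mitral_valve_resistance_g_per_mm4_s"],
        L_mv=col["mitral_valve_inductance_g_per_mm4"],
    )
    vp = VentricleParams(
        V_u=col["unstressed_volume_mm3"],
        k_LV=col["ventricular_resistance_s_per_mm3"],
        V_ed=col["end_diastolic_volume_mm3"],
        P_LA=col["preload_g_per_mm_s2"],
    )
    return HeartParams(elastance=ep, valves=vv, ventricle=vp)
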