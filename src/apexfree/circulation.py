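"""Closed-loop lumped-parameter hemodynamics.

A minimal left-heart loop: left atrium (passive compliance, optional
elastance booster), diode-resistor mitral and aortic valves, a two-element
Windkessel arterial load (compliance + systemic resistance) and a venous
return compartment feeding the atrium.  Volumes are stressed volumes (mL);
pressures in mmHg; flows in mL/s.  The update is explicit and exactly
conservative: every flux leaves one compartment and enters another as the
same floating-point number, so total blood volume (including the LV) is
conserved to round-off.

The LV itself is mechanical: :func:`run_coupled_beat` alternates
circulation sub-steps (dt <= 2 ms) with volume-driven equilibrium solves
of a :class:`~apexfree.mechanics.WallModel` and repeats beats until the
stroke volume settles to a limit cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CirculationError
from .mechanics import WallModel

__all__ = ["CirculationParams", "CirculationState", "step_circulation",
           "BeatTrace", "run_coupled_beat"]


@dataclass(frozen=True)
class CirculationParams:
    """Lumped circulation constants (mmHg, mL, s)."""

    r_mv: float = 0.01        # mitral valve resistance (mmHg s/mL)
    r_av: float = 0.01        # aortic valve resistance
    c_art: float = 1.7        # arterial (Windkessel) compliance (mL/mmHg)
    r_sys: float = 0.9        # systemic resistance
    c_ven: float = 50.0       # venous compliance
    r_ven: float = 0.05       # venous-return resistance into the LA
    c_la: float = 8.0         # atrial compliance
    la_booster_amp: float = 0.0   # optional atrial elastance booster (mmHg)
    total_volume: float = 620.0   # total stressed blood volume incl. LV (mL)
    cycle_length: float = 1.0     # s (60 bpm; leaves a full diastole after
                                  # the ~0.9 s twitch of the most stretched
                                  # fibers)
    dt_max: float = 0.002         # circulation sub-step cap (s)

    def __post_init__(self):
        for name in ("r_mv", "r_av", "c_art", "r_sys", "c_ven", "r_ven",
                     "c_la"):
            if getattr(self, name) <= 0:
                raise CirculationError(f"{name} must be > 0")


@dataclass
class CirculationState:
    """Volumes/pressures of the non-LV compartments plus valve state."""

    v_la: float
    v_art: float
    v_ven: float
    mitral_open: bool = False
    aortic_open: bool = False
    q_mv: float = 0.0
    q_av: float = 0.0

    def pressures(self, params: CirculationParams, t: float = 0.0):
        p_la = self.v_la / params.c_la
        if params.la_booster_amp:
            # booster timed just before ventricular activation (end of cycle)
            phase = (t % params.cycle_length) / params.cycle_length
            p_la += params.la_booster_amp * max(
                0.0, np.sin(np.pi * (phase - 0.85) / 0.15))
        return p_la, self.v_art / params.c_art, self.v_ven / params.c_ven


def step_circulation(state: CirculationState, lv_pressure: float, dt: float,
                     params: CirculationParams, t: float = 0.0):
    """Advance the lumped loop by ``dt`` at fixed LV pressure.

    Returns ``(new_state, lv_inflow, lv_outflow)`` with flows in mL/s;
    the LV volume increment over the step is
    ``(lv_inflow - lv_outflow) * dt``.  Valves are ideal diodes in series
    with a resistance: no negative flow ever.
    """
    if dt <= 0:
        raise CirculationError("dt must be > 0")
    p_la, p_art, p_ven = state.pressures(params, t)
    q_mv = max(0.0, p_la - lv_pressure) / params.r_mv
    q_av = max(0.0, lv_pressure - p_art) / params.r_av
    q_sys = (p_art - p_ven) / params.r_sys
    q_ret = (p_ven - p_la) / params.r_ven

    d_mv, d_av = q_mv * dt, q_av * dt
    d_sys, d_ret = q_sys * dt, q_ret * dt
    new = replace(state,
                  v_la=state.v_la + d_ret - d_mv,
                  v_art=state.v_art + d_av - d_sys,
                  v_ven=state.v_ven + d_sys - d_ret,
                  mitral_open=q_mv > 0.0, aortic_open=q_av > 0.0,
                  q_mv=q_mv, q_av=q_av)
    if new.v_la < 0 or new.v_art < 0 or new.v_ven < 0:
        raise CirculationError("negative compartment volume: "
                               "time step too large")
    return new, q_mv, q_av


@dataclass
class BeatTrace:
    """Per-step record of the last (converged) coupled beat."""

    t: np.ndarray
    p_lv: np.ndarray            # mmHg
    v_lv: np.ndarray            # mL (conservative bookkeeping volume)
    p_art: np.ndarray
    p_la: np.ndarray
    q_mv: np.ndarray
    q_av: np.ndarray
    x_root: np.ndarray          # axial root displacement (mm, + toward base)
    x_apex: np.ndarray
    q_modes: np.ndarray         # (n_steps, n_modes) mechanical states
    total_volume: np.ndarray    # conservation diagnostic (mL)
    converged: bool = True
    n_beats: int = 0
    sv_history: list = field(default_factory=list)
    final_state: dict = field(default_factory=dict)  # resume payload

    @property
    def ed_index(self) -> int:
        """Index of end-diastole: the first step reaching the volume
        maximum (within 0.05 mL) — the end of filling, before the
        isovolumic pressure rise."""
        v = self.v_lv
        near = np.flatnonzero(v >= v.max() - 0.05)
        return int(near[0]) if len(near) else int(np.argmax(v))

    @property
    def es_index(self) -> int:
        """Index of end-systole: the first step reaching the volume
        minimum (within 0.05 mL), i.e. end of ejection rather than an
        arbitrary point of the flat isovolumic-relaxation segment."""
        v = self.v_lv
        near = np.flatnonzero(v <= v.min() + 0.05)
        return int(near[0]) if len(near) else int(np.argmin(v))


def run_coupled_beat(model: WallModel, params: CirculationParams,
                     n_steps: int = 80, max_beats: int = 10,
                     sv_tol: float = 0.01, v_lv_init: float | None = None,
                     p_art_init: float = 80.0, p_la_init: float = 10.0,
                     p_ven_init: float = 9.0,
                     resume: dict | None = None) -> BeatTrace:
    """Run coupled beats until the stroke volume reaches a limit cycle.

    Each mechanical step (cycle_length / n_steps) holds the LV pressure
    while the lumped loop is sub-stepped, accumulates the net LV in/outflow,
    and then re-solves wall equilibrium at the updated target volume
    (volume-driven coupling).  Activation restarts at each beat onset.
    Returns the last beat; if no limit cycle is reached within
    ``max_beats`` a warning is issued and the trace flagged.
    """
    dt = params.cycle_length / n_steps
    if resume:
        # continue from the end state of a previous run; total-volume
        # changes are absorbed by the venous compartment
        v_lv = resume["v_lv"]
        v_la, v_art = resume["v_la"], resume["v_art"]
        v_ven = params.total_volume - v_lv - v_la - v_art
        q_init, p_init = resume["q"], resume["p"]
    else:
        if v_lv_init is None:
            # start at the passive volume held by the initial atrial
            # pressure
            st0 = model.solve_equilibrium(p_la_init,
                                          t_act=params.cycle_length,
                                          t_scale=0.0)
            v_lv = st0.cavity_volume
            q_init, p_init = st0.q, st0.pressure
        else:
            v_lv = v_lv_init
            q_init, p_init = None, 1.0
        v_la = params.c_la * p_la_init
        v_art = params.c_art * p_art_init
        v_ven = params.total_volume - v_lv - v_la - v_art
    if v_ven <= 0:
        raise CirculationError("total_volume too small for the initial "
                               "compartment pressures")
    circ = CirculationState(v_la=v_la, v_art=v_art, v_ven=v_ven)

    state = model.pressure_for_volume(v_lv, t_act=params.cycle_length,
                                      q0=q_init, p0=p_init)
    sv_prev, converged = None, False
    sv_history = []
    dpdv = 0.5  # running LV stiffness estimate (mmHg/mL) for sub-stepping

    dv_max = 3.0  # mL per mechanical solve; larger changes split the step

    def advance(circ, v_lv, state, dpdv, t0, dt_step, depth=0):
        """One (possibly split) mechanical step; returns the new coupled
        state plus time-averaged valve flows over [t0, t0 + dt_step]."""
        m = max(1, int(np.ceil(dt_step / params.dt_max)))
        h = dt_step / m
        circ_try, dv = circ, 0.0
        q_mv_acc = q_av_acc = 0.0
        for _ in range(m):
            # linearized LV pressure during the sub-step keeps fast valve
            # flows stable between mechanical solves
            p_est = state.pressure + dpdv * dv
            circ_try, q_mv, q_av = step_circulation(
                circ_try, p_est, h, params, t0)
            dv += (q_mv - q_av) * h
            q_mv_acc += q_mv / m
            q_av_acc += q_av / m
        if abs(dv) > dv_max and depth < 5:
            half = dt_step / 2.0
            circ, v_lv, state, dpdv, qm1, qa1 = advance(
                circ, v_lv, state, dpdv, t0, half, depth + 1)
            circ, v_lv, state, dpdv, qm2, qa2 = advance(
                circ, v_lv, state, dpdv, t0 + half, half, depth + 1)
            return circ, v_lv, state, dpdv, 0.5 * (qm1 + qm2), 0.5 * (qa1 + qa2)
        v_new = v_lv + dv
        p_prev = state.pressure
        state = model.pressure_for_volume(
            v_new, t_act=t0 + dt_step, q0=state.q, p0=state.pressure)
        if abs(dv) > 0.5:
            slope = (state.pressure - p_prev) / dv
            if 0.02 <= slope <= 20.0:
                dpdv = slope
        return circ_try, v_new, state, dpdv, q_mv_acc, q_av_acc

    for beat in range(1, max_beats + 1):
        rows = {k: [] for k in ("t", "p_lv", "v_lv", "p_art", "p_la",
                                "q_mv", "q_av", "x_root", "x_apex", "tot")}
        qs = []
        for i in range(n_steps):
            t = i * dt
            circ, v_lv, state, dpdv, q_mv_acc, q_av_acc = advance(
                circ, v_lv, state, dpdv, t, dt)
            apex, root, _ = model.landmark_axial_displacements(state.q)
            p_la, p_art, _ = circ.pressures(params, t)
            rows["t"].append(t)
            rows["p_lv"].append(state.pressure)
            rows["v_lv"].append(v_lv)
            rows["p_art"].append(p_art)
            rows["p_la"].append(p_la)
            rows["q_mv"].append(q_mv_acc)
            rows["q_av"].append(q_av_acc)
            rows["x_root"].append(root)
            rows["x_apex"].append(apex)
            rows["tot"].append(v_lv + circ.v_la + circ.v_art + circ.v_ven)
            qs.append(state.q.copy())
        v = np.asarray(rows["v_lv"])
        sv = float(v.max() - v.min())
        sv_history.append(sv)
        if sv_prev is not None and abs(sv - sv_prev) <= sv_tol * max(sv, 1.0):
            converged = True
            break
        sv_prev = sv
    if not converged:
        warnings.warn("no limit cycle within max_beats; returning last beat",
                      RuntimeWarning)
    return BeatTrace(
        t=np.asarray(rows["t"]), p_lv=np.asarray(rows["p_lv"]),
        v_lv=v, p_art=np.asarray(rows["p_art"]),
        p_la=np.asarray(rows["p_la"]), q_mv=np.asarray(rows["q_mv"]),
        q_av=np.asarray(rows["q_av"]), x_root=np.asarray(rows["x_root"]),
        x_apex=np.asarray(rows["x_apex"]), q_modes=np.asarray(qs),
        total_volume=np.asarray(rows["tot"]), converged=converged,
        n_beats=beat, sv_history=sv_history,
        final_state={"v_lv": v_lv, "v_la": circ.v_la, "v_art": circ.v_art,
                     "q": state.q.copy(), "p": state.pressure})
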