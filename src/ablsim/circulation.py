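"""Closed-loop 0D circulation with valve states and 3D-0D volume coupling.

Eight volume states: systemic/pulmonary arterial and venous compartments
(linear compliances) and the four heart chambers (time-varying elastance
driven by the active-tension twitch shape).  Flows pass through smooth
resistance valves between chambers and linear resistances elsewhere; each
flow enters exactly two volume derivatives with opposite signs, so total
blood volume is conserved to round-off by construction.

A stroke-volume-difference accumulator integrates the difference between
aortic and pulmonary-artery flow; at integer multiples of the cycle
length its magnitude is compared against a threshold (1 mL) to decide
whether the periodic limit cycle has been reached, and is reset when not.

Chamber parameters expose an ``active_fraction`` (scales the contractile
elastance rise), an ``activation_delay`` and a ``passive_stiffening``
factor so electrophysiological and material consequences of ablation can
be imposed on the lumped chamber.  All pressures in mmHg, volumes in mL,
flows in mL/s, time in s.  Parameter values are implementation defaults
for a resting adult, declared in this module.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import tension as tn

MMHG_PER_KPA = 7.50062


@dataclass
class ChamberParams:
    name: str
    E_max: float            # mmHg/mL
    E_min: float
    V0: float                # mL, unstressed volume
    onset: float             # s, activation onset within the cycle
    twitch: tn.TensionParams
    active_fraction: float = 1.0
    activation_delay: float = 0.0  # s, extra delay from altered activation
    passive_stiffening: float = 1.0

    def elastance(self, t: float | np.ndarray, cycle: float) -> np.ndarray:
        """Periodic time-varying elastance E(t) in mmHg/mL."""
        tc = np.mod(np.asarray(t, dtype=float), cycle)
        t_ms = tc * 1e3
        onset_ms = (self.onset + self.activation_delay) * 1e3
        a = tn.tension(t_ms, onset_ms, 1.0, self.twitch) / _twitch_peak(self.twitch)
        E_min = self.E_min * self.passive_stiffening
        return E_min + (self.E_max - E_min) * self.active_fraction * a

    def pressure(self, V, t, cycle):
        return self.elastance(t, cycle) * (np.asarray(V, float) - self.V0)


def _twitch_peak(params: tn.TensionParams) -> float:
    ts = np.linspace(0.0, params.t_dur, 800)
    return float(tn.tension(ts + params.t_emd, 0.0, 1.0, params).max())


# twitch shapes reused from the tissue tension model (lambda held at 1)
_ATRIAL_TWITCH = tn.ATRIAL
_VENTRICULAR_TWITCH = tn.VENTRICULAR


@dataclass
class CircParams:
    cycle_length: float = 1.2        # s
    av_delay: float = 0.16           # s, atria to ventricles
    # compartment compliances (mL/mmHg) and unstressed volumes (mL)
    C_SysArt: float = 1.4
    C_SysVen: float = 60.0
    C_PulArt: float = 5.0
    C_PulVen: float = 16.0
    V0_SysArt: float = 700.0
    V0_SysVen: float = 2400.0
    V0_PulArt: float = 120.0
    V0_PulVen: float = 450.0
    # resistances (mmHg s/mL)
    R_sys: float = 1.05
    R_sysven: float = 0.05
    R_pul: float = 0.08
    R_pulven: float = 0.035
    R_mv: float = 0.004
    R_av: float = 0.008
    R_tv: float = 0.004
    R_pv: float = 0.008
    R_closed: float = 1e5
    p_smooth: float = 0.3            # mmHg, valve opening smoothness
    chambers: dict[str, ChamberParams] = field(default_factory=lambda: {
        "LA": ChamberParams("LA", E_max=0.22, E_min=0.13, V0=8.0,
                            onset=0.0, twitch=_ATRIAL_TWITCH),
        "LV": ChamberParams("LV", E_max=3.0, E_min=0.10, V0=12.0,
                            onset=0.16, twitch=_VENTRICULAR_TWITCH),
        "RA": ChamberParams("RA", E_max=0.30, E_min=0.11, V0=12.0,
                            onset=0.0, twitch=_ATRIAL_TWITCH),
        "RV": ChamberParams("RV", E_max=0.65, E_min=0.05, V0=18.0,
                            onset=0.16, twitch=_VENTRICULAR_TWITCH),
    })


STATE_ORDER = ("SysArt", "SysVen", "PulArt", "PulVen", "LV", "RV", "LA", "RA")


@dataclass
class CircState:
    volumes: np.ndarray            # (8,), mL, STATE_ORDER
    t: float = 0.0                 # s
    sv_diff: float = 0.0           # mL, accumulator
    converged: bool = False

    def volume(self, name: str) -> float:
        return float(self.volumes[STATE_ORDER.index(name)])


@dataclass
class CouplingSpec:
    tolerance: float = 1e-7        # mL
    max_subiter: int = 60
    stopping_threshold: float = 1.0  # mL
    cycle_length: float = 1.2      # s

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def initial_state(params: CircParams) -> CircState:
    v = np.array([780.0, 2700.0, 160.0, 520.0, 130.0, 130.0, 60.0, 60.0])
    return CircState(volumes=v)


def _valve_flow(p_up, p_dn, R_open, R_closed, p_smooth):
    dp = p_up - p_dn
    s = 1.0 / (1.0 + np.exp(np.clip(-dp / p_smooth, -60.0, 60.0)))
    return dp * (s / R_open + (1.0 - s) / R_closed), s


def pressures(volumes: np.ndarray, t: float, params: CircParams,
              overrides: dict[str, float] | None = None) -> dict[str, float]:
    v = dict(zip(STATE_ORDER, volumes))
    p = {
        "SysArt": (v["SysArt"] - params.V0_SysArt) / params.C_SysArt,
        "SysVen": (v["SysVen"] - params.V0_SysVen) / params.C_SysVen,
        "PulArt": (v["PulArt"] - params.V0_PulArt) / params.C_PulArt,
        "PulVen": (v["PulVen"] - params.V0_PulVen) / params.C_PulVen,
    }
    for name in ("LV", "RV", "LA", "RA"):
        if overrides and name in overrides:
            p[name] = overrides[name]
        else:
            p[name] = float(params.chambers[name].pressure(
                v[name], t, params.cycle_length))
    return p


def circulation_rhs(volumes: np.ndarray, t: float, params: CircParams,
                    overrides: dict[str, float] | None = None):
    """dV/dt for all compartments plus flows and valve states."""
    if np.any(volumes < 0):
        raise ValueError("negative compartment volume")
    p = pressures(volumes, t, params, overrides)
    q_mv, s_mv = _valve_flow(p["LA"], p["LV"], params.R_mv,
                             params.R_closed, params.p_smooth)
    q_av, s_av = _valve_flow(p["LV"], p["SysArt"], params.R_av,
                             params.R_closed, params.p_smooth)
    q_tv, s_tv = _valve_flow(p["RA"], p["RV"], params.R_tv,
                             params.R_closed, params.p_smooth)
    q_pv, s_pv = _valve_flow(p["RV"], p["PulArt"], params.R_pv,
                             params.R_closed, params.p_smooth)
    q_sys = (p["SysArt"] - p["SysVen"]) / params.R_sys
    q_sv = (p["SysVen"] - p["RA"]) / params.R_sysven
    q_pul = (p["PulArt"] - p["PulVen"]) / params.R_pul
    q_pvn = (p["PulVen"] - p["LA"]) / params.R_pulven
    dv = {
        "SysArt": q_av - q_sys,
        "SysVen": q_sys - q_sv,
        "PulArt": q_pv - q_pul,
        "PulVen": q_pul - q_pvn,
        "LV": q_mv - q_av,
        "RV": q_tv - q_pv,
        "LA": q_pvn - q_mv,
        "RA": q_sv - q_tv,
    }
    flows = {"Q_SysArt": q_av, "Q_PulArt": q_pv, "Q_mv": q_mv, "Q_tv": q_tv,
             "valve_mv": s_mv, "valve_av": s_av, "valve_tv": s_tv,
             "valve_pv": s_pv}
    return np.array([dv[k] for k in STATE_ORDER]), flows


def rk4_step(volumes: np.ndarray, t: float, dt: float, params: CircParams,
             overrides=None) -> np.ndarray:
    k1, _ = circulation_rhs(volumes, t, params, overrides)
    k2, _ = circulation_rhs(volumes + 0.5 * dt * k1, t + 0.5 * dt, params, overrides)
    k3, _ = circulation_rhs(volumes + 0.5 * dt * k2, t + 0.5 * dt, params, overrides)
    k4, _ = circulation_rhs(volumes + dt * k3, t + dt, params, overrides)
    return volumes + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def stopping_criterion(sv_diff: float, threshold: float = 1.0):
    """Cycle-boundary convergence check; returns (converged, new accumulator).

    The accumulator is reset to zero when the criterion is not yet met and
    kept (frozen) once it is.
    """
    converged = abs(sv_diff) < threshold
    return converged, (sv_diff if converged else 0.0)


def simulate(params: CircParams | None = None, n_cycles: int = 30,
             dt: float = 1e-3, spec: CouplingSpec | None = None,
             state: CircState | None = None, record: bool = True):
    """March the closed loop to the limit cycle (or n_cycles at most).

    Returns (final CircState, trace dict of numpy arrays).
    """
    params = params or CircParams()
    spec = spec or CouplingSpec(cycle_length=params.cycle_length)
    st = state or initial_state(params)
    v = st.volumes.copy()
    steps_per_cycle = int(round(params.cycle_length / dt))
    trace: dict[str, list] = {k: [] for k in
                              ["t", *[f"V_{c}" for c in STATE_ORDER],
                               *[f"p_{c}" for c in ("LA", "LV", "RA", "RV")],
                               "Q_SysArt", "Q_PulArt", "valve_mv", "valve_av"]}
    sv_diff = st.sv_diff
    converged = False
    t = st.t
    for cyc in range(n_cycles):
        for i in range(steps_per_cycle):
            d, flows = circulation_rhs(v, t, params)
            if record:
                p = pressures(v, t, params)
                trace["t"].append(t)
                for c in STATE_ORDER:
                    trace[f"V_{c}"].append(v[STATE_ORDER.index(c)])
                for c in ("LA", "LV", "RA", "RV"):
                    trace[f"p_{c}"].append(p[c])
                trace["Q_SysArt"].append(flows["Q_SysArt"])
                trace["Q_PulArt"].append(flows["Q_PulArt"])
                trace["valve_mv"].append(flows["valve_mv"])
                trace["valve_av"].append(flows["valve_av"])
            # accumulate the stroke-volume difference alongside the volumes
            sv_diff += dt * (flows["Q_SysArt"] - flows["Q_PulArt"])
            v = rk4_step(v, t, dt, params)
            t += dt
        converged, sv_diff = stopping_criterion(sv_diff, spec.stopping_threshold)
        if converged:
            break
    out = {k: np.asarray(val) for k, val in trace.items()}
    return CircState(volumes=v, t=t, sv_diff=sv_diff, converged=converged), out


def couple_chamber(v3d, v0d, p_lo: float = -5.0, p_hi: float = 40.0,
                   tol: float = 1e-7, max_iter: int = 200) -> float:
    """Find the chamber pressure where 3D and 0D volumes agree within tol.

    `v3d` and `v0d` are callables p -> V (mL).  Safeguarded secant with
    bracket expansion on the residual V3D(p) - V0D(p).
    """
    def f(p):
        return v3d(p) - v0d(p)

    flo, fhi = f(p_lo), f(p_hi)
    expand = 0
    while flo * fhi > 0 and expand < 12:
        span = p_hi - p_lo
        p_lo -= 0.5 * span
        p_hi += 0.5 * span
        flo, fhi = f(p_lo), f(p_hi)
        expand += 1
    if flo * fhi > 0:
        raise RuntimeError("chamber pressure root not bracketed")
    a, b, fa, fb = p_lo, p_hi, flo, fhi
    for _ in range(max_iter):
        # secant proposal, safeguarded to stay inside the bracket
        p = b - fb * (b - a) / (fb - fa) if fb != fa else 0.5 * (a + b)
        if not (min(a, b) < p < max(a, b)):
            p = 0.5 * (a + b)
        fp = f(p)
        if abs(fp) < tol:
            return float(p)
        if fa * fp < 0:
            b, fb = p, fp
        else:
            a, fa = p, fp
    raise RuntimeError("chamber coupling did not converge")
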