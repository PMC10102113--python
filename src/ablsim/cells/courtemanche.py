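"""Courtemanche–Ramirez–Nattel human atrial myocyte model.

Full 21-state formulation with fast/late sodium, transient-outward,
ultrarapid/rapid/slow delayed-rectifier and inward-rectifier potassium
currents, L-type calcium current, pumps and exchangers, and an SR calcium
handling subsystem (uptake, release, transfer, buffering).  Parameter
values follow the original publication.  All rates are per millisecond,
voltages in mV, concentrations in mM.

Two integration entry points are provided: :func:`rhs` for adaptive stiff
single-cell integration and :func:`step_rush_larsen` for the explicit
reaction half-step inside tissue simulations (exponential gate updates,
forward-Euler voltage and concentration updates).  Both are vectorized
over a trailing node axis.
"""
from __future__ import annotations

import json

import numpy as np

# physical constants and cell geometry
R = 8.3143          # J/(mol K)
T = 310.0           # K
F = 96.4867         # C/mmol
CM = 100.0          # pF, whole-cell membrane capacitance
V_CELL = 20100.0    # µm^3
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

K_O = 5.4           # mM
NA_O = 140.0
CA_O = 1.8

G_NA = 7.8          # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CA_L = 0.12375
G_B_NA = 0.0006744375
G_B_CA = 0.001131

I_NAK_MAX = 0.59933874   # pA/pF
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0      # pA/pF
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_CAP_MAX = 0.275        # pA/pF

I_UP_MAX = 0.005         # mM/ms
K_UP = 0.00092
CA_UP_MAX = 15.0
K_REL = 30.0             # 1/ms
TAU_TR = 180.0           # ms
TAU_U = 8.0
TAU_F_CA = 2.0
K_Q10 = 3.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "f_Ca", "u", "v", "w", "Na_i", "K_i", "Ca_i",
    "Ca_up", "Ca_rel",
)
N_STATES = len(STATE_NAMES)
_GATES = slice(1, 16)        # m .. w
_CONCS = slice(16, 21)       # Na_i .. Ca_rel

_Y0 = np.array([
    -81.18, 2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1,
    4.966e-3, 9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1,
    7.755e-1, 2.35e-112, 1.0, 9.992e-1, 1.117e1, 1.39e2,
    1.013e-4, 1.488, 1.488,
])


def initial_state(n: int | None = None) -> np.ndarray:
    """Published initial state; shape (21,) or (21, n)."""
    if n is None:
        return _Y0.copy()
    return np.repeat(_Y0[:, None], n, axis=1)


def _safe_div(num, den, lim):
    """num/den with a supplied limit where den ~ 0 (removable singularities)."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-10
    out = np.where(small, lim, num / np.where(small, 1.0, den))
    return out


def _gate_inf_tau(V, Ca_i, i_rel_flux):
    """Steady states and time constants of all 15 gates."""
    exp = np.exp

    a_m = _safe_div(0.32 * (V + 47.13), 1.0 - exp(-0.1 * (V + 47.13)), 3.2)
    b_m = 0.08 * exp(-V / 11.0)

    lo = V < -40.0
    a_h = np.where(lo, 0.135 * exp((V + 80.0) / -6.8), 0.0)
    b_h = np.where(lo, 3.56 * exp(0.079 * V) + 3.1e5 * exp(0.35 * V),
                   1.0 / (0.13 * (1.0 + exp((V + 10.66) / -11.1))))
    a_j = np.where(
        lo,
        (-1.2714e5 * exp(0.2444 * V) - 3.474e-5 * exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.1212 * exp(-0.01052 * V) / (1.0 + exp(-0.1378 * (V + 40.14))),
        0.3 * exp(-2.535e-7 * V) / (1.0 + exp(-0.1 * (V + 32.0))),
    )

    a_oa = 0.65 / (exp((V + 10.0) / -8.5) + exp((V - 30.0) / -59.0))
    b_oa = 0.65 / (2.5 + exp((V + 82.0) / 17.0))
    oa_inf = 1.0 / (1.0 + exp((V + 20.47) / -17.54))
    a_oi = 1.0 / (18.53 + exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + exp((V + 1.26) / -7.44))
    oi_inf = 1.0 / (1.0 + exp((V + 43.1) / 5.3))

    a_ua = 0.65 / (exp((V + 10.0) / -8.5) + exp((V - 30.0) / -59.0))
    b_ua = 0.65 / (2.5 + exp((V + 82.0) / 17.0))
    ua_inf = 1.0 / (1.0 + exp((V + 30.3) / -9.6))
    a_ui = 1.0 / (21.0 + exp((V - 185.0) / -28.0))
    b_ui = exp((V - 158.0) / 16.0)
    ui_inf = 1.0 / (1.0 + exp((V - 99.45) / 27.48))

    a_xr = _safe_div(0.0003 * (V + 14.1), 1.0 - exp((V + 14.1) / -5.0), 0.0015)
    b_xr = _safe_div(7.3898e-5 * (V - 3.3328),
                     exp((V - 3.3328) / 5.1237) - 1.0, 3.7861e-4)
    xr_inf = 1.0 / (1.0 + exp((V + 14.1) / -6.5))

    a_xs = _safe_div(4e-5 * (V - 19.9), 1.0 - exp((V - 19.9) / -17.0), 6.8e-4)
    b_xs = _safe_div(3.5e-5 * (V - 19.9),
                     exp((V - 19.9) / 9.0) - 1.0, 3.15e-4)
    xs_inf = 1.0 / np.sqrt(1.0 + exp((V - 19.9) / -12.7))

    d_inf = 1.0 / (1.0 + exp((V + 10.0) / -8.0))
    e10 = exp((V + 10.0) / -6.24)
    tau_d = _safe_div((1.0 - e10) * 1.0,
                      0.035 * (V + 10.0) * (1.0 + e10),
                      4.579 / (1.0 + e10))
    f_inf = 1.0 / (1.0 + exp((V + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * np.exp(-(0.0337**2) * (V + 10.0) ** 2) + 0.02)

    f_Ca_inf = 1.0 / (1.0 + Ca_i / 0.00035)

    # SR release gates driven by Fn
    Fn = i_rel_flux
    u_inf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    tau_w = _safe_div(6.0 * (1.0 - exp(-(V - 7.9) / 5.0)),
                      (1.0 + 0.3 * exp(-(V - 7.9) / 5.0)) * (V - 7.9),
                      6.0 * 0.2 / 1.3)

    inf = np.stack([
        a_m / (a_m + b_m), a_h / (a_h + b_h), a_j / (a_j + b_j),
        oa_inf, oi_inf, ua_inf, ui_inf, xr_inf, xs_inf,
        d_inf, f_inf, f_Ca_inf, u_inf, v_inf, w_inf,
    ])
    tau = np.stack([
        1.0 / (a_m + b_m), 1.0 / (a_h + b_h), 1.0 / (a_j + b_j),
        1.0 / ((a_oa + b_oa) * K_Q10), 1.0 / ((a_oi + b_oi) * K_Q10),
        1.0 / ((a_ua + b_ua) * K_Q10), 1.0 / ((a_ui + b_ui) * K_Q10),
        1.0 / (a_xr + b_xr), 0.5 / (a_xs + b_xs),
        tau_d, tau_f, np.full_like(np.asarray(V, dtype=float), TAU_F_CA),
        np.full_like(np.asarray(V, dtype=float), TAU_U), tau_v, tau_w,
    ])
    return inf, tau


def _currents(y):
    """All membrane currents (pA) and SR fluxes; returns a dict."""
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, f_Ca, u, v, w,
     Na_i, K_i, Ca_i, Ca_up, Ca_rel) = y
    exp = np.exp
    RT_F = R * T / F

    E_Na = RT_F * np.log(NA_O / Na_i)
    E_K = RT_F * np.log(K_O / K_i)
    E_Ca = RT_F / 2.0 * np.log(CA_O / Ca_i)

    i_Na = CM * G_NA * m**3 * h * j * (V - E_Na)
    i_K1 = CM * G_K1 * (V - E_K) / (1.0 + exp(0.07 * (V + 80.0)))
    i_to = CM * G_TO * oa**3 * oi * (V - E_K)
    g_Kur = 0.005 + 0.05 / (1.0 + exp((V - 15.0) / -13.0))
    i_Kur = CM * g_Kur * ua**3 * ui * (V - E_K)
    i_Kr = CM * G_KR * xr * (V - E_K) / (1.0 + exp((V + 15.0) / 22.4))
    i_Ks = CM * G_KS * xs**2 * (V - E_K)
    i_Ca_L = CM * G_CA_L * d * f * f_Ca * (V - 65.0)

    sigma = (exp(NA_O / 67.3) - 1.0) / 7.0
    f_NaK = 1.0 / (1.0 + 0.1245 * exp(-0.1 * V / RT_F)
                   + 0.0365 * sigma * exp(-V / RT_F))
    i_NaK = (CM * I_NAK_MAX * f_NaK / (1.0 + (KM_NA_I / Na_i) ** 1.5)
             * K_O / (K_O + KM_K_O))
    i_NaCa = (CM * I_NACA_MAX
              * (exp(GAMMA * V / RT_F) * Na_i**3 * CA_O
                 - exp((GAMMA - 1.0) * V / RT_F) * NA_O**3 * Ca_i)
              / ((KM_NA**3 + NA_O**3) * (KM_CA + CA_O)
                 * (1.0 + K_SAT * exp((GAMMA - 1.0) * V / RT_F))))
    i_CaP = CM * I_CAP_MAX * Ca_i / (0.0005 + Ca_i)
    i_B_Na = CM * G_B_NA * (V - E_Na)
    i_B_Ca = CM * G_B_CA * (V - E_Ca)

    i_rel = K_REL * u**2 * v * w * (Ca_rel - Ca_i)
    Fn = 1e3 * (1e-15 * V_REL * i_rel
                - 1e-15 / (2.0 * F) * (0.5 * i_Ca_L - 0.2 * i_NaCa))
    i_up = I_UP_MAX / (1.0 + K_UP / Ca_i)
    i_up_leak = I_UP_MAX * Ca_up / CA_UP_MAX
    i_tr = (Ca_up - Ca_rel) / TAU_TR

    i_ion = (i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_B_Na + i_B_Ca
             + i_NaK + i_CaP + i_NaCa + i_Ca_L)
    return dict(i_Na=i_Na, i_K1=i_K1, i_to=i_to, i_Kur=i_Kur, i_Kr=i_Kr,
                i_Ks=i_Ks, i_Ca_L=i_Ca_L, i_NaK=i_NaK, i_NaCa=i_NaCa,
                i_CaP=i_CaP, i_B_Na=i_B_Na, i_B_Ca=i_B_Ca, i_rel=i_rel,
                i_up=i_up, i_up_leak=i_up_leak, i_tr=i_tr, Fn=Fn,
                i_ion=i_ion)


def _conc_derivs(y, c):
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, f_Ca, u, v, w,
     Na_i, K_i, Ca_i, Ca_up, Ca_rel) = y
    dNa = (-3.0 * c["i_NaK"] - 3.0 * c["i_NaCa"] - c["i_B_Na"]
           - c["i_Na"]) / (F * V_I)
    dK = (2.0 * c["i_NaK"] - c["i_K1"] - c["i_to"] - c["i_Kur"]
          - c["i_Kr"] - c["i_Ks"]) / (F * V_I)
    B1 = ((2.0 * c["i_NaCa"] - (c["i_CaP"] + c["i_Ca_L"] + c["i_B_Ca"]))
          / (2.0 * F * V_I)
          + (V_UP * (c["i_up_leak"] - c["i_up"]) + c["i_rel"] * V_REL) / V_I)
    B2 = (1.0 + TRPN_MAX * KM_TRPN / (Ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Ca_i + KM_CMDN) ** 2)
    dCa_i = B1 / B2
    dCa_up = c["i_up"] - c["i_up_leak"] - c["i_tr"] * V_REL / V_UP
    dCa_rel = ((c["i_tr"] - c["i_rel"])
               / (1.0 + CSQN_MAX * KM_CSQN / (Ca_rel + KM_CSQN) ** 2))
    return dNa, dK, dCa_i, dCa_up, dCa_rel


def ionic_current(y: np.ndarray) -> np.ndarray:
    """Total ionic current per unit capacitance, pA/pF (= µA/µF)."""
    return _currents(y)["i_ion"] / CM


def rhs(y: np.ndarray, I_ext: float | np.ndarray = 0.0) -> np.ndarray:
    """Time derivative of the full state; I_ext in pA/pF depolarizing > 0."""
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    c = _currents(y)
    inf, tau = _gate_inf_tau(y[0], y[18], c["Fn"])
    dy = np.empty_like(np.asarray(y, dtype=float))
    dy[0] = -c["i_ion"] / CM + I_ext
    dy[_GATES] = (inf - y[_GATES]) / tau
    dy[_CONCS] = _conc_derivs(y, c)
    return dy


def step_rush_larsen(y: np.ndarray, dt: float,
                     I_ext: float | np.ndarray = 0.0) -> np.ndarray:
    """One explicit reaction step: exponential gates, Euler V and ions."""
    c = _currents(y)
    inf, tau = _gate_inf_tau(y[0], y[18], c["Fn"])
    out = np.empty_like(y)
    out[0] = y[0] + dt * (-c["i_ion"] / CM + I_ext)
    out[_GATES] = inf + (y[_GATES] - inf) * np.exp(-dt / tau)
    dNa, dK, dCa_i, dCa_up, dCa_rel = _conc_derivs(y, c)
    out[16] = y[16] + dt * dNa
    out[17] = y[17] + dt * dK
    out[18] = y[18] + dt * dCa_i
    out[19] = y[19] + dt * dCa_up
    out[20] = y[20] + dt * dCa_rel
    return out


def state_to_json(y: np.ndarray) -> str:
    """Named-variable snapshot for reproducible tissue initialization."""
    return json.dumps({k: float(v) for k, v in zip(STATE_NAMES, y)}, indent=1)


def state_from_json(text: str) -> np.ndarray:
    d = json.loads(text)
    return np.array([d[k] for k in STATE_NAMES])
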