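"""Reduced ventricular membrane surrogate (two-variable excitable model).

A Mitchell–Schaeffer-type model rescaled to physical voltage, tuned to a
ventricular-like action potential duration (~300 ms at a 1.2 s cycle
length, longer than the atrial model's) with a fast upstroke so the same
-20 mV activation threshold applies.  State: Vm (mV) and a recovery gate
h in [0, 1].
"""
from __future__ import annotations

import numpy as np

V_REST = -85.0   # mV
V_PEAK = 36.0    # mV
DV = V_PEAK - V_REST

TAU_IN = 0.3     # ms, excitation
TAU_OUT = 6.0    # ms, repolarization
TAU_OPEN = 120.0  # ms, gate recovery
TAU_CLOSE = 175.0  # ms, gate closing (sets APD ~330 ms, above the atrial model's)
U_GATE = 0.13    # normalized threshold

STATE_NAMES = ("V", "h")
N_STATES = 2


def initial_state(n: int | None = None) -> np.ndarray:
    y = np.array([V_REST, 1.0])
    if n is None:
        return y
    return np.repeat(y[:, None], n, axis=1)


def ionic_current(y: np.ndarray) -> np.ndarray:
    """Total ionic current per unit capacitance (pA/pF), so dV/dt = -I_ion."""
    V, h = y
    u = (V - V_REST) / DV
    J_in = h * u * u * (1.0 - u) / TAU_IN
    J_out = -u / TAU_OUT
    return -DV * (J_in + J_out)


def rhs(y: np.ndarray, I_ext: float | np.ndarray = 0.0) -> np.ndarray:
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    V, h = y
    u = (V - V_REST) / DV
    dV = np.broadcast_to(np.asarray(-ionic_current(y) + I_ext, dtype=float),
                         np.shape(V))
    dh = np.where(u < U_GATE, (1.0 - h) / TAU_OPEN, -h / TAU_CLOSE)
    return np.stack([dV, dh])


def step_rush_larsen(y: np.ndarray, dt: float,
                     I_ext: float | np.ndarray = 0.0) -> np.ndarray:
    """Explicit reaction step; the gate uses its exact exponential update."""
    V, h = y
    u = (V - V_REST) / DV
    out = np.empty_like(y)
    out[0] = V + dt * (-ionic_current(y) + I_ext)
    below = u < U_GATE
    out[1] = np.where(below,
                      1.0 + (h - 1.0) * np.exp(-dt / TAU_OPEN),
                      h * np.exp(-dt / TAU_CLOSE))
    return out
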