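"""Single-cell pacing to a limit cycle.

Cells are paced at a fixed cycle length for a number of beats and the
final state is used to initialize tissue simulations.  A per-beat APD90
trace is returned so convergence toward the limit cycle can be inspected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class PacingProtocol:
    cycle_length: float = 1200.0  # ms
    n_cycles: int = 1000
    amplitude: float = 20.0       # pA/pF, depolarizing
    duration: float = 2.0         # ms

    def __post_init__(self):
        if self.cycle_length <= self.duration:
            raise ValueError("cycle length must exceed stimulus duration")


def _apd90(t: np.ndarray, V: np.ndarray) -> float:
    """APD90 of one beat from a sampled trace (nan if no action potential)."""
    base = V[0]
    peak_i = int(np.argmax(V))
    peak = V[peak_i]
    if peak < 0.0:
        return float("nan")
    v90 = peak - 0.9 * (peak - base)
    up = np.where(V[: peak_i + 1] >= v90)[0]
    if len(up) == 0:
        return float("nan")
    t_up = t[up[0]]
    below = np.where(V[peak_i:] < v90)[0]
    if len(below) == 0:
        return float("nan")
    k = peak_i + below[0]
    # linear interpolation of the downward crossing
    t_dn = t[k - 1] + (t[k] - t[k - 1]) * (V[k - 1] - v90) / (V[k - 1] - V[k])
    return float(t_dn - t_up)


def pace_to_limit_cycle(protocol: PacingProtocol, model) -> tuple[np.ndarray, np.ndarray]:
    """Pace `model` (a cell module) and return (final state, APD90 per beat).

    Integration is adaptive and stiff-stable (LSODA); the stimulus window
    is integrated as a separate interval so the square pulse is exact.
    """
    y = model.initial_state()
    apds = []
    for beat in range(protocol.n_cycles):
        sol1 = solve_ivp(lambda t, yy: model.rhs(yy, protocol.amplitude),
                         (0.0, protocol.duration), y, method="LSODA",
                         rtol=1e-6, atol=1e-8, max_step=0.5)
        if not sol1.success or not np.all(np.isfinite(sol1.y[:, -1])):
            raise RuntimeError(f"numerical blow-up during beat {beat}")
        t_eval = np.arange(protocol.duration, protocol.cycle_length, 1.0)
        sol2 = solve_ivp(lambda t, yy: model.rhs(yy, 0.0),
                         (protocol.duration, protocol.cycle_length),
                         sol1.y[:, -1], method="LSODA",
                         rtol=1e-6, atol=1e-8, t_eval=t_eval, max_step=5.0)
        if not sol2.success or not np.all(np.isfinite(sol2.y[:, -1])):
            raise RuntimeError(f"numerical blow-up during beat {beat}")
        y = sol2.y[:, -1].copy()
        t_full = np.concatenate([sol1.t, sol2.t])
        V_full = np.concatenate([sol1.y[0], sol2.y[0]])
        apds.append(_apd90(t_full, V_full))
    return y, np.asarray(apds)
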