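"""Phenomenological active tension transient and active stress tensor.

The twitch is a product of two squared-tanh ramps gated by the local
activation time: contraction rises over tau_c after the electromechanical
delay, relaxes over tau_r, and lasts t_dur.  A length-dependence factor
phi(lambda) = max(tanh(ld (lambda - lambda0)), 0) scales the peak and
(through ld_up) slows contraction at short sarcomere length.  The active
second Piola-Kirchhoff stress distributes the scalar tension across the
fiber/sheet/normal directions weighted by n_f, n_s, n_n and divided by the
directional stretch.

Atrial and ventricular parameter sets differ mainly in t_dur: atrial
twitches are shorter, so atrial and ventricular tension do not overlap in
time under the sinus timing (atria stimulated at 0, ventricles 160 ms
later).  Scar tissue never reaches the activation threshold, hence never
develops tension.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class TensionParams:
    """Parameters of the active tension transient (defaults: ventricle)."""

    S_peak: float = 60.0     # kPa
    t_dur: float = 400.0     # ms, twitch duration
    tau_c0: float = 80.0     # ms, baseline contraction time constant
    tau_r: float = 70.0      # ms, relaxation time constant
    ld: float = 5.0          # length-dependence gain
    ld_up: float = 500.0     # ms, contraction slow-down at low stretch
    lambda0: float = 0.7     # stretch below which no tension develops
    t_emd: float = 20.0      # ms, electromechanical delay

    def __post_init__(self):
        if min(self.t_dur, self.tau_c0, self.tau_r) <= 0:
            raise ValueError("time constants must be positive")
        if not 0 < self.lambda0 < 1.2:
            raise ValueError("lambda0 out of range")


#: atrial twitch: shorter duration and faster relaxation than ventricular,
#: so atrial tension has decayed before ventricular tension onset (AV delay
#: 160 ms + electromechanical delay) for tissue activated early in the P wave
ATRIAL = TensionParams(S_peak=30.0, t_dur=140.0, tau_c0=40.0, tau_r=40.0,
                       ld_up=300.0)
VENTRICULAR = TensionParams()


def scaled(params: TensionParams, peak_scale: float) -> TensionParams:
    return replace(params, S_peak=params.S_peak * peak_scale)


@dataclass
class ActiveStressConfig:
    """Orthotropic activation weights (fiber-only by default)."""

    n_f: float = 1.0
    n_s: float = 0.0
    n_n: float = 0.0

    def __post_init__(self):
        if min(self.n_f, self.n_s, self.n_n) < 0:
            raise ValueError("activation weights must be nonnegative")


def phi(lam, params: TensionParams):
    """Length dependence max(tanh(ld (lambda - lambda0)), 0)."""
    return np.maximum(np.tanh(params.ld * (np.asarray(lam, float)
                                           - params.lambda0)), 0.0)


def tension(t, t_A, lam, params: TensionParams):
    """Active tension S_A(t) in kPa; t and t_A in ms, vectorized.

    Nodes that never activated (t_A = nan) develop no tension.
    """
    t = np.asarray(t, dtype=float)
    t_A = np.asarray(t_A, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(lam))):
        raise ValueError("non-finite inputs")
    ph = phi(lam, params)
    tau_c = params.tau_c0 + params.ld_up * (1.0 - ph)
    t_s = t - t_A - params.t_emd
    active = np.isfinite(t_s) & (t_s > 0.0) & (t_s < params.t_dur)
    t_s = np.where(active, t_s, 0.0)
    S = (params.S_peak * ph
         * np.tanh(t_s / tau_c) ** 2
         * np.tanh((params.t_dur - t_s) / params.tau_r) ** 2)
    return np.where(active, S, 0.0)


def active_stress(F: np.ndarray, S_A, frame: np.ndarray,
                  config: ActiveStressConfig | None = None) -> np.ndarray:
    """Active second Piola-Kirchhoff stress, shape like (..., 3, 3).

    S_act = S_A sum_k n_k (k0 x k0) / lambda_k,  lambda_k = |F k0|.
    """
    if config is None:
        config = ActiveStressConfig()
    F = np.asarray(F, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if F.ndim == 2:
        if np.linalg.det(F) <= 0:
            raise ValueError("det F must be positive")
    S = np.zeros(F.shape)
    S_A = np.asarray(S_A, dtype=float)
    for k, weight in enumerate((config.n_f, config.n_s, config.n_n)):
        if weight == 0.0:
            continue
        k0 = frame[..., :, k]
        Fk = np.einsum("...ij,...j->...i", F, k0)
        lam_k = np.linalg.norm(Fk, axis=-1)
        if np.any(lam_k <= 0):
            raise ValueError("zero directional stretch")
        outer = k0[..., :, None] * k0[..., None, :]
        S = S + (weight * S_A / lam_k)[..., None, None] * outer
    return S
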