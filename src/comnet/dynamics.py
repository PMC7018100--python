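"""Elementary right-hand sides of the circuit equations.

Pure functions of state and parameters: no integration, no randomness.
All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters, hz_to_per_ms

__all__ = [
    "threshold_linear",
    "io_gain",
    "stimulus_current",
    "sensorimotor_input",
    "synaptic_drift",
    "uncertainty_drift",
    "hand_drift",
    "ou_noise_drift",
]


def threshold_linear(u):
    """Threshold-linear transfer [u]_+ = max(u, 0).

    Rejects non-finite input so NaNs cannot propagate silently through
    the rectification used by the uncertainty and hand populations.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("threshold_linear requires finite input")
    out = np.maximum(u, 0.0)
    return float(out) if out.ndim == 0 else out


def io_gain(x, params: ModelParameters):
    """Firing rate of a sensorimotor population given total current x (nA).

    H(x) = G_S (a x - b) / (1 - exp(-d (a x - b))), the standard
    sigmoid-linear transfer of the mean-field reduction.  The removable
    singularity at a x = b is replaced by its analytic limit G_S / d;
    the large-|u| branches are handled so the function never overflows
    and stays strictly increasing.
    """
    x = np.asarray(x, dtype=float)
    u = params.a * x - params.b
    du = params.d * u
    # denominator -expm1(-du) -> inf for very negative du, giving H -> +0,
    # which is the correct asymptote; silence the spurious overflow warning.
    with np.errstate(over="ignore", invalid="ignore"):
        h = params.G_S * u / (-np.expm1(-du))
    # series u/(1-e^{-du}) = (1/d)(1 + du/2 + du^2/12 + O(du^4)) near du = 0
    small = np.abs(du) < 1e-8
    if np.any(small):
        limit = (params.G_S / params.d) * (1.0 + du / 2.0 + du * du / 12.0)
        h = np.where(small, limit, h)
    return float(h) if h.ndim == 0 else h


def stimulus_current(coherence, side, t, params: ModelParameters):
    """External stimulus currents (I_L, I_R) in nA at time t (ms).

    While the stimulus is on (0 <= t < t_stim) the population favoured
    by the motion direction receives J_A_ext * mu_0 * (1 + c') and the
    other J_A_ext * mu_0 * (1 - c'), with c' the coherence fraction.
    Outside the stimulus window both currents are zero.
    """
    coherence = float(coherence)
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    t = np.asarray(t, dtype=float)
    on = (t >= 0.0) & (t < params.t_stim)
    base = params.J_A_ext * params.mu_0
    fav = base * (1.0 + coherence)
    unf = base * (1.0 - coherence)
    I_fav = np.where(on, fav, 0.0)
    I_unf = np.where(on, unf, 0.0)
    if side == "left":
        I_L, I_R = I_fav, I_unf
    else:
        I_L, I_R = I_unf, I_fav
    if I_L.ndim == 0:
        return float(I_L), float(I_R)
    return I_L, I_R


def sensorimotor_input(S_i, S_j, I_stim_i, y_HU, I_eta_i,
                       params: ModelParameters):
    """Total synaptic current x_i (nA) into one sensorimotor population.

    x_i = J_N_ii S_i - J_N_ij S_j + I_0 + I_i + J_mc0 y_HU + I_eta_i:
    recurrent self-excitation, cross-inhibition, tonic background,
    stimulus drive, excitatory uncertainty feedback and the OU noise
    current.
    """
    return (params.J_N_ii * S_i - params.J_N_ij * S_j + params.I_0
            + I_stim_i + params.J_mc0 * y_HU + I_eta_i)


def synaptic_drift(S_L, S_R, H_L, H_R, params: ModelParameters):
    """Drift (per ms) of the two NMDA gating variables.

    dS_i/dt = -S_i / tau_S + (1 - S_i) * gamma * H_i, with H converted
    from Hz to per-ms.  The (1 - S) factor keeps S below 1 and the decay
    term keeps it above 0.
    """
    gL = params.gamma * hz_to_per_ms(H_L)
    gR = params.gamma * hz_to_per_ms(H_R)
    dS_L = -S_L / params.tau_S + (1.0 - S_L) * gL
    dS_R = -S_R / params.tau_S + (1.0 - S_R) * gR
    return dS_L, dS_R


def uncertainty_drift(y_HU, H_L, H_R, g, params: ModelParameters):
    """Drift (Hz per ms) of the uncertainty-monitoring population.

    tau_mc dy/dt = [J_VHU (H_L + H_R) - g]_+ - y.  The top-down
    inhibition g gates monitoring: while g exceeds the summed drive the
    bracket is zero and the rate decays exponentially.
    """
    drive = threshold_linear(params.J_VHU * (np.asarray(H_L) + np.asarray(H_R)) - g)
    return (drive - y_HU) / params.tau_mc


def hand_drift(y_HL, y_HR, H_L, H_R, g, params: ModelParameters):
    """Drifts (Hz per ms) of the two mutually inhibiting hand populations.

    tau_h dy_L/dt = [H_L - J_N_LR y_HR - g]_+ - y_HL (and mirror with
    J_N_RL).  With g at its pre-decision value both populations are
    suppressed toward zero; with g = 0 they form a line-attractor race.
    """
    dL = (threshold_linear(H_L - params.J_N_LR * np.asarray(y_HR) - g) - y_HL) / params.tau_h
    dR = (threshold_linear(H_R - params.J_N_RL * np.asarray(y_HL) - g) - y_HR) / params.tau_h
    return dL, dR


def ou_noise_drift(I_eta, params: ModelParameters):
    """Ornstein-Uhlenbeck drift (nA/ms) and diffusion (nA/sqrt(ms)).

    dI = -I/tau_noise dt + sigma_noise sqrt(2/tau_noise) dW, whose
    stationary standard deviation is exactly sigma_noise.
    """
    drift = -np.asarray(I_eta, dtype=float) / params.tau_noise
    diffusion = params.sigma_noise * np.sqrt(2.0 / params.tau_noise)
    if drift.ndim == 0:
        return float(drift), float(diffusion)
    return drift, diffusion
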