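"""Model parameters and trial protocols.

Unit conventions used throughout the package: time in milliseconds,
firing rates in Hz, currents in nA, synaptic gating variables
dimensionless in [0, 1].  The single place where Hz is converted to a
per-millisecond rate is :func:`hz_to_per_ms`; every drift function calls
it so the circuit equations read exactly like their published form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import yaml

#: Coherence levels of the random-dot stimulus used in the study design.
STANDARD_COHERENCES = (0.0, 0.032, 0.064, 0.128, 0.256, 0.512)

Side = Literal["left", "right"]


def hz_to_per_ms(rate_hz):
    """Convert a firing rate in Hz to events per millisecond.

    Gating-variable kinetics multiply a dimensionless constant by a
    population rate; the product must be a per-ms rate because the
    integration clock runs in milliseconds.
    """
    return rate_hz / 1000.0


@dataclass
class ModelParameters:
    """Full parameter set of the uncertainty-monitoring decision circuit.

    Defaults are the published operating point of the model: a
    two-variable mean-field sensorimotor module (NMDA gating variables
    ``S_L``, ``S_R``), a single uncertainty-monitoring population
    (``y_HU``) that receives the summed sensorimotor rates and feeds
    excitation back to both sides, and a mutually inhibiting pair of
    motor ("hand") populations whose rate difference maps linearly onto
    cursor x-position.

    Attributes
    ----------
    tau_S : float
        Sensorimotor (NMDA gating) time constant, ms.
    tau_h : float
        Hand-population time constant, ms.
    tau_mc : float
        Uncertainty-population time constant, ms.
    a, b, d : float
        Input-output function parameters: gain (V nC)^-1, rate offset Hz
        and curvature s of the fitted leaky integrate-and-fire transfer
        function.
    I_0 : float
        Effective tonic background current, nA.
    J_N_ii, J_N_ij : float
        Sensorimotor self-excitation and cross-inhibition strengths, nA.
    mu_0 : float
        Baseline stimulus input strength, Hz.
    J_A_ext : float
        External input synaptic coupling, nA Hz^-1.
    J_mc0 : float
        Excitatory feedback strength from the uncertainty population
        (dimensionless scaling of its rate into nA).
    J_VHU : float
        Input coupling from sensorimotor rates to the uncertainty
        population, nA.
    J_N_LR, J_N_RL : float
        Mutual inhibition between the hand populations, nA.
    S_th : float
        Sensorimotor decision threshold, Hz: first crossing defines the
        model's response time.
    H_th : float
        Hand target threshold, Hz: rate difference at which the mapped
        cursor reaches a choice target.
    G_S : float
        Sensorimotor input-output gain (dimensionless multiplier).
    gamma : float
        Gating kinetic constant of the NMDA variables (dimensionless).
    sigma_noise : float
        Stationary s.d. of the Ornstein-Uhlenbeck noise currents, nA.
        The default (0.017) is the calibrated operating point at which
        the simulated non-decision rate matches the published 3.4%;
        see the methods note.
    tau_noise : float
        OU noise time constant, ms.
    g_pre : float
        Top-down inhibition of the uncertainty population before the
        monitoring gate opens, nA.
    g_post : float
        Top-down inhibition re-applied once a sensorimotor population
        crosses ``S_th``, nA.
    g_hand : float
        Suppression of the hand populations before the decision, nA.
        Any value above the maximum feasible drive acts identically.
    C_pos : float
        x-position of a choice target in pixels (centre line = 0).
    dt : float
        Euler-Maruyama integration step, ms.
    t_gate : float
        Gate-opening latency of uncertainty monitoring after stimulus
        onset, ms.
    t_stim : float
        Stimulus duration, ms; response time is measured from stimulus
        offset.
    t_max : float
        Maximum trial duration, ms; trials with no threshold crossing by
        ``t_max`` are non-decision trials.
    """

    tau_S: float = 100.0
    tau_h: float = 50.0
    tau_mc: float = 150.0
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    I_0: float = 0.3255
    J_N_ii: float = 0.248
    J_N_ij: float = 0.0497
    mu_0: float = 30.0
    J_A_ext: float = 0.00052
    J_mc0: float = 0.002
    J_VHU: float = 10.0
    J_N_LR: float = 1.0
    J_N_RL: float = 1.0
    S_th: float = 42.5
    H_th: float = 17.4
    G_S: float = 1.12
    gamma: float = 0.641
    sigma_noise: float = 0.017
    tau_noise: float = 2.0
    g_pre: float = 1000.0
    g_post: float = 3000.0
    g_hand: float = 1000.0
    C_pos: float = 760.0
    dt: float = 0.5
    t_gate: float = 600.0
    t_stim: float = 800.0
    t_max: float = 4000.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("tau_S", "tau_h", "tau_mc", "tau_noise", "dt",
                     "t_stim", "t_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dt > self.tau_noise:
            raise ValueError("dt must not exceed tau_noise")
        if self.S_th <= 0 or self.H_th <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")
        if self.t_gate < 0:
            raise ValueError("t_gate must be nonnegative")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(
                "unknown parameter key(s): " + ", ".join(sorted(unknown))
            )
        return cls(**{k: float(v) for k, v in data.items()})

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("parameter file must contain a mapping")
        return cls.from_dict(data)


@dataclass
class StimulusProtocol:
    """One trial's stimulus condition.

    ``coherence`` is the motion-coherence fraction in [0, 1]; stimulus
    onset defines t = 0 and the stimulus is extinguished at
    ``ModelParameters.t_stim``.
    """

    coherence: float
    correct_side: Side = "right"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        if self.correct_side not in ("left", "right"):
            raise ValueError("correct_side must be 'left' or 'right'")


@dataclass
class CircuitState:
    """Instantaneous state of the seven dynamical variables plus clock.

    ``S_L``/``S_R`` are the NMDA gating variables, ``I_eta_*`` the OU
    noise currents, ``y_HU`` the uncertainty-population rate and
    ``y_HL``/``y_HR`` the hand-population rates.
    """

    S_L: float = 0.0
    S_R: float = 0.0
    I_eta_L: float = 0.0
    I_eta_R: float = 0.0
    y_HU: float = 0.0
    y_HL: float = 0.0
    y_HR: float = 0.0
    t: float = 0.0
    decided: bool = False
    decision_time: float | None = None

    def copy(self) -> "CircuitState":
        return dataclasses.replace(self)
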