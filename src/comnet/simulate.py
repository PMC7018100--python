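"""Stochastic trial simulation of the full circuit.

The integrator advances seven dynamical variables per trial with a
forward Euler-Maruyama scheme (dt from :class:`ModelParameters`,
0.5 ms by default): two NMDA gating variables ``S_L``/``S_R``, two
Ornstein-Uhlenbeck noise currents, the uncertainty-population rate
``y_HU`` and the two hand-population rates ``y_HL``/``y_HR``.

Event schedule within a trial (t = 0 at stimulus onset):

* ``t < t_gate`` — uncertainty monitoring inhibited (g = g_pre), hand
  populations suppressed (g_hand).
* ``t_gate <= t`` until decision — monitoring gate open (g = 0): y_HU
  integrates the summed sensorimotor rates and feeds excitation back.
* decision — first time a sensorimotor rate reaches S_th (42.5 Hz):
  monitoring is re-inhibited (g = g_post) and the hand race is released
  (g_hand -> 0).
* trial end — hand rate difference reaches H_th (cursor at a choice
  target) or t_max elapses.

A trial with no completed response by t_max — no S_th crossing, or a
motor race that never reaches the choice target — is a non-decision
trial ("target threshold was not reached").  A
change-of-mind is a reversal of dominance between the hand populations,
where dominance requires an absolute rate difference above 2 Hz.

Trials are simulated in vectorized batches; each trial consumes an
independent counter-derived random stream, so results do not depend on
batch composition or ordering.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynamics
from .params import CircuitState, ModelParameters, StimulusProtocol

__all__ = [
    "TrialResult",
    "simulate_trial",
    "run_experiment",
    "classify_change_of_mind",
    "map_hand_to_x",
    "COM_DOMINANCE_THRESHOLD_HZ",
]

#: Absolute hand-rate difference (Hz) required for dominance when
#: counting reversals.
COM_DOMINANCE_THRESHOLD_HZ = 2.0

_NOISE_CHUNK = 512  # integration steps of noise drawn per generator call


@dataclass
class TrialResult:
    """Outcome of one simulated trial.

    ``response_time`` is measured from stimulus offset and may be
    negative if the decision threshold was crossed during the stimulus;
    it is ``None`` for non-decision trials, as is ``choice``.
    """

    choice: str | None
    correct: bool | None
    response_time: float | None
    decision_time_raw: float | None
    is_com: bool
    n_reversals: int
    peak_uncertainty: float
    protocol: StimulusProtocol
    timeseries: pd.DataFrame | None = None
    x_trace: np.ndarray | None = None

    @property
    def non_decision(self) -> bool:
        return self.choice is None


def map_hand_to_x(y_HL, y_HR, params: ModelParameters):
    """Map hand-population rates onto cursor x-position in pixels.

    x = q (y_HL - y_HR) with q = |C_pos| / H_th, so a rate difference of
    H_th places the cursor exactly on a choice target.  Positive x is
    the left target by convention.
    """
    q = abs(params.C_pos) / params.H_th
    x = q * (np.asarray(y_HL, dtype=float) - np.asarray(y_HR, dtype=float))
    return float(x) if x.ndim == 0 else x


def classify_change_of_mind(hand_trace, threshold: float = COM_DOMINANCE_THRESHOLD_HZ):
    """Classify a hand-rate trace as change-of-mind or not.

    Parameters
    ----------
    hand_trace : array-like, shape (T, 2)
        Time series of (y_HL, y_HR) covering the post-decision period.
    threshold : float
        Minimum absolute rate difference (Hz) for a dominance episode.

    Returns
    -------
    (is_com, n_reversals)
        ``n_reversals`` counts sign alternations between successive
        maximal episodes with |y_HL - y_HR| > threshold; a trial is a
        change-of-mind when at least one reversal occurred.
    """
    trace = np.asarray(hand_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("hand trace is empty")
    delta = trace[:, 0] - trace[:, 1]
    signs = np.sign(delta) * (np.abs(delta) > threshold)
    episodes = signs[signs != 0]
    if episodes.size == 0:
        return False, 0
    changes = np.count_nonzero(np.diff(episodes) != 0)
    return changes >= 1, int(changes)


def _spawn_trial_seed(master_seed: int, condition_index: int, trial_index: int):
    """Counter-based per-trial seed: independent of batch ordering."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(condition_index, trial_index)
    )


def _simulate_batch(coherence, right_favoured, params: ModelParameters,
                    generators, tie_rng, record: bool = False):
    """Integrate a batch of trials of one stimulus condition.

    Parameters
    ----------
    coherence : float
        Motion coherence fraction shared by the batch.
    right_favoured : bool array, shape (n,)
        True where the correct direction is rightward.
    generators : sequence of numpy Generators or None
        One independent stream per trial (None in noise-off mode).
    tie_rng : numpy Generator
        Used only to break an exact hand-rate tie at trial end.
    record : bool
        Record per-step traces (intended for small batches).

    Returns
    -------
    dict of per-trial result arrays (and stacked traces if recorded).
    """
    n = right_favoured.shape[0]
    p = params
    dt = p.dt
    n_steps = int(round(p.t_max / dt))
    sqdt = np.sqrt(dt)

    S_L = np.zeros(n)
    S_R = np.zeros(n)
    I_eta_L = np.zeros(n)
    I_eta_R = np.zeros(n)
    y_HU = np.zeros(n)
    y_HL = np.zeros(n)
    y_HR = np.zeros(n)

    decided = np.zeros(n, dtype=bool)
    decision_step = np.full(n, -1, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    end_step = np.full(n, n_steps, dtype=np.int64)
    final_delta = np.zeros(n)
    peak_y = np.zeros(n)
    # streaming dominance-episode tracking for change-of-mind counting
    last_sign = np.zeros(n, dtype=np.int8)
    n_reversals = np.zeros(n, dtype=np.int64)

    base = p.J_A_ext * p.mu_0
    I_fav = base * (1.0 + coherence)
    I_unf = base * (1.0 - coherence)
    stim_L = np.where(right_favoured, I_unf, I_fav)
    stim_R = np.where(right_favoured, I_fav, I_unf)

    noisy = p.sigma_noise > 0 and generators is not None
    diffusion = p.sigma_noise * np.sqrt(2.0 / p.tau_noise)
    noise = None

    traces = [] if record else None

    for k in range(n_steps):
        if not active.any():
            break
        t = k * dt
        if noisy and k % _NOISE_CHUNK == 0:
            m = min(_NOISE_CHUNK, n_steps - k)
            noise = np.zeros((n, m, 2))
            for i in np.nonzero(active)[0]:
                noise[i] = generators[i].standard_normal((m, 2))

        stim_on = t < p.t_stim
        I_L = stim_L if stim_on else 0.0
        I_R = stim_R if stim_on else 0.0

        x_L = (p.J_N_ii * S_L - p.J_N_ij * S_R + p.I_0 + I_L
               + p.J_mc0 * y_HU + I_eta_L)
        x_R = (p.J_N_ii * S_R - p.J_N_ij * S_L + p.I_0 + I_R
               + p.J_mc0 * y_HU + I_eta_R)
        H_L = dynamics.io_gain(x_L, p)
        H_R = dynamics.io_gain(x_R, p)

        # decision: first S_th crossing; takes effect within this step so
        # monitoring halts and the hand race is released at that moment
        newly = active & ~decided & ((H_L >= p.S_th) | (H_R >= p.S_th))
        if newly.any():
            decided |= newly
            decision_step[newly] = k

        g_mc = np.where(decided, p.g_post,
                        np.where(t >= p.t_gate, 0.0, p.g_pre))
        g_hand = np.where(decided, 0.0, p.g_hand)

        dS_L, dS_R = dynamics.synaptic_drift(S_L, S_R, H_L, H_R, p)
        drive_mc = np.maximum(p.J_VHU * (H_L + H_R) - g_mc, 0.0)
        dy_HU = (drive_mc - y_HU) / p.tau_mc
        dy_HL = (np.maximum(H_L - p.J_N_LR * y_HR - g_hand, 0.0) - y_HL) / p.tau_h
        dy_HR = (np.maximum(H_R - p.J_N_RL * y_HL - g_hand, 0.0) - y_HR) / p.tau_h

        upd = active
        S_L = np.where(upd, np.clip(S_L + dt * dS_L, 0.0, 1.0), S_L)
        S_R = np.where(upd, np.clip(S_R + dt * dS_R, 0.0, 1.0), S_R)
        y_HU = np.where(upd, y_HU + dt * dy_HU, y_HU)
        y_HL = np.where(upd, np.maximum(y_HL + dt * dy_HL, 0.0), y_HL)
        y_HR = np.where(upd, np.maximum(y_HR + dt * dy_HR, 0.0), y_HR)
        if noisy:
            xi = noise[:, k % _NOISE_CHUNK, :]
            I_eta_L = np.where(upd, I_eta_L - dt * I_eta_L / p.tau_noise
                               + diffusion * sqdt * xi[:, 0], I_eta_L)
            I_eta_R = np.where(upd, I_eta_R - dt * I_eta_R / p.tau_noise
                               + diffusion * sqdt * xi[:, 1], I_eta_R)

        bad = upd & ~(np.isfinite(S_L) & np.isfinite(S_R) & np.isfinite(y_HU)
                      & np.isfinite(y_HL) & np.isfinite(y_HR))
        if bad.any():
            raise FloatingPointError(
                f"non-finite state in {int(bad.sum())} trial(s) at t={t} ms"
            )

        np.maximum(peak_y, np.where(upd, y_HU, 0.0), out=peak_y)

        delta = y_HL - y_HR
        sgn = np.sign(delta).astype(np.int8)
        dominant = np.abs(delta) > COM_DOMINANCE_THRESHOLD_HZ
        track = upd & decided & dominant
        flip = track & (last_sign != 0) & (sgn != last_sign)
        n_reversals[flip] += 1
        last_sign = np.where(track, sgn, last_sign)

        if record:
            traces.append(np.stack(
                [S_L, S_R, I_eta_L, I_eta_R, y_HU, y_HL, y_HR], axis=-1
            ).copy())

        finished = upd & decided & (np.abs(delta) >= p.H_th)
        if finished.any():
            end_step[finished] = k + 1
            final_delta[finished] = delta[finished]
            active &= ~finished

    # trials that ran to t_max: freeze whatever dominance held at the end
    final_delta[active] = (y_HL - y_HR)[active]

    choice = np.zeros(n, dtype=np.int8)  # +1 left, -1 right, 0 none
    dec = decision_step >= 0
    choice[dec] = np.sign(final_delta[dec]).astype(np.int8)
    ties = dec & (choice == 0)
    if ties.any():
        choice[ties] = np.where(tie_rng.random(int(ties.sum())) < 0.5, 1, -1)

    out = {
        "decision_step": decision_step,
        "end_step": end_step,
        "resolved": end_step < n_steps,
        "choice": choice,
        "n_reversals": n_reversals,
        "peak_uncertainty": peak_y,
    }
    if record:
        out["traces"] = np.stack(traces, axis=1) if traces else np.zeros((n, 0, 7))
    return out


_TRACE_COLUMNS = ["S_L", "S_R", "I_eta_L", "I_eta_R", "y_HU", "y_HL", "y_HR"]


def simulate_trial(protocol: StimulusProtocol, params: ModelParameters | None = None,
                   record_timeseries: bool = False) -> TrialResult:
    """Simulate a single trial.

    The trial's random stream is derived from ``protocol.seed``;
    identical protocol and parameters reproduce the result bit for bit.
    In noise-off mode (``sigma_noise = 0``) the trial is deterministic
    and the seed is ignored.
    """
    params = params or ModelParameters()
    seed = 0 if protocol.seed is None else protocol.seed
    gen = [np.random.Generator(np.random.PCG64(_spawn_trial_seed(seed, 0, 0)))]
    tie_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(0, 1))
    )
    right = np.array([protocol.correct_side == "right"])
    res = _simulate_batch(protocol.coherence, right, params, gen, tie_rng,
                          record=record_timeseries)
    return _to_result(res, 0, protocol, params, record_timeseries)


def _to_result(res, i, protocol, params, record) -> TrialResult:
    ds = int(res["decision_step"][i])
    crossed = ds >= 0
    responded = crossed and bool(res["resolved"][i])
    choice = None if not responded else ("left" if res["choice"][i] > 0 else "right")
    decision_time = ds * params.dt if crossed else None
    rt = decision_time - params.t_stim if responded else None
    nrev = int(res["n_reversals"][i])
    timeseries = None
    x_trace = None
    if record:
        tr = res["traces"][i, : int(res["end_step"][i])]
        timeseries = pd.DataFrame(tr, columns=_TRACE_COLUMNS)
        timeseries.insert(0, "t", np.arange(len(tr)) * params.dt + params.dt)
        x_trace = map_hand_to_x(tr[:, 5], tr[:, 6], params)
    return TrialResult(
        choice=choice,
        correct=None if not responded else choice == protocol.correct_side,
        response_time=rt,
        decision_time_raw=decision_time,
        is_com=nrev >= 1,
        n_reversals=nrev,
        peak_uncertainty=float(res["peak_uncertainty"][i]),
        protocol=protocol,
        timeseries=timeseries,
        x_trace=x_trace,
    )


def run_experiment(design, params: ModelParameters | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Simulate a full experiment and return one row per trial.

    Parameters
    ----------
    design : iterable of (coherence, n_trials)
        Stimulus conditions; the correct side is randomized per trial.
    params : ModelParameters, optional
    seed : int
        Master seed.  Per-trial noise streams are derived by a counter
        scheme (condition index, trial index), so every trial's stream
        is independent of how many trials run beside it.

    Returns
    -------
    pandas.DataFrame
        Columns: ``trial``, ``coherence``, ``correct_side``, ``choice``,
        ``correct``, ``response_time`` (ms from stimulus offset),
        ``decision_time_raw`` (first 42.5 Hz crossing, ms from onset),
        ``crossed``, ``motor_time``, ``non_decision``, ``is_com``,
        ``n_reversals``, ``com_excluded`` (more than one reversal),
        ``peak_uncertainty``.  A non-decision trial is one with no
        completed response by ``t_max`` — the decision threshold was
        never crossed or the motor race never reached the choice
        target; such trials are retained and flagged.  Provenance
        (seed, parameters) is stored in ``DataFrame.attrs``.
    """
    params = params or ModelParameters()
    frames = []
    trial_offset = 0
    for ci, (coherence, n_trials) in enumerate(design):
        n_trials = int(n_trials)
        if n_trials == 0:
            continue
        side_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(ci, 1 << 24))
        )
        tie_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(ci, (1 << 24) + 1))
        )
        right = side_rng.random(n_trials) < 0.5
        if params.sigma_noise > 0:
            gens = [np.random.Generator(np.random.PCG64(
                _spawn_trial_seed(seed, ci, ti))) for ti in range(n_trials)]
        else:
            gens = None
        res = _simulate_batch(float(coherence), right, params, gens, tie_rng)

        ds = res["decision_step"].astype(float)
        crossed = res["decision_step"] >= 0
        responded = crossed & res["resolved"]
        non_dec = ~responded
        decision_time = np.where(crossed, ds * params.dt, np.nan)
        choice = np.where(responded & (res["choice"] > 0), "left",
                          np.where(responded & (res["choice"] < 0),
                                   "right", None))
        correct_side = np.where(right, "right", "left")
        frames.append(pd.DataFrame({
            "trial": np.arange(trial_offset, trial_offset + n_trials),
            "coherence": coherence,
            "correct_side": correct_side,
            "choice": choice,
            "correct": np.where(non_dec, np.nan,
                                (choice == correct_side).astype(float)),
            "response_time": np.where(responded,
                                      decision_time - params.t_stim, np.nan),
            "decision_time_raw": decision_time,
            "crossed": crossed,
            "motor_time": res["end_step"] * params.dt,
            "non_decision": non_dec,
            "is_com": res["n_reversals"] >= 1,
            "n_reversals": res["n_reversals"],
            "com_excluded": res["n_reversals"] > 1,
            "peak_uncertainty": res["peak_uncertainty"],
        }))
        trial_offset += n_trials

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=[
            "trial", "coherence", "correct_side", "choice", "correct",
            "response_time", "decision_time_raw", "crossed", "motor_time",
            "non_decision", "is_com", "n_reversals", "com_excluded",
            "peak_uncertainty"])
    table.attrs["seed"] = seed
    table.attrs["parameters"] = params.to_dict()
    return table
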