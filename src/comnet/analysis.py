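"""Trial-level summary statistics of simulated experiments.

Operates on the experiment table returned by
:func:`comnet.simulate.run_experiment`.  All analyses exclude
non-decision trials; change-of-mind analyses additionally exclude trials
with more than one reversal, mirroring the experimental exclusion of
multi-change trials.  Summary curves report the group mean, the standard
error of the mean (sample s.d. / sqrt(n)) and the group size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "decided_trials",
    "peak_uncertainty",
    "minmax_normalize",
    "zscore_within",
    "pearson_r",
    "psychometric_by_com",
    "com_probability_by",
    "uncertainty_by_coherence_outcome",
    "uncertainty_rt_correlation",
]


def decided_trials(table: pd.DataFrame, drop_multi_com: bool = False) -> pd.DataFrame:
    """Trials with a completed response; optionally drop multi-reversal trials."""
    out = table[~table["non_decision"]]
    if drop_multi_com:
        out = out[~out["com_excluded"]]
    return out


def peak_uncertainty(trial) -> float:
    """Maximum uncertainty-population rate over a trial (Hz).

    Accepts a :class:`~comnet.simulate.TrialResult`; if a full time
    series was stored it is used, otherwise the streaming reduction
    recorded during integration.
    """
    if trial.timeseries is not None:
        return float(trial.timeseries["y_HU"].max())
    if trial.peak_uncertainty is None:
        raise ValueError("trial carries no uncertainty reduction")
    return float(trial.peak_uncertainty)


def minmax_normalize(values):
    """Min-max normalisation X' = (X - X_min) / (X_max - X_min).

    Maps the minimum to 0 and the maximum to 1, preserving order.
    Constant input is rejected (the transform would be undefined).
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise ValueError("min-max normalisation undefined for constant input")
    return (x - lo) / (hi - lo)


def zscore_within(values, groups):
    """Z-score values within each group (per participant / per run).

    Each group must contain at least two values with nonzero spread.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))

    def _z(v):
        if len(v) < 2 or v.std(ddof=1) == 0:
            raise ValueError("degenerate group in z-scoring")
        return (v - v.mean()) / v.std(ddof=1)

    return s.groupby(g.values).transform(_z).to_numpy()


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def _empty_curve(group_col: str) -> pd.DataFrame:
    return pd.DataFrame({group_col: pd.Series(dtype=float),
                         "mean": pd.Series(dtype=float),
                         "n": pd.Series(dtype=np.int64),
                         "sem": pd.Series(dtype=float)})


def _curve(frame: pd.DataFrame, group_col: str, value_col: str) -> pd.DataFrame:
    g = frame.groupby(group_col, observed=True)[value_col]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def psychometric_by_com(table: pd.DataFrame) -> pd.DataFrame:
    """Accuracy vs coherence, split by the change-of-mind flag.

    Excludes non-decision and multi-reversal trials.  Returns a tidy
    frame with columns ``is_com``, ``coherence``, ``mean``, ``n``,
    ``sem``; splits with no trials appear with n = 0.
    """
    d = decided_trials(table, drop_multi_com=True)
    rows = []
    for flag in (False, True):
        sub = d[d["is_com"] == flag]
        cur = (_curve(sub, "coherence", "correct") if len(sub)
               else _empty_curve("coherence"))
        cur.insert(0, "is_com", flag)
        rows.append(cur)
    return pd.concat(rows, ignore_index=True)


def _tertile_labels(values: pd.Series) -> pd.Series:
    """Tertile membership (0, 1, 2) by the 1/3 and 2/3 empirical quantiles."""
    q1, q2 = values.quantile([1 / 3, 2 / 3])
    return pd.Series(np.digitize(values, [q1, q2], right=False),
                     index=values.index)


def com_probability_by(table: pd.DataFrame, grouping: str = "coherence",
                       tertile_scope: str = "pooled") -> pd.DataFrame:
    """Probability of a change-of-mind per group.

    Parameters
    ----------
    grouping : {"coherence", "rt_tertile", "uncertainty_tertile"}
        Tertiles are the empirical 1/3 and 2/3 quantiles over decided
        trials; uncertainty tertiles are computed on min-max-normalized
        peak uncertainty.
    tertile_scope : {"pooled", "within_coherence"}
        Whether tertile boundaries are shared across the whole decided
        set or computed separately per coherence level.

    Returns
    -------
    Tidy frame with the grouping column(s), ``mean`` (the CoM
    probability), ``n`` and ``sem``.
    """
    d = decided_trials(table, drop_multi_com=True).copy()
    d["is_com"] = d["is_com"].astype(float)
    if grouping == "coherence":
        return _curve(d, "coherence", "is_com")
    if grouping == "rt_tertile":
        var = d["response_time"]
    elif grouping == "uncertainty_tertile":
        var = pd.Series(minmax_normalize(d["peak_uncertainty"]), index=d.index)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if tertile_scope == "within_coherence":
        if d.groupby("coherence").size().min() < 3:
            raise ValueError("fewer than 3 trials in a coherence condition")
        lab = var.groupby(d["coherence"]).transform(
            lambda v: _tertile_labels(v))
    elif tertile_scope == "pooled":
        if len(d) < 3:
            raise ValueError("fewer than 3 decided trials")
        lab = _tertile_labels(var)
    else:
        raise ValueError(f"unknown tertile_scope {tertile_scope!r}")
    d["tertile"] = lab
    out = d.groupby(["coherence", "tertile"], observed=True)["is_com"].agg(
        mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def uncertainty_by_coherence_outcome(table: pd.DataFrame,
                                     normalize: bool = True) -> pd.DataFrame:
    """Mean (normalized) peak uncertainty vs coherence by trial outcome.

    The '<' signature of decision uncertainty: the error-trial curve
    rises with coherence while the correct-trial curve falls.
    """
    d = decided_trials(table, drop_multi_com=True).copy()
    value = "peak_uncertainty"
    if normalize:
        d["uncertainty_norm"] = minmax_normalize(d["peak_uncertainty"])
        value = "uncertainty_norm"
    rows = []
    for outcome, label in ((1.0, "correct"), (0.0, "error")):
        sub = d[d["correct"] == outcome]
        cur = (_curve(sub, "coherence", value) if len(sub)
               else _empty_curve("coherence"))
        cur.insert(0, "outcome", label)
        rows.append(cur)
    return pd.concat(rows, ignore_index=True)


def uncertainty_rt_correlation(table: pd.DataFrame) -> tuple[float, int]:
    """Pearson r between peak uncertainty and response time.

    Pools all decided trials and discards trials with zero peak
    uncertainty (trials decided before the monitoring gate opened).
    Returns (r, number of trials used).
    """
    d = decided_trials(table)
    d = d[d["peak_uncertainty"] > 0]
    return pearson_r(d["peak_uncertainty"], d["response_time"]), len(d)
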