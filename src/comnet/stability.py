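"""Fixed-point and bifurcation analysis of the sensorimotor subsystem.

The two-variable deterministic subsystem (S_L, S_R) is analysed with the
uncertainty feedback term J_mc0 * y_HU replaced by a constant current
``feedback`` (nA) added to both population inputs, noise off and (by
default) stimulus off — the post-offset regime in which the transient
feedback governs the dynamics.  At low feedback the circuit is
winner-take-all: two
asymmetric stable states (the decision states) separated
by a symmetric saddle.  Increasing the feedback current merges the
decision states with the saddle in a fold, leaving a single symmetric
stable state that corresponds to indecision.  The critical feedback
magnitude of that collapse is located by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import dynamics
from .params import ModelParameters

__all__ = [
    "FixedPoint",
    "BifurcationBranch",
    "reduced_vector_field",
    "find_fixed_points",
    "bifurcation_scan",
    "locate_saddle_node",
]

RESIDUAL_TOL = 1e-10


@dataclass
class FixedPoint:
    """A steady state of the reduced (S_L, S_R) system."""

    S_L: float
    S_R: float
    stability: str  # "stable" | "saddle" | "unstable"
    eigenvalues: tuple[complex, complex]

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class BifurcationBranch:
    """Fixed points indexed by feedback magnitude, with detected folds."""

    feedback_grid: np.ndarray
    points: list[list[FixedPoint]]
    fold_points: list[float] = field(default_factory=list)

    def n_stable(self) -> np.ndarray:
        return np.array([sum(fp.is_stable for fp in fps) for fps in self.points])


def reduced_vector_field(S_L, S_R, feedback: float, coherence: float,
                         params: ModelParameters, stimulus_on: bool = False):
    """Noise-free drift of (S_L, S_R) with constant uncertainty feedback.

    The feedback current is added equally to both populations, mirroring
    the equal excitation the uncertainty population provides.  By
    default the stimulus current is off: the bifurcation structure
    describes the late-trial regime (after stimulus offset) in which the
    transient uncertainty feedback decides between winner-take-all and
    indecision, and in which changes-of-mind unfold.  Set
    ``stimulus_on=True`` to analyse the stimulus epoch instead.
    """
    p = params
    base = p.J_A_ext * p.mu_0 if stimulus_on else 0.0
    I_L = base * (1.0 - coherence)
    I_R = base * (1.0 + coherence)
    x_L = p.J_N_ii * S_L - p.J_N_ij * S_R + p.I_0 + I_L + feedback
    x_R = p.J_N_ii * S_R - p.J_N_ij * S_L + p.I_0 + I_R + feedback
    H_L = dynamics.io_gain(x_L, p)
    H_R = dynamics.io_gain(x_R, p)
    return dynamics.synaptic_drift(S_L, S_R, H_L, H_R, p)


def _jacobian(S_L, S_R, feedback, coherence, params, stimulus_on=False, h=1e-7):
    """Central-difference Jacobian of the reduced vector field."""
    J = np.empty((2, 2))
    for j, (dL, dR) in enumerate(((h, 0.0), (0.0, h))):
        fp = reduced_vector_field(S_L + dL, S_R + dR, feedback, coherence,
                                  params, stimulus_on)
        fm = reduced_vector_field(S_L - dL, S_R - dR, feedback, coherence,
                                  params, stimulus_on)
        J[0, j] = (fp[0] - fm[0]) / (2 * h)
        J[1, j] = (fp[1] - fm[1]) / (2 * h)
    return J


def _classify(eigenvalues) -> str:
    re = np.real(eigenvalues)
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points(feedback: float, coherence: float = 0.0,
                      params: ModelParameters | None = None,
                      grid_size: int = 200, dedupe_tol: float = 1e-6,
                      stimulus_on: bool = False) -> list[FixedPoint]:
    """Locate all fixed points of the reduced system in the unit square.

    Roots are seeded from every cell of a ``grid_size`` x ``grid_size``
    lattice on which both drift components change sign, refined with a
    Newton-hybrid root finder, validated against a residual bound of
    1e-10 and deduplicated.  Stability follows the real parts of the
    Jacobian eigenvalues.
    """
    if feedback < 0:
        raise ValueError("feedback must be nonnegative")
    params = params or ModelParameters()
    grid = np.linspace(0.0, 1.0, grid_size + 1)
    SL, SR = np.meshgrid(grid, grid, indexing="ij")
    F1, F2 = reduced_vector_field(SL, SR, feedback, coherence, params,
                                  stimulus_on)

    # cells whose corners change sign in both components
    def cell_sign_change(F):
        corners = np.stack([F[:-1, :-1], F[1:, :-1], F[:-1, 1:], F[1:, 1:]])
        return (corners.min(axis=0) <= 0) & (corners.max(axis=0) >= 0)

    cells = cell_sign_change(F1) & cell_sign_change(F2)
    ii, jj = np.nonzero(cells)
    seeds = np.stack([(grid[ii] + grid[ii + 1]) / 2,
                      (grid[jj] + grid[jj + 1]) / 2], axis=-1)

    roots: list[np.ndarray] = []
    for seed in seeds:
        sol = optimize.root(
            lambda s: np.array(reduced_vector_field(
                s[0], s[1], feedback, coherence, params, stimulus_on)),
            seed, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        s = sol.x
        if not (-1e-9 <= s[0] <= 1 + 1e-9 and -1e-9 <= s[1] <= 1 + 1e-9):
            continue
        res = reduced_vector_field(s[0], s[1], feedback, coherence, params,
                                   stimulus_on)
        if max(abs(res[0]), abs(res[1])) > RESIDUAL_TOL:
            continue
        if any(np.hypot(*(s - r)) < dedupe_tol for r in roots):
            continue
        roots.append(s)

    points = []
    for s in sorted(roots, key=lambda r: (r[0], r[1])):
        eig = np.linalg.eigvals(
            _jacobian(s[0], s[1], feedback, coherence, params, stimulus_on))
        points.append(FixedPoint(float(s[0]), float(s[1]),
                                 _classify(eig), (complex(eig[0]), complex(eig[1]))))
    return points


def bifurcation_scan(feedback_grid, params: ModelParameters | None = None,
                     coherence: float = 0.0, grid_size: int = 200
                     ) -> BifurcationBranch:
    """Fixed points along an ascending grid of feedback currents.

    Fold (saddle-node) points are reported at the midpoint of every grid
    interval across which the number of stable fixed points changes.
    """
    feedback_grid = np.asarray(feedback_grid, dtype=float)
    if feedback_grid.size and np.any(np.diff(feedback_grid) < 0):
        raise ValueError("feedback grid must be sorted ascending")
    params = params or ModelParameters()
    points = [find_fixed_points(f, coherence, params, grid_size=grid_size)
              for f in feedback_grid]
    branch = BifurcationBranch(feedback_grid, points)
    ns = branch.n_stable()
    for k in range(len(ns) - 1):
        if ns[k] != ns[k + 1]:
            branch.fold_points.append(
                float((feedback_grid[k] + feedback_grid[k + 1]) / 2))
    return branch


def locate_saddle_node(params: ModelParameters | None = None,
                       coherence: float = 0.0,
                       bracket: tuple[float, float] = (0.0, 0.1),
                       tolerance: float = 1e-4, grid_size: int = 200
                       ) -> float:
    """Critical feedback current at which bistability collapses (nA).

    Bisects on the predicate "more than one stable fixed point" between
    the bracket endpoints.  Fails loudly if the endpoints do not differ
    in that predicate.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    params = params or ModelParameters()

    def bistable(f):
        pts = find_fixed_points(f, coherence, params, grid_size=grid_size)
        return sum(fp.is_stable for fp in pts) > 1

    lo, hi = bracket
    b_lo, b_hi = bistable(lo), bistable(hi)
    if b_lo == b_hi:
        raise ValueError(
            f"bracket endpoints {bracket} do not straddle the fold: "
            f"bistable(lo)={b_lo}, bistable(hi)={b_hi}")
    while hi - lo > tolerance:
        mid = (lo + hi) / 2
        if bistable(mid) == b_lo:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
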