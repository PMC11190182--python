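"""Full first-passage-time distributions by time integration.

Deleting the rows and columns of the absorbing set ``Y`` from the CME
generator ``A`` (no transpose) gives the reduced system
``d_t P = A_Y P`` over the transient states; its solution from an initial
distribution loses probability exactly at the rate the process is
absorbed.  The survival function of the FPT is then
``S(t) = sum_transient P(t)`` and the density is ``-dS/dt``.

Note that the finite state projection makes leaving the truncation
indistinguishable from absorption in ``Y``, so ``S`` is (slightly) biased
low whenever the truncation leaks; the leak rate is available separately
from :func:`fptcme.statespace.column_defect`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .solver import TargetSet, fpt_moments
from .statespace import StateSpace

__all__ = ["SurvivalCurve", "fpt_survival", "fpt_density"]


@dataclass
class SurvivalCurve:
    """``S(t) = P(FPT > t)`` on a time grid, for a fixed initial condition."""

    time_grid: np.ndarray
    survival: np.ndarray
    initial_condition: np.ndarray  # distribution over the full state space

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)


def default_time_grid(t_max: float, n: int = 400) -> np.ndarray:
    """Grid that resolves both the early transient and the exponential tail:
    log-spaced points up to ``t_max/10`` followed by linear spacing."""
    n_log = n // 4
    log_part = np.geomspace(t_max * 1e-4, t_max / 10.0, n_log)
    lin_part = np.linspace(t_max / 10.0, t_max, n - n_log - 1, endpoint=True)[1:]
    return np.concatenate([[0.0], log_part, lin_part])


def _initial_vector(space: StateSpace, initial) -> np.ndarray:
    initial = np.asarray(initial)
    if initial.ndim == 1 and initial.size == space.n_species:
        p0 = np.zeros(space.n_states)
        p0[space.index_of(initial)] = 1.0
        return p0
    if initial.shape == (space.n_states,):
        p0 = np.asarray(initial, dtype=float)
        if p0.min() < 0 or not np.isclose(p0.sum(), 1.0):
            raise ValueError("initial distribution must be a probability vector")
        return p0
    raise ValueError(
        "initial must be a state vector or a distribution over the state space"
    )


def fpt_survival(
    A: sp.spmatrix,
    space: StateSpace,
    target: TargetSet,
    initial,
    time_grid: np.ndarray | None = None,
    t_max: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SurvivalCurve:
    """Integrate the Y-reduced master equation and return the survival curve.

    Parameters
    ----------
    initial
        Either an integer state vector (point mass) or a probability
        distribution over the full state space; all mass must lie on
        transient states.
    time_grid, t_max
        Explicit grid, or none — then ``t_max`` defaults to 10x the
        slowest mean FPT reachable from the initial condition and the grid
        to 400 points (log-then-linear).

    The integrator is stiff-capable (BDF with the sparse reduced generator
    as Jacobian), since gene-switching models mix well-separated rates.
    """
    y_mask = target.mask(space)
    p0_full = _initial_vector(space, initial)
    if p0_full[y_mask].sum() > 0:
        raise ValueError("initial probability mass lies inside the target set Y")
    keep = np.nonzero(~y_mask)[0]
    A_Y = sp.csc_matrix(A)[np.ix_(keep, keep)].tocsc()
    p0 = p0_full[keep]

    if time_grid is None:
        if t_max is None:
            moments = fpt_moments(A, space, target, k_max=1)
            support = moments.mean[p0 > 0]
            t_max = 10.0 * float(support.max())
        time_grid = default_time_grid(float(t_max))
    time_grid = np.asarray(time_grid, dtype=float)

    sol = solve_ivp(
        lambda t, p: A_Y @ p,
        (time_grid[0], time_grid[-1]),
        p0,
        method="BDF",
        jac=lambda t, p: A_Y,
        t_eval=time_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"survival integration failed: {sol.message}")
    S = sol.y.sum(axis=0)
    # integration noise tolerance: allow tiny non-monotonicity, reject gross
    increments = np.diff(S)
    if increments.max(initial=0.0) > 100 * max(atol * len(keep), rtol):
        raise RuntimeError(
            f"survival curve is non-monotone beyond tolerance "
            f"(max increment {increments.max():.3e})"
        )
    S = np.minimum.accumulate(np.clip(S, 0.0, 1.0))
    return SurvivalCurve(time_grid=time_grid, survival=S, initial_condition=p0_full)


def fpt_density(curve: SurvivalCurve) -> np.ndarray:
    """FPT probability density ``-dS/dt`` by central differences.

    Nonnegative up to differencing noise; its trapezoidal integral equals
    ``1 - S(t_max)`` up to the same noise.
    """
    return -np.gradient(curve.survival, curve.time_grid)
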