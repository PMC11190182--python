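"""Mean-field reaction-rate equations and deterministic threshold crossing.

The deterministic counterpart of a stochastic reaction network is the
reaction-rate equation (RRE) ``d_tau X = sum_j v_j abar_j(X)``, where the
mean-field rate ``abar_j`` replaces the combinatorial count of reactant
molecules by the product of continuous copy numbers (``x -> X``,
``x*y -> X*Y``, ``binom(x,2) -> X^2/2``).  Binary gene-state species
become continuous occupancies in ``[0, 1]``.

The deterministic first-passage time ``tau_d`` is the first time the RRE
trajectory crosses a threshold level; for the simple birth-death process
with target a fraction ``rho`` of the steady-state mean this has the
closed form ``tau_d = -ln(1 - rho)``, independent of the production rate.
A threshold at or above the steady state is never crossed in finite time
and is reported as unreachable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .network import ReactionNetwork

__all__ = [
    "RateEquationSystem",
    "DeterministicFPT",
    "rre_from_network",
    "deterministic_fpt",
    "steady_state",
    "telegraph_piecewise_f",
    "telegraph_piecewise_mfpt",
    "PiecewiseValidityError",
]


class PiecewiseValidityError(ValueError):
    """The piecewise-deterministic telegraph approximation was evaluated
    outside its window of validity ``[0, tau_off]``."""


@dataclass
class RateEquationSystem:
    """Mean-field ODE system ``d_tau X = rhs(X)`` with named components."""

    rhs: Callable[[float, np.ndarray], np.ndarray]
    initial_condition: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.initial_condition = np.asarray(self.initial_condition, dtype=float)

    def index(self, species: str | int) -> int:
        if isinstance(species, str):
            return self.labels.index(species)
        return int(species)


@dataclass
class DeterministicFPT:
    """Deterministic threshold-crossing result.

    ``status`` is ``"crossed"`` (``tau_d`` finite), ``"unreachable"``
    (trajectory confirmed to stay below the level with non-positive
    approach slope by ``t_max``), or an inconclusive run raises instead.
    """

    tau_d: float
    status: str
    species: str | int
    level: float

    @property
    def reachable(self) -> bool:
        return self.status == "crossed"


def rre_from_network(
    network: ReactionNetwork, initial_condition=None
) -> RateEquationSystem:
    """Mean-field limit of a stochastic network.

    Mass-action reactions translate automatically; a ``custom``-propensity
    reaction must carry a registered ``mean_field_fn`` or an error is
    raised.
    """
    for r in network.reactions:
        if r.propensity_kind == "custom" and r.mean_field_fn is None:
            raise ValueError(
                f"reaction {r.label or r.net_change} has a custom propensity "
                "without a mean-field override; cannot form rate equations"
            )
    V = network.stoichiometry().T.astype(float)  # (n_species, n_reactions)
    reactions = list(network.reactions)

    def rhs(t: float, X: np.ndarray) -> np.ndarray:
        rates = np.empty(len(reactions))
        for j, r in enumerate(reactions):
            if r.mean_field_fn is not None:
                rates[j] = r.mean_field_fn(X)
            else:
                a = r.rate_constant
                for i in np.nonzero(r.reactant_stoich)[0]:
                    s = int(r.reactant_stoich[i])
                    a *= X[i] ** s / math.factorial(s)
                rates[j] = a
        return V @ rates

    if initial_condition is None:
        initial_condition = np.zeros(network.n_species)
    return RateEquationSystem(
        rhs=rhs,
        initial_condition=initial_condition,
        labels=network.species_names,
    )


def deterministic_fpt(
    system: RateEquationSystem,
    species: str | int,
    level: float,
    t_max: float = 200.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> DeterministicFPT:
    """First upcrossing time of ``X[species] = level`` along the RRE.

    Integrates with a terminal upcrossing event and refines the root to
    ``|X(tau) - level| < 1e-9 * level``.  If no crossing occurs by
    ``t_max``, the trajectory must be confirmed below the level and
    approaching it with non-positive slope (relative to its distance) to
    be declared unreachable; anything else raises an inconclusive error.
    """
    idx = system.index(species)
    x0 = system.initial_condition
    if x0[idx] >= level:
        raise ValueError("initial value already at or above the threshold level")

    def event(t, X):
        return X[idx] - level

    event.terminal = True
    event.direction = 1.0

    sol = solve_ivp(
        system.rhs,
        (0.0, t_max),
        x0,
        method="LSODA",
        events=event,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"RRE integration failed: {sol.message}")
    if sol.t_events[0].size:
        tau = float(sol.t_events[0][0])
        # an "event" with vanishing slope is asymptotic contact with the
        # level (threshold exactly at a fixed point), not a crossing
        slope_at_tau = system.rhs(tau, sol.sol(tau))[idx]
        if slope_at_tau <= 1e-9 * max(abs(level), 1.0):
            return DeterministicFPT(
                tau_d=math.inf, status="unreachable", species=species, level=level
            )
        # polish the root on the dense output
        f = lambda t: sol.sol(t)[idx] - level
        lo = max(0.0, tau - 1e-6 * max(tau, 1.0))
        hi = min(t_max, tau + 1e-6 * max(tau, 1.0))
        if f(lo) < 0 < f(hi):
            tau = brentq(f, lo, hi, xtol=1e-12 * max(level, 1.0))
        return DeterministicFPT(
            tau_d=float(tau), status="crossed", species=species, level=level
        )
    # No crossing by t_max.  Unreachable only if the trajectory has settled
    # onto a fixed point at or below the level (asymptotic approach);
    # a still-moving trajectory is inconclusive, not unreachable.
    x_end = sol.y[:, -1]
    slope = system.rhs(sol.t[-1], x_end)[idx]
    gap = level - x_end[idx]
    scale = max(abs(level), np.abs(x_end).max(), 1.0)
    settled = np.abs(system.rhs(sol.t[-1], x_end)).max() < 1e-8 * scale
    if settled and gap >= -1e-9 * scale and slope <= max(gap, 0.0) + 1e-12 * scale:
        return DeterministicFPT(
            tau_d=math.inf, status="unreachable", species=species, level=level
        )
    raise RuntimeError(
        f"no crossing by t_max={t_max} but the trajectory has not settled "
        f"below the level (gap {gap:.3e}, slope {slope:.3e}); increase t_max"
    )


def steady_state(
    system: RateEquationSystem, t_settle: float = 400.0, rtol: float = 1e-12
) -> np.ndarray:
    """Asymptotic fixed point of the RRE from its initial condition.

    Integrates to ``t_settle`` and polishes with a Newton solve of
    ``rhs(X) = 0`` seeded from the endpoint.
    """
    from scipy.optimize import fsolve

    sol = solve_ivp(
        system.rhs,
        (0.0, t_settle),
        system.initial_condition,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
    )
    x_end = sol.y[:, -1]
    root, info, ier, _ = fsolve(
        lambda X: system.rhs(0.0, X), x_end, full_output=True, xtol=1e-13
    )
    return root if ier == 1 else x_end


# ---------------------------------------------------------------------------
# Piecewise-deterministic approximation of the telegraph model
# ---------------------------------------------------------------------------


def telegraph_piecewise_f(
    lambda_on: float, mu_off: float, K: float, tau: float
) -> float:
    """Approximate mRNA level for the telegraph model, valid on one
    on/off gene cycle ``0 <= tau <= tau_off = 1/lambda + 1/mu``.

    The gene is off for the mean activation waiting time ``1/lambda``
    (no expression), then mRNA relaxes deterministically towards ``K``:
    zero for ``tau <= 1/lambda`` and ``K(1 - exp(-(tau - 1/lambda)))``
    afterwards — a sudden linear rise of slope ``K`` just after switch-on.
    """
    tau_off = 1.0 / lambda_on + 1.0 / mu_off
    if tau < 0 or tau > tau_off:
        raise PiecewiseValidityError(
            f"tau={tau:g} outside the validity window [0, {tau_off:g}]"
        )
    if tau <= 1.0 / lambda_on:
        return 0.0
    return K * (1.0 - math.exp(-(tau - 1.0 / lambda_on)))


def telegraph_piecewise_mfpt(
    lambda_on: float, mu_off: float, K: float, N: float
) -> float:
    """Approximate telegraph MFPT by inverting the piecewise mRNA rise:
    ``1/lambda - ln(1 - N/K)``.

    The activation waiting time ``1/lambda`` is a strict lower bound for
    any positive target.  The inversion is refused when the crossing falls
    outside ``[0, tau_off]`` — at intermediate switching rates a fraction
    of trajectories fails to reach the target within one gene cycle and
    the approximation breaks down.
    """
    if N >= K:
        raise PiecewiseValidityError(
            f"target N={N:g} is not below the active-state asymptote K={K:g}"
        )
    if N < 0:
        raise ValueError("N must be nonnegative")
    tau = 1.0 / lambda_on - math.log(1.0 - N / K)
    tau_off = 1.0 / lambda_on + 1.0 / mu_off
    if tau > tau_off:
        raise PiecewiseValidityError(
            f"crossing time {tau:g} exceeds tau_off={tau_off:g}; the "
            "single-cycle approximation is invalid for these parameters"
        )
    return tau
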