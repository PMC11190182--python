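"""Exact stochastic simulation (Gillespie direct method).

Serves as the independent Monte-Carlo oracle for the finite-state-
projection solvers: :func:`ssa_trajectory` generates single trajectories,
:func:`ssa_fpt_sample` estimates first-passage times to a target set by
simulating many independent chains.

Sampling is exact (direct method — exponential dwell at the total
propensity, channel chosen proportionally to its propensity; no
tau-leaping) and the target check happens after every jump, so the
reach-or-exceed overshoot semantics match the linear-algebra solver.

Reproducibility: chains are simulated in fixed-width chunks of 1024;
chunk ``c`` draws from ``numpy`` streams seeded with
``SeedSequence([seed, c])``, and partial chunks are simulated at full
width and trimmed.  Sample ``i`` therefore never changes when
``n_samples`` grows or shrinks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork
from .solver import TargetSet

__all__ = ["Trajectory", "FPTSample", "ssa_trajectory", "ssa_fpt_sample"]

CHUNK = 1024


@dataclass
class Trajectory:
    """One SSA realization: states after each jump, with jump times."""

    jump_times: np.ndarray
    states: np.ndarray  # (n_jumps + 1, n_species), row 0 = initial state
    seed: int
    absorbed: bool = False  # ended in a state with zero total propensity


@dataclass
class FPTSample:
    """Monte-Carlo FPT estimate from independent SSA chains."""

    samples: np.ndarray
    n_samples: int
    seed: int
    n_censored: int = 0
    t_cap: float = math.inf
    warnings_: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def standard_error(self) -> float:
        return float(self.samples.std(ddof=1) / math.sqrt(self.samples.size))


def ssa_trajectory(
    network: ReactionNetwork, x0, t_max: float, seed: int
) -> Trajectory:
    """Simulate one trajectory of the direct method until ``t_max``.

    If the chain reaches a state in which every propensity vanishes, the
    trajectory ends there and is flagged ``absorbed``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    V = network.stoichiometry()
    state = np.asarray(x0, dtype=np.int64).copy()
    network._check_state(state)
    t = 0.0
    times = [0.0]
    states = [state.copy()]
    while True:
        a = network.propensity_matrix(state[None, :])[0]
        a0 = a.sum()
        if a0 <= 0.0:
            return Trajectory(
                jump_times=np.array(times),
                states=np.array(states),
                seed=seed,
                absorbed=True,
            )
        t += rng.exponential(1.0 / a0)
        if t > t_max:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a0), side="right"))
        j = min(j, len(a) - 1)
        state = state + V[j]
        times.append(t)
        states.append(state.copy())
    return Trajectory(
        jump_times=np.array(times), states=np.array(states), seed=seed
    )


def time_average(traj: Trajectory, t_max: float, species: int = 0) -> float:
    """Time-averaged copy number of one species over ``[0, t_max]``."""
    t = np.append(traj.jump_times, t_max)
    dt = np.diff(t)
    return float(np.dot(dt, traj.states[: dt.size, species]) / t_max)


def ssa_fpt_sample(
    network: ReactionNetwork,
    x0,
    target: TargetSet,
    n_samples: int,
    seed: int,
    t_cap: float = 1000.0,
) -> FPTSample:
    """Estimate the FPT distribution to ``target`` by Monte Carlo.

    Chains that have not reached the target by ``t_cap`` (including
    chains stuck in a zero-propensity state) are censored at ``t_cap``; a
    censoring fraction above 1% attaches a warning to the result, since
    it biases the mean estimate low.
    """
    target = target.resolve(network)
    x0 = np.asarray(x0, dtype=np.int64)
    network._check_state(x0)
    if bool(np.asarray(target.predicate(x0[None, :]))[0]):
        raise ValueError("initial state already lies in the target set")
    V = network.stoichiometry()
    # constant-propensity channels (zeroth-order mass action, e.g. the
    # burst family of the geometric model) are filled once per chunk
    const_cols = np.array(
        [
            j
            for j, r in enumerate(network.reactions)
            if r.propensity_kind == "mass_action" and not r.reactant_stoich.any()
        ],
        dtype=np.intp,
    )
    const_vals = np.array(
        [network.reactions[j].rate_constant for j in const_cols]
    )
    varying_cols = np.array(
        [j for j in range(network.n_reactions) if j not in set(const_cols.tolist())],
        dtype=np.intp,
    )

    def propensities(state: np.ndarray, A: np.ndarray) -> np.ndarray:
        for j in varying_cols:
            r = network.reactions[j]
            if r.propensity_kind == "custom":
                A[:, j] = np.asarray(r.propensity_fn(state), dtype=np.float64)
            else:
                a = np.full(state.shape[0], r.rate_constant)
                for i in np.nonzero(r.reactant_stoich)[0]:
                    from .network import _combinations

                    a *= _combinations(state[:, i], int(r.reactant_stoich[i]))
                A[:, j] = a
        return A

    n_chunks = math.ceil(n_samples / CHUNK)
    all_samples = []
    n_censored = 0
    for c in range(n_chunks):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        t = np.zeros(CHUNK)
        state = np.tile(x0, (CHUNK, 1))
        fpt = np.full(CHUNK, np.nan)
        active = np.ones(CHUNK, dtype=bool)
        A = np.empty((CHUNK, network.n_reactions))
        A[:, const_cols] = const_vals
        while active.any():
            A = propensities(state, A)
            a0 = A.sum(axis=1)
            stuck = active & (a0 <= 0.0)
            if stuck.any():  # absorbing state without target: censor
                fpt[stuck] = t_cap
                active &= ~stuck
            u_dwell = rng.random(CHUNK)
            u_choice = rng.random(CHUNK)
            with np.errstate(divide="ignore"):
                dt = -np.log1p(-u_dwell) / a0
            step = active & np.isfinite(dt)
            t = np.where(step, t + dt, t)
            timed_out = step & (t > t_cap)
            if timed_out.any():
                fpt[timed_out] = t_cap
                active &= ~timed_out
                step &= ~timed_out
            # choose reaction channel proportionally to propensity
            cum = np.cumsum(A, axis=1)
            r = (u_choice * a0)[:, None]
            j = (cum < r).sum(axis=1)
            j = np.minimum(j, A.shape[1] - 1)
            state = np.where(step[:, None], state + V[j], state)
            arrived = step & np.asarray(target.predicate(state), dtype=bool)
            if arrived.any():
                fpt[arrived] = t[arrived]
                active &= ~arrived
        censored = fpt >= t_cap
        n_censored += int(censored.sum())
        all_samples.append(fpt)
    samples = np.concatenate(all_samples)[:n_samples]
    n_censored = int((samples >= t_cap).sum())
    result = FPTSample(
        samples=samples,
        n_samples=n_samples,
        seed=seed,
        n_censored=n_censored,
        t_cap=t_cap,
    )
    if n_censored > 0.01 * n_samples:
        msg = (
            f"{n_censored}/{n_samples} chains censored at t_cap={t_cap:g}; "
            "the FPT mean is biased low"
        )
        result.warnings_.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return result
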