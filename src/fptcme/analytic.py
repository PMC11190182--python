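"""Closed-form first-passage-time results for birth-death processes.

For the simple birth-death process (production at constant rate ``K``,
unit-rate degradation; time nondimensionalized by the degradation rate)
the mean FPT from ``n`` to ``N >= n`` molecules is the double
falling-factorial sum

    <tau_n> = (1/K) [ sum_{i=0}^{N-1} N^(i+1)_ / (i+1) K^{-i}
                      - sum_{i=0}^{n-1} n^(i+1)_ / (i+1) K^{-i} ],

with ``x^m_`` the falling factorial ``x(x-1)...(x-m+1)``.  The
deterministic counterpart, the time for ``d_tau X = K - X`` from zero to
reach a fraction ``rho`` of the steady state ``K``, is
``tau_d = -ln(1 - rho)`` independent of ``K``; term-by-term comparison
(the stochastic sum is a truncated, falling-factorial-damped Taylor
series of ``-ln(1-rho)``) proves ``<tau_0> < tau_d`` strictly, i.e. for
constitutive expression intrinsic noise always *shortens* the mean time
to threshold.

For bursty production in fixed bursts of ``r > 1``, the deterministic
route wins instead whenever the target lies below
``K r (1 - e^{-1/K}) ~ r`` — below the burst size the stochastic waiting
time saturates at the first-event time ``1/K``.
"""

from __future__ import annotations

import math

__all__ = [
    "mfpt_birth_death_closed_form",
    "deterministic_fpt_closed_form",
    "taylor_partial_sum",
    "bursty_regime_boundary",
    "steady_state_mean",
    "target_from_fraction",
]


def _bd_sum(m: int, K: float) -> float:
    """``sum_{i=0}^{m-1} m^(i+1)_/(i+1) * K^{-i}`` by stable term recursion.

    Every term is positive (the falling factorial of ``m`` is positive for
    order up to ``m``), so the sum has no cancellation; each term follows
    from the previous via ``t_i = t_{i-1} * (m-i)/K * i/(i+1)``.
    """
    if m == 0:
        return 0.0
    term = float(m)  # i = 0: m^(1)_/1
    total = term
    for i in range(1, m):
        term *= (m - i) / K * (i / (i + 1))
        total += term
    return total


def mfpt_birth_death_closed_form(K: float, N: int, n: int = 0) -> float:
    """Mean FPT of the simple birth-death process from ``n`` to ``N``.

    Parameters
    ----------
    K : float
        Production rate (equals the steady-state mean, since the
        degradation rate is 1).
    N : int
        Target copy number (threshold), ``N >= 1``.
    n : int
        Initial copy number, ``0 <= n <= N``.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    return (_bd_sum(N, K) - _bd_sum(n, K)) / K


def deterministic_fpt_closed_form(rho: float) -> float:
    """Deterministic time to reach a fraction ``rho`` of the steady-state
    mean for constitutive production: ``-ln(1 - rho)``, independent of the
    production rate."""
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly between 0 and 1")
    return -math.log1p(-rho)


def taylor_partial_sum(rho: float, N: int) -> float:
    """``sum_{i=0}^{N-1} rho^{i+1}/(i+1)``: the ``N``-term truncation of the
    Taylor series of ``-ln(1-rho)``.

    It upper-bounds the stochastic mean FPT (replace each falling
    factorial by its power bound) and lower-bounds the deterministic time
    strictly, which proves the deterministic time is a strict upper bound
    on the stochastic mean for every ``0 < rho < 1``.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly between 0 and 1")
    if N < 1:
        raise ValueError("N must be >= 1")
    term = rho
    total = term
    for i in range(1, N):
        term *= rho * i / (i + 1)
        total += term
    return total


def bursty_regime_boundary(K: float, r: int) -> float:
    """Target level below which the deterministic model beats the
    stochastic mean for fixed-burst production: ``K r (1 - e^{-1/K})``.

    For large ``K`` this approaches the burst size ``r``; for ``r = 1`` it
    is strictly below 1, so no integer target qualifies and the
    deterministic time is always the slower one.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if r < 1:
        raise ValueError("r must be >= 1")
    return K * r * -math.expm1(-1.0 / K)


def steady_state_mean(model_id: str, **params) -> float:
    """Closed-form steady-state mean copy number of the thresholded species.

    ``simple_bd``: ``K``; ``bursty_bd``: ``K*r``; ``bursty_geometric``:
    ``K*b``; ``telegraph``: ``K*lambda/(lambda+mu)``.  The feedback model
    has no closed form here — use the numerical RRE fixed point via its
    model bundle.
    """
    if model_id == "simple_bd":
        return float(params["K"])
    if model_id == "bursty_bd":
        return float(params["K"]) * float(params["r"])
    if model_id == "bursty_geometric":
        return float(params["K"]) * float(params["b"])
    if model_id == "telegraph":
        lam, mu = float(params["lambda_on"]), float(params["mu_off"])
        return float(params["K"]) * lam / (lam + mu)
    raise ValueError(
        f"no closed-form steady-state mean for {model_id!r} "
        "(feedback means are computed numerically from the rate equations)"
    )


def target_from_fraction(mean: float, rho: float) -> int:
    """Integer threshold ``N = floor(rho * mean)``; must be >= 1."""
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly between 0 and 1")
    if mean <= 0:
        raise ValueError("mean must be positive")
    N = math.floor(rho * mean)
    if N < 1:
        raise ValueError(
            f"floor(rho * mean) = {N}: no nontrivial integer target exists"
        )
    return N
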