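"""Canonical gene-expression model families.

Each constructor returns a :class:`ModelBundle` pairing the stochastic
reaction network with its mean-field rate equations, the species whose
copy number is thresholded, matched default initial conditions, and the
steady-state mean (closed form where one exists, otherwise the numerical
RRE fixed point).

All models use nondimensional time: every rate is expressed in units of
the degradation rate, which is therefore 1.

Families
--------
``simple_bd(K)``
    Constitutive production at rate ``K``, unit-rate degradation.
``bursty_bd(K, r)``
    Production in fixed bursts of ``r`` molecules at burst frequency ``K``.
``bursty_bd_geometric(K, b)``
    Burst sizes geometrically distributed on {1, 2, ...} with mean ``b``
    (a burst of size zero would be unobservable in a first-passage
    problem, so the support excludes it).
``telegraph(lambda_on, mu_off, K)``
    Two-state gene: activation ``lambda_on``, inactivation ``mu_off``,
    transcription at ``K`` only while active, unit-rate mRNA decay.  The
    gene is one binary species (1 = active); the inactive state is the
    implicit complement.
``feedback(rho_u, rho_b, sigma_b, sigma_u)``
    Autoregulation: protein binds its own promoter (rate ``sigma_b``,
    consuming one free protein), unbinds at ``sigma_u`` (releasing it),
    and is produced at ``rho_u``/``rho_b`` in the unbound/bound gene state
    (positive feedback iff ``rho_b > rho_u``).  The threshold counts
    *free* protein.  The gene is one binary species (1 = unbound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import analytic
from .deterministic import RateEquationSystem, rre_from_network, steady_state
from .network import Reaction, ReactionNetwork, SpeciesSpec
from .solver import TargetSet

__all__ = [
    "ModelBundle",
    "simple_bd",
    "bursty_bd",
    "bursty_bd_geometric",
    "telegraph",
    "feedback",
    "MODEL_REGISTRY",
    "make_model",
]


@dataclass
class ModelBundle:
    """A stochastic network with its deterministic twin and metadata."""

    name: str
    network: ReactionNetwork
    params: dict
    threshold_species: str
    default_initial_state: np.ndarray
    default_rho: float
    _closed_form_mean: float | None = None
    _rre_initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.default_initial_state = np.asarray(
            self.default_initial_state, dtype=np.int64
        )

    def rre(self) -> RateEquationSystem:
        """Mean-field rate equations with matched initial conditions."""
        x0 = (
            self._rre_initial
            if self._rre_initial is not None
            else self.default_initial_state.astype(float)
        )
        return rre_from_network(self.network, initial_condition=x0)

    def steady_state_mean(self) -> float:
        """Steady-state mean of the thresholded species (closed form if
        available, else the numerical RRE fixed point)."""
        if self._closed_form_mean is not None:
            return self._closed_form_mean
        ss = steady_state(self.rre())
        return float(ss[self.network.species_index(self.threshold_species)])

    def target(self, rho: float | None = None) -> tuple[TargetSet, int]:
        """Threshold target at ``N = floor(rho * steady-state mean)``."""
        rho = self.default_rho if rho is None else rho
        N = analytic.target_from_fraction(self.steady_state_mean(), rho)
        idx = self.network.species_index(self.threshold_species)
        return TargetSet.threshold(idx, N), N

    def with_bound(self, species: str, max_count: int) -> "ModelBundle":
        """Copy of the bundle with one species' truncation bound replaced."""
        new_species = [
            SpeciesSpec(sp.name, sp.index, max_count if sp.name == species else sp.max_count)
            for sp in self.network.species
        ]
        net = ReactionNetwork(new_species, self.network.reactions, self.network.name)
        return ModelBundle(
            self.name,
            net,
            self.params,
            self.threshold_species,
            self.default_initial_state,
            self.default_rho,
            self._closed_form_mean,
            self._rre_initial,
        )


def _default_bound(mean: float, rho: float, max_burst: int) -> int:
    """Truncation heuristic: generous headroom above both the target and
    the steady-state mean — max(N + 10 * burst, 4 * mean)."""
    N = max(1, math.floor(rho * mean))
    return int(math.ceil(max(N + 10 * max_burst, 4.0 * mean)))


def bursty_bd(K: float = 20.0, r: int = 10, rho: float = 0.9) -> ModelBundle:
    """Fixed-burst birth-death process: ``0 -> rP`` at rate ``K``, unit decay."""
    if K <= 0 or r < 1:
        raise ValueError("need K > 0 and integer r >= 1")
    mean = K * r
    bound = _default_bound(mean, rho, r)
    P = SpeciesSpec("P", 0, bound)
    burst = Reaction([0], [r], K, label=f"0 -> {r} P")
    decay = Reaction([1], [0], 1.0, label="P -> 0")
    net = ReactionNetwork([P], [burst, decay], name=f"bursty_bd(K={K:g}, r={r})")
    return ModelBundle(
        name="bursty_bd" if r > 1 else "simple_bd",
        network=net,
        params={"K": K, "r": r, "delta": 1.0},
        threshold_species="P",
        default_initial_state=[0],
        default_rho=rho,
        _closed_form_mean=mean,
    )


def simple_bd(K: float = 50.0, rho: float = 0.8) -> ModelBundle:
    """Simple birth-death process (bursty model with ``r = 1``)."""
    return bursty_bd(K=K, r=1, rho=rho)


def bursty_bd_geometric(
    K: float = 20.0, b: float = 10.0, rho: float = 0.9, tail_mass: float = 1e-13
) -> ModelBundle:
    """Birth-death with geometric burst sizes on {1, 2, ...}, mean ``b``.

    The burst-size family ``P(size = k) = (1/b)(1 - 1/b)^{k-1}`` is
    truncated at the smallest ``k_max`` with tail mass below
    ``tail_mass``; the tail probability is lumped onto ``k_max`` so the
    total burst frequency is exactly ``K``.  ``b <= 1`` degenerates to
    all bursts of size 1 (the simple birth-death process).
    """
    if K <= 0 or b <= 0:
        raise ValueError("need K > 0 and b > 0")
    if b <= 1.0:
        sizes, probs = np.array([1]), np.array([1.0])
    else:
        q = 1.0 - 1.0 / b
        k_max = max(1, math.ceil(math.log(tail_mass) / math.log(q)))
        sizes = np.arange(1, k_max + 1)
        probs = (1.0 / b) * q ** (sizes - 1.0)
        probs[-1] += q**k_max  # lump the tail onto the largest burst
    mean = K * b
    bound = _default_bound(mean, rho, int(sizes[-1]))
    P = SpeciesSpec("P", 0, bound)
    reactions = [
        Reaction([0], [int(k)], K * p, label=f"0 -> {int(k)} P")
        for k, p in zip(sizes, probs)
    ]
    reactions.append(Reaction([1], [0], 1.0, label="P -> 0"))
    net = ReactionNetwork(
        [P], reactions, name=f"bursty_geom(K={K:g}, b={b:g})"
    )
    bundle = ModelBundle(
        name="bursty_geom",
        network=net,
        params={"K": K, "b": b, "delta": 1.0},
        threshold_species="P",
        default_initial_state=[0],
        default_rho=rho,
        _closed_form_mean=K * float(np.dot(sizes, probs)),
    )
    bundle.burst_sizes = sizes
    bundle.burst_probs = probs
    return bundle


def telegraph(
    lambda_on: float = 2.0,
    mu_off: float = 0.5,
    K: float = 625.0,
    rho: float = 0.6,
) -> ModelBundle:
    """Two-state telegraph model of transcription.

    State ``(g, m)``: ``g = 1`` while the gene is active, ``m`` the mRNA
    count.  The stochastic system starts in the *inactive* state with no
    mRNA, so ``1/lambda_on`` (the mean activation waiting time) is a
    strict lower bound on any mean FPT to a positive target.
    """
    if min(lambda_on, mu_off, K) <= 0:
        raise ValueError("all telegraph rates must be positive")
    mean = K * lambda_on / (lambda_on + mu_off)
    bound = _default_bound(mean, rho, 1)
    G = SpeciesSpec("G", 0, 1)
    M = SpeciesSpec("M", 1, bound)

    def act_prop(s, _lam=lambda_on):
        return _lam * (1.0 - s[..., 0])

    activation = Reaction(
        [0, 0], [1, 0], lambda_on,
        propensity_kind="custom",
        propensity_fn=act_prop,
        mean_field_fn=lambda X, _lam=lambda_on: _lam * (1.0 - X[0]),
        label="G* -> G",
    )
    deactivation = Reaction([1, 0], [0, 0], mu_off, label="G -> G*")
    transcription = Reaction([1, 0], [1, 1], K, label="G -> G + M")
    decay = Reaction([0, 1], [0, 0], 1.0, label="M -> 0")
    net = ReactionNetwork(
        [G, M],
        [activation, deactivation, transcription, decay],
        name=f"telegraph(lambda={lambda_on:g}, mu={mu_off:g}, K={K:g})",
    )
    return ModelBundle(
        name="telegraph",
        network=net,
        params={"lambda_on": lambda_on, "mu_off": mu_off, "K": K, "delta": 1.0},
        threshold_species="M",
        default_initial_state=[0, 0],  # inactive gene, no mRNA
        default_rho=rho,
        _closed_form_mean=mean,
        _rre_initial=np.array([0.0, 0.0]),
    )


def feedback(
    rho_u: float = 10.0,
    rho_b: float = 50.0,
    sigma_b: float = 1.0,
    sigma_u: float = 20.0,
    rho: float = 0.9,
    bound: int | None = None,
) -> ModelBundle:
    """Autoregulatory feedback loop (positive iff ``rho_b > rho_u``).

    State ``(u, p)``: ``u = 1`` while the gene is unbound, ``p`` the
    *free* protein count; binding consumes a free protein and unbinding
    releases it, so the threshold applies to free protein.  The steady
    state mean is computed numerically from the rate equations

        du/dt = sigma_u (1-u) - sigma_b u p
        dp/dt = rho_u u + rho_b (1-u) - p - sigma_b u p + sigma_u (1-u).
    """
    if min(rho_u, rho_b, sigma_b, sigma_u) < 0:
        raise ValueError("all feedback rates must be nonnegative")
    U = SpeciesSpec("G", 0, 1)

    def unbind_prop(s, _su=sigma_u):
        return _su * (1.0 - s[..., 0])

    def prod_bound_prop(s, _rb=rho_b):
        return _rb * (1.0 - s[..., 0])

    reactions_proto = [
        # P + G -> G*   (binding, consumes one free protein)
        Reaction([1, 1], [0, 0], sigma_b, label="P + G -> G*"),
        # G* -> P + G   (unbinding, releases the protein)
        Reaction(
            [0, 0], [1, 1], sigma_u,
            propensity_kind="custom",
            propensity_fn=unbind_prop,
            mean_field_fn=lambda X, _su=sigma_u: _su * (1.0 - X[0]),
            label="G* -> P + G",
        ),
        # G -> G + P    (production while unbound)
        Reaction([1, 0], [1, 1], rho_u, label="G -> G + P"),
        # G* -> G* + P  (production while bound)
        Reaction(
            [0, 0], [0, 1], rho_b,
            propensity_kind="custom",
            propensity_fn=prod_bound_prop,
            mean_field_fn=lambda X, _rb=rho_b: _rb * (1.0 - X[0]),
            label="G* -> G* + P",
        ),
        # P -> 0
        Reaction([0, 1], [0, 0], 1.0, label="P -> 0"),
    ]

    name = (
        f"feedback(rho_u={rho_u:g}, rho_b={rho_b:g}, "
        f"sigma_b={sigma_b:g}, sigma_u={sigma_u:g})"
    )
    if bound is None:
        # provisional network only to find the numerical steady state
        proto = ReactionNetwork(
            [U, SpeciesSpec("P", 1, 1)], reactions_proto, name=name
        )
        ss = steady_state(
            rre_from_network(proto, initial_condition=np.array([1.0, 0.0]))
        )
        bound = _default_bound(float(ss[1]), rho, 1)
    P = SpeciesSpec("P", 1, int(bound))
    net = ReactionNetwork([U, P], reactions_proto, name=name)
    return ModelBundle(
        name="feedback",
        network=net,
        params={
            "rho_u": rho_u,
            "rho_b": rho_b,
            "sigma_b": sigma_b,
            "sigma_u": sigma_u,
            "delta": 1.0,
        },
        threshold_species="P",
        default_initial_state=[1, 0],  # unbound gene, no protein
        default_rho=rho,
        _rre_initial=np.array([1.0, 0.0]),
    )


MODEL_REGISTRY = {
    "simple_bd": simple_bd,
    "bursty_bd": bursty_bd,
    "bursty_geom": bursty_bd_geometric,
    "telegraph": telegraph,
    "feedback": feedback,
}


def make_model(name: str, **params) -> ModelBundle:
    """Construct a registered model by name (CLI / config entry point)."""
    if name not in MODEL_REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        )
    return MODEL_REGISTRY[name](**params)
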