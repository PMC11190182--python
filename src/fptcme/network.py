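"""Stochastic reaction networks: species, reactions and propensities.

A :class:`ReactionNetwork` is the common input to every solver in this
package.  States are integer copy-number vectors (counts, not
concentrations) and time is nondimensional: all rate constants are assumed
to be pre-scaled by the first-order degradation rate, so degradation has
unit rate and one time unit is one mean molecule lifetime.

Propensities follow standard stochastic mass-action kinetics,
``a_j(x) = c_j * h_j(x)`` with ``h_j`` the number of distinct combinations
of reactant molecules (``h = x`` for a first-order reaction, ``h = x*y``
for a bimolecular ``X + Y`` reaction, ``h = 1`` for zeroth order,
``h = binom(x, s)`` in general).  A ``custom`` propensity kind accepts an
arbitrary function of the state; it is used for reactions that fire out of
the implicit complement of a binary gene species and for distributed-burst
models that attach per-burst-size rates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpeciesSpec",
    "Reaction",
    "ReactionNetwork",
    "propensity",
    "apply_reaction",
    "load_network",
    "dump_network",
    "InvalidStateError",
]


class InvalidStateError(ValueError):
    """Raised when a state vector has negative entries or the wrong length."""


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species with a finite truncation bound.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"P"`` or ``"M"``.
    index : int
        0-based position in state vectors; contiguous across the network.
    max_count : int
        Inclusive copy-number truncation bound used by the finite state
        projection (the species occupies ``0..max_count``).
    """

    name: str
    index: int
    max_count: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("species index must be nonnegative")
        if self.max_count < 0:
            raise ValueError("max_count must be nonnegative")


@dataclass
class Reaction:
    """A single reaction channel.

    ``reactant_stoich`` and ``product_stoich`` are nonnegative integer
    vectors of length ``n_species``; the state change on firing is
    ``product_stoich - reactant_stoich``.  ``propensity_kind`` is either
    ``"mass_action"`` or ``"custom"``; a custom reaction carries its
    propensity as ``propensity_fn(state) -> rate`` (the function should
    accept batched states of shape ``(m, n_species)`` as well, returning a
    length-``m`` array) and may carry ``mean_field_fn(X) -> rate`` giving
    its deterministic mean-field rate for the reaction-rate equations.
    """

    reactant_stoich: np.ndarray
    product_stoich: np.ndarray
    rate_constant: float
    propensity_kind: str = "mass_action"
    propensity_fn: Callable[[np.ndarray], np.ndarray] | None = None
    mean_field_fn: Callable[[np.ndarray], float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.reactant_stoich = np.asarray(self.reactant_stoich, dtype=np.int64)
        self.product_stoich = np.asarray(self.product_stoich, dtype=np.int64)
        if np.any(self.reactant_stoich < 0) or np.any(self.product_stoich < 0):
            raise ValueError("stoichiometric coefficients must be nonnegative")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be nonnegative")
        if self.propensity_kind not in ("mass_action", "custom"):
            raise ValueError(f"unknown propensity kind {self.propensity_kind!r}")
        if self.propensity_kind == "custom" and self.propensity_fn is None:
            raise ValueError("custom propensity requires propensity_fn")

    @property
    def net_change(self) -> np.ndarray:
        """Stoichiometry (state-change) vector ``v = products - reactants``."""
        return self.product_stoich - self.reactant_stoich


def _combinations(x: np.ndarray, s: int) -> np.ndarray:
    """Distinct combinations of ``s`` molecules drawn from ``x``: binom(x, s)."""
    if s == 1:
        return x.astype(np.float64)
    out = np.ones_like(x, dtype=np.float64)
    for i in range(s):
        out *= np.maximum(x - i, 0)
    return out / math.factorial(s)


@dataclass
class ReactionNetwork:
    """A named collection of species and reactions.

    Species indices must be 0-based, contiguous and match their list
    position; every stoichiometry vector must have length ``n_species``.
    """

    species: list[SpeciesSpec]
    reactions: list[Reaction]
    name: str = "network"

    def __post_init__(self) -> None:
        for i, sp in enumerate(self.species):
            if sp.index != i:
                raise ValueError(
                    f"species {sp.name!r} has index {sp.index}, expected {i}"
                )
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        n = len(self.species)
        for r in self.reactions:
            if len(r.reactant_stoich) != n or len(r.product_stoich) != n:
                raise ValueError("stoichiometry vector length != number of species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    @property
    def bounds(self) -> np.ndarray:
        """Per-species truncation bounds (inclusive)."""
        return np.array([sp.max_count for sp in self.species], dtype=np.int64)

    def species_index(self, name: str) -> int:
        for sp in self.species:
            if sp.name == name:
                return sp.index
        raise KeyError(f"no species named {name!r}")

    def stoichiometry(self) -> np.ndarray:
        """Net-change matrix of shape ``(n_reactions, n_species)``."""
        return np.array([r.net_change for r in self.reactions], dtype=np.int64)

    def _check_state(self, state: np.ndarray) -> np.ndarray:
        state = np.asarray(state, dtype=np.int64)
        if state.shape[-1] != self.n_species:
            raise InvalidStateError(
                f"state has length {state.shape[-1]}, expected {self.n_species}"
            )
        if np.any(state < 0):
            raise InvalidStateError("state has negative copy numbers")
        return state

    def propensity(self, reaction_index: int, state: Sequence[int]) -> float:
        """Propensity ``a_j(x)`` of one reaction in one state."""
        state = self._check_state(np.atleast_1d(np.asarray(state)))
        r = self.reactions[reaction_index]
        if r.propensity_kind == "custom":
            return float(np.asarray(r.propensity_fn(state)))
        a = r.rate_constant
        for i in np.nonzero(r.reactant_stoich)[0]:
            a *= float(_combinations(state[i : i + 1], int(r.reactant_stoich[i]))[0])
        return a

    def propensity_matrix(self, states: np.ndarray) -> np.ndarray:
        """Propensities for a batch of states.

        Parameters
        ----------
        states : (m, n_species) integer array

        Returns
        -------
        (m, n_reactions) float array
        """
        states = np.asarray(states, dtype=np.int64)
        m = states.shape[0]
        out = np.empty((m, self.n_reactions), dtype=np.float64)
        for j, r in enumerate(self.reactions):
            if r.propensity_kind == "custom":
                a = np.asarray(r.propensity_fn(states), dtype=np.float64)
                if a.shape != (m,):
                    # scalar-only custom function: fall back to a row loop
                    a = np.array(
                        [float(r.propensity_fn(states[i])) for i in range(m)]
                    )
                out[:, j] = a
            else:
                a = np.full(m, r.rate_constant, dtype=np.float64)
                for i in np.nonzero(r.reactant_stoich)[0]:
                    a *= _combinations(states[:, i], int(r.reactant_stoich[i]))
                out[:, j] = a
        return out

    def apply_reaction(self, state: Sequence[int], reaction_index: int) -> np.ndarray:
        """State after one firing (may fall outside the truncation)."""
        state = np.asarray(state, dtype=np.int64)
        return state + self.reactions[reaction_index].net_change


def propensity(network: ReactionNetwork, reaction_index: int, state) -> float:
    """Module-level convenience wrapper for :meth:`ReactionNetwork.propensity`."""
    return network.propensity(reaction_index, state)


def apply_reaction(state, reaction: Reaction) -> np.ndarray:
    """Return ``state + v`` for the reaction's net-change vector ``v``."""
    return np.asarray(state, dtype=np.int64) + reaction.net_change


# ---------------------------------------------------------------------------
# Plain-text configuration format
#
# YAML with reactions written as chemical equations::
#
#     name: bursty_bd
#     species:
#       - {name: P, max_count: 400}
#     reactions:
#       - "0 -> 10 P @ 20"
#       - "P -> 0 @ 1"
#
# An empty side may be written "0" or left blank.  Custom propensities are
# not representable in config files (they require Python callables).
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s*\*?\s*)?([A-Za-z_][A-Za-z0-9_*']*)\s*$")


def _parse_side(side: str, index_of: dict[str, int], n: int) -> np.ndarray:
    stoich = np.zeros(n, dtype=np.int64)
    side = side.strip()
    if side in ("", "0", "∅"):
        return stoich
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if m is None:
            raise ValueError(f"cannot parse reaction term {term!r}")
        count = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        if name not in index_of:
            raise ValueError(f"unknown species {name!r} in reaction")
        stoich[index_of[name]] += count
    return stoich


def _format_side(stoich: np.ndarray, names: list[str]) -> str:
    terms = []
    for i in np.nonzero(stoich)[0]:
        c = int(stoich[i])
        terms.append(names[i] if c == 1 else f"{c} {names[i]}")
    return " + ".join(terms) if terms else "0"


def parse_reaction(text: str, index_of: dict[str, int], n: int) -> Reaction:
    """Parse ``"reactants -> products @ rate"`` into a :class:`Reaction`."""
    if "@" not in text or "->" not in text:
        raise ValueError(f"reaction must look like 'A -> B @ rate': {text!r}")
    eqn, rate = text.rsplit("@", 1)
    lhs, rhs = eqn.split("->", 1)
    return Reaction(
        reactant_stoich=_parse_side(lhs, index_of, n),
        product_stoich=_parse_side(rhs, index_of, n),
        rate_constant=float(rate),
    )


def load_network(source) -> ReactionNetwork:
    """Read a network from a YAML config file path, file object, or string."""
    import yaml

    import os

    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    elif "\n" not in str(source) and os.path.exists(str(source)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(str(source))
    species = [
        SpeciesSpec(name=str(s["name"]), index=i, max_count=int(s["max_count"]))
        for i, s in enumerate(doc.get("species", []))
    ]
    index_of = {sp.name: sp.index for sp in species}
    n = len(species)
    reactions = [parse_reaction(str(r), index_of, n) for r in doc.get("reactions", [])]
    return ReactionNetwork(species, reactions, name=str(doc.get("name", "network")))


def dump_network(network: ReactionNetwork, path=None) -> str:
    """Serialize a network to the YAML config format; round-trips with
    :func:`load_network`.  Custom-propensity reactions cannot be serialized."""
    import yaml

    for r in network.reactions:
        if r.propensity_kind != "mass_action":
            raise ValueError("custom-propensity reactions are not serializable")
    names = network.species_names
    doc = {
        "name": network.name,
        "species": [
            {"name": sp.name, "max_count": int(sp.max_count)} for sp in network.species
        ],
        "reactions": [
            f"{_format_side(r.reactant_stoich, names)} -> "
            f"{_format_side(r.product_stoich, names)} @ {r.rate_constant:g}"
            for r in network.reactions
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
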