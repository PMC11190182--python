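"""Truncated state-space enumeration and the sparse CME generator.

The chemical master equation for a reaction network is the linear system
``d_t P = A P`` over the (generally infinite) lattice of copy-number
states.  Here the lattice is truncated to the rectangular box
``0..max_count_i`` per species (a finite state projection): transitions
leaving the box are dropped, so the leaked probability is implicitly
absorbed.  Column ``i`` of ``A`` then has off-diagonal entries
``a_j(x_i)`` at the rows of the destination states ``x_i + v_j`` that
remain inside the box, and diagonal entry ``-sum_j a_j(x_i)`` over *all*
reactions — including those exiting the truncation.  A column therefore
sums to minus the total outflow rate from its state across the boundary
(the "defect"), which is the quantity used to diagnose whether the
truncation is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import ReactionNetwork

__all__ = [
    "StateSpace",
    "enumerate_states",
    "build_transition_matrix",
    "column_defect",
    "export_triplets",
    "StateSpaceSizeError",
]

DEFAULT_MAX_STATES = 2_000_000


class StateSpaceSizeError(ValueError):
    """Raised when the rectangular truncation exceeds the state cap."""

    def __init__(self, required: int, cap: int):
        self.required = required
        self.cap = cap
        super().__init__(
            f"truncation requires {required} states, exceeding the cap of {cap}; "
            f"raise max_states to at least {required} or tighten the bounds"
        )


@dataclass
class StateSpace:
    """Ordered enumeration of all states in a rectangular truncation.

    States are ordered lexicographically in ``(species_0, species_1, ...)``
    with the last species varying fastest, so the index of a state is a
    mixed-radix expansion of its copy numbers.
    """

    bounds: np.ndarray  # inclusive per-species bounds
    states: np.ndarray  # (n_states, n_species) int64

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def n_species(self) -> int:
        return self.states.shape[1]

    @property
    def strides(self) -> np.ndarray:
        sizes = self.bounds + 1
        return np.concatenate([np.cumprod(sizes[::-1])[-2::-1], [1]]).astype(np.int64)

    def index_of(self, state) -> int:
        """Row index of a state; raises ``KeyError`` outside the truncation."""
        state = np.asarray(state, dtype=np.int64)
        if np.any(state < 0) or np.any(state > self.bounds):
            raise KeyError(f"state {state.tolist()} outside truncation")
        return int(np.dot(state, self.strides))

    def indices_of(self, states: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`index_of`; -1 marks states outside the box."""
        states = np.asarray(states, dtype=np.int64)
        inside = np.all((states >= 0) & (states <= self.bounds), axis=1)
        idx = states @ self.strides
        return np.where(inside, idx, -1)


def enumerate_states(
    network: ReactionNetwork, max_states: int = DEFAULT_MAX_STATES
) -> StateSpace:
    """Enumerate the full rectangular truncation of a network.

    The number of states is ``prod(max_count_i + 1)``; an explicit
    :class:`StateSpaceSizeError` is raised when this exceeds ``max_states``.
    """
    bounds = network.bounds
    sizes = bounds + 1
    total = int(np.prod(sizes, dtype=np.int64))
    if total > max_states:
        raise StateSpaceSizeError(total, max_states)
    grids = np.meshgrid(*[np.arange(s) for s in sizes], indexing="ij")
    states = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    return StateSpace(bounds=bounds, states=states)


def build_transition_matrix(
    network: ReactionNetwork, space: StateSpace
) -> sp.csc_matrix:
    """Assemble the sparse CME generator ``A`` with ``d_t P = A P``.

    The diagonal accumulates the propensities of *all* reactions, so
    probability flowing through the truncation boundary leaves the system
    (finite-state-projection convention).
    """
    n = space.n_states
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n, dtype=np.float64)
    all_idx = np.arange(n, dtype=np.int64)
    props = network.propensity_matrix(space.states)
    for j, r in enumerate(network.reactions):
        a = props[:, j]
        diag -= a
        dest = space.indices_of(space.states + r.net_change)
        ok = (dest >= 0) & (a != 0.0)
        rows.append(dest[ok])
        cols.append(all_idx[ok])
        vals.append(a[ok])
    rows.append(all_idx)
    cols.append(all_idx)
    vals.append(diag)
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    A.eliminate_zeros()
    return A


def column_defect(A: sp.spmatrix) -> np.ndarray:
    """Per-state outflow rate through the truncation boundary.

    ``defect_i = -(column sum)_i``; zero everywhere iff the truncation
    contains all states reachable in one reaction firing.  Tiny negative
    rounding residue is clipped to zero.
    """
    colsum = np.asarray(A.sum(axis=0)).ravel()
    return np.clip(-colsum, 0.0, None)


def export_triplets(A: sp.spmatrix, path) -> None:
    """Write the generator as whitespace-separated ``row col value`` triplets."""
    coo = sp.coo_matrix(A)
    with open(path, "w") as fh:
        fh.write(f"# {coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {v:.17g}\n")
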