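"""Independent brute-force validator for the closed forms.

A generalized first-order activation/decay network dN/dt = M N is solved
with the matrix exponential (exact to machine precision for the small
systems in this package).  The test suite compares every closed-form
expression against trajectories produced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = ["LinearNetwork", "integrate"]


@dataclass(frozen=True)
class LinearNetwork:
    """First-order network: states, rate matrix (s^-1), initial atoms.

    Off-diagonal entries are gain rates into a state; diagonal entries are
    total loss rates (negative).  Losses may exceed tracked gains (leaks
    to untracked sinks are allowed).
    """

    states: tuple[str, ...]
    rate_matrix: np.ndarray
    initial_atoms: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.rate_matrix, dtype=float)
        n0 = np.asarray(self.initial_atoms, dtype=float)
        n = len(self.states)
        if m.shape != (n, n):
            raise ValueError(f"rate matrix shape {m.shape} != ({n}, {n})")
        if n0.shape != (n,):
            raise ValueError("initial atoms length mismatch")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite rates")
        off = m - np.diag(np.diag(m))
        if np.any(off < 0):
            raise ValueError("off-diagonal (gain) rates must be non-negative")
        # column loss must cover tracked gains (no spontaneous creation)
        gains = off.sum(axis=0)
        losses = -np.diag(m)
        if np.any(gains > losses * (1 + 1e-12) + 1e-300):
            raise ValueError("a column gains more into tracked states than it loses")
        object.__setattr__(self, "rate_matrix", m)
        object.__setattr__(self, "initial_atoms", n0)

    @classmethod
    def from_edges(cls, states, edges, initial_atoms) -> "LinearNetwork":
        """Build from (source, destination | None, rate) triples.

        ``destination=None`` leaks to an untracked sink.
        """
        states = tuple(states)
        idx = {s: i for i, s in enumerate(states)}
        m = np.zeros((len(states), len(states)))
        for src, dst, rate in edges:
            if rate < 0:
                raise ValueError("edge rates must be non-negative")
            m[idx[src], idx[src]] -= rate
            if dst is not None:
                m[idx[dst], idx[src]] += rate
        return cls(states, m, np.asarray(initial_atoms, dtype=float))

    def with_sink(self, label: str = "_sink") -> "LinearNetwork":
        """Append a cumulative sink state absorbing every leak, making the
        total atom count a conserved quantity."""
        n = len(self.states)
        m = np.zeros((n + 1, n + 1))
        m[:n, :n] = self.rate_matrix
        leak = -self.rate_matrix.sum(axis=0)  # loss not captured by gains
        m[n, :n] = leak
        n0 = np.concatenate([self.initial_atoms, [0.0]])
        return LinearNetwork(self.states + (label,), m, n0)


def integrate(network: LinearNetwork, times) -> np.ndarray:
    """Trajectories N(t) for each requested time, shape (n_times, n_states)."""
    t_arr = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    out = np.empty((len(t_arr), len(network.states)))
    for k, t in enumerate(t_arr):
        out[k] = expm(network.rate_matrix * t) @ network.initial_atoms
    return out
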