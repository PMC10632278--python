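"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pytest

from hhepi import ExponentialLaw, common_size, two_point_tilde


@pytest.fixture(scope="session")
def exp1():
    """Unit-mean exponential infectious period (the E[T_I] = 1 convention)."""
    return ExponentialLaw(1.0)


@pytest.fixture(scope="session")
def mix14():
    """Half the individuals alone, half in households of size 4."""
    return two_point_tilde(4, 0.5)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def markov_household_extra_infections(s: int, i: int, lam: float, gamma: float = 1.0):
    """Exact distribution of additional infections in a Markov SIR household.

    Embedded jump chain on (susceptibles, infectives): the next event is a
    local infection with probability lam*s/(lam*s + gamma), else a recovery.
    Returns an array p with p[k] = P(k of the s susceptibles ever infected).
    Independent of the package's Gontcharoff-coefficient machinery.
    """

    @lru_cache(maxsize=None)
    def rec(s_, i_):
        if s_ == 0 or i_ == 0:
            out = np.zeros(s_ + 1)
            out[0] = 1.0
            return tuple(out)
        p_inf = lam * s_ / (lam * s_ + gamma)
        down = np.array(rec(s_ - 1, i_ + 1))
        stay = np.array(rec(s_, i_ - 1))
        out = np.zeros(s_ + 1)
        out[1:] += p_inf * down
        out[: s_ + 1] += (1.0 - p_inf) * stay
        return tuple(out)

    return np.array(rec(s, i))


def markov_household_outcome(n: int, lam: float, pi: float, gamma: float = 1.0):
    """Exact (P_{n,0..n}) for a Markov household with Bin(n, 1-pi) introductions."""
    out = np.zeros(n + 1)
    for j in range(n + 1):
        w = math.comb(n, j) * (1 - pi) ** j * pi ** (n - j)
        if w == 0.0:
            continue
        extra = markov_household_extra_infections(n - j, j, lam, gamma)
        for k, p in enumerate(extra):
            out[j + k] += w * p
    return out


def sample_household_graphs(n: int, lambda_L: float, law, rng, reps: int):
    """Within-household infection digraphs: adjacency[r, i, j] for rep r.

    Individual i contacts j (j != i) with probability 1 - exp(-lambda_L T_i)
    conditionally independently given its infectious period T_i.
    """
    T = np.asarray(law.sample(rng, reps * n)).reshape(reps, n)
    p = 1.0 - np.exp(-lambda_L * T)
    adj = rng.random((reps, n, n)) < p[:, :, None]
    idx = np.arange(n)
    adj[:, idx, idx] = False
    return adj


def mc_generations(adj):
    """Generation (BFS-layer) sizes from vertex 0; returns (reps, n) counts."""
    reps, n, _ = adj.shape
    reached = np.zeros((reps, n), dtype=bool)
    frontier = np.zeros((reps, n), dtype=bool)
    frontier[:, 0] = True
    reached[:, 0] = True
    gens = np.zeros((reps, n), dtype=int)
    gens[:, 0] = 1
    for g in range(1, n):
        nxt = np.any(frontier[:, :, None] & adj, axis=1) & ~reached
        if not nxt.any():
            break
        reached |= nxt
        frontier = nxt
        gens[:, g] = nxt.sum(axis=1)
    return gens


def mc_final_sizes(adj):
    """Number reachable from vertex 0 (including it) per replicate."""
    gens = mc_generations(adj)
    return gens.sum(axis=1)
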