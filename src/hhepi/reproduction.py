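"""Reproduction numbers, growth rate and calibration for household models.

Two threshold parameters are in play.  The household reproduction number

    R_* = lambda_G E[T_I] sum_n alpha~_n mu_n(lambda_L)

counts the expected global contacts emanating from a typical newly infected
household and is trivial to compute.  The rank-generation basic reproduction
number R_0 is the asymptotic geometric growth rate of mean generation sizes
in the infection graph (generations by shortest path length): it is the
unique positive root lambda of

    1 - lambda_G E[T_I] sum_{i>=0} mu_i / lambda^{i+1} = 0,

where mu_i = sum_n alpha~_n mu_i^{(n)} and mu_i^{(n)} is the mean size of
the i-th rank generation of a single-household epidemic of size n.  The two
agree at criticality: R_0 = 1 iff R_* = 1.

Rank-generation means are computed by an exact recursion over the
breadth-first frontier of the within-household random digraph.  Conditional
on its infectious period T, an infective contacts each housemate
independently with probability 1 - exp(-lambda_L T), so the probability
that every one of f independent infectives misses a given set of m
housemates is phi(m lambda_L)^f.  Inclusion-exclusion turns this into the
law of the number of new individuals contacted by a frontier of size f out
of u not-yet-reached susceptibles, and the frontier process ((u, f) pairs)
is a small Markov chain — exact for every household size.

The module also provides the early exponential growth rate of the Markov
households SEIR/SIR model via the household Lotka-Euler equation

    lambda_G sum_n alpha~_n int_0^inf exp(-r t) E[I_n(t)] dt = 1,

with the Laplace transform of the expected number of infectives in a
single-household epidemic obtained by a linear solve against the
within-household generator, and the inverse problem (choosing lambda_G to
match a target growth rate, as when calibrating to an estimate of r from
incidence data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .distributions import (
    ExponentialLaw,
    HouseholdSizeDistribution,
    InfectiousPeriodLaw,
)
from .final_size import single_household_mean_size

__all__ = [
    "R_star",
    "RankGenerationProfile",
    "rank_generation_means",
    "R0",
    "R_U_hat",
    "R_DI_from_outcome",
    "growth_rate",
    "r_from_R0BBT",
    "calibrate_lambda_G",
]


def R_star(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
) -> float:
    """Household reproduction number R_*."""
    sb = dist.size_biased()
    phi = T_I.phi
    total = 0.0
    for n in sb.sizes:
        a = sb.probs[n - 1]
        if a > 0.0:
            total += a * single_household_mean_size(int(n), lambda_L, phi)
    return lambda_G * T_I.mean * total


@dataclass(frozen=True)
class RankGenerationProfile:
    """Mean rank-generation sizes (mu_0^{(n)}, ..., mu_{n-1}^{(n)})."""

    n: int
    means: np.ndarray

    def __post_init__(self) -> None:
        assert self.means.shape == (self.n,)
        assert abs(self.means[0] - 1.0) < 1e-12


def rank_generation_means(n: int, lambda_L: float, phi) -> RankGenerationProfile:
    """Mean sizes of rank generations in a size-n household epidemic.

    Exact for all n via the frontier recursion described in the module
    docstring.  Generation 0 is the introduced case, so the means sum to
    mu_n(lambda_L).
    """
    if n < 1:
        raise ValueError("household size must be >= 1")
    means = np.zeros(n)
    means[0] = 1.0
    if n == 1 or lambda_L == 0.0:
        return RankGenerationProfile(n=n, means=means)
    if math.isinf(lambda_L):
        means[1] = n - 1.0
        return RankGenerationProfile(n=n, means=means)

    # P(all f infectives miss a given m-set) = phi(m lambda_L)^f
    phi_m = [phi(m * lambda_L) for m in range(n)]

    def new_contact_law(u: int, f: int) -> np.ndarray:
        """Law of the number of new contacts among u susceptibles by f infectives."""
        out = np.zeros(u + 1)
        for j in range(u + 1):
            acc = 0.0
            for a in range(j + 1):
                acc += math.comb(j, a) * (-1.0) ** (j - a) * phi_m[u - a] ** f
            out[j] = math.comb(u, j) * acc
        # numerical guard: the law is exact but alternating sums can dip below 0
        out = np.clip(out, 0.0, None)
        return out / out.sum()

    # state: probability mass over (u, f) = (unreached susceptibles, frontier size)
    state = {(n - 1, 1): 1.0}
    gen = 0
    while state and gen + 1 < n:
        gen += 1
        nxt: dict = {}
        for (u, f), p in state.items():
            if u == 0 or f == 0:
                continue
            law = new_contact_law(u, f)
            for j in range(u + 1):
                if law[j] > 0.0:
                    key = (u - j, j)
                    nxt[key] = nxt.get(key, 0.0) + p * law[j]
        means[gen] = sum(p * f for (u, f), p in nxt.items())
        state = {k: v for k, v in nxt.items() if k[1] > 0}
    return RankGenerationProfile(n=n, means=means)


def _mean_generation_sizes(dist: HouseholdSizeDistribution, lambda_L: float, phi) -> np.ndarray:
    """Population-averaged generation means mu_i = sum_n alpha~_n mu_i^{(n)}."""
    sb = dist.size_biased()
    mu = np.zeros(dist.n_max)
    for n in sb.sizes:
        a = sb.probs[n - 1]
        if a > 0.0:
            prof = rank_generation_means(int(n), lambda_L, phi)
            mu[: prof.n] += a * prof.means
    return mu


def R0(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
) -> float:
    """Rank-generation basic reproduction number.

    Unique positive root lambda of 1 - lambda_G E[T_I] sum_i mu_i/lambda^{i+1} = 0.
    """
    if lambda_G <= 0:
        raise ValueError("lambda_G must be positive")
    mu = _mean_generation_sizes(dist, lambda_L, T_I.phi)
    c = lambda_G * T_I.mean

    def g(lam: float) -> float:
        return 1.0 - c * sum(mu[i] / lam ** (i + 1) for i in range(len(mu)))

    lo = 1e-12
    hi = max(c * mu.sum(), 1.0) + 1.0
    while g(lo) > 0:  # pragma: no cover - g(0+) = -inf in exact arithmetic
        lo *= 0.1
    while g(hi) < 0:
        hi *= 2.0
    return brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)


def R_U_hat(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
    c: float,
) -> float:
    """Post-vaccination threshold parameter R^_U(c).

    Each individual is vaccinated independently with probability c with a
    perfect vaccine; strictly decreasing from R_* at c = 0 to 0 at c = 1.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("coverage c must lie in [0, 1]")
    sb = dist.size_biased()
    phi = T_I.phi
    mu_cache = {0: 0.0}
    total = 0.0
    for n in sb.sizes:
        a = sb.probs[n - 1]
        if a <= 0.0:
            continue
        n = int(n)
        inner = 0.0
        for v in range(n + 1):
            k = n - v  # unvaccinated members
            if k not in mu_cache:
                mu_cache[k] = single_household_mean_size(k, lambda_L, phi)
            w = math.comb(n, v) * c**v * (1.0 - c) ** (n - v)
            inner += w * (k / n) * mu_cache[k]
        total += a * inner
    return lambda_G * T_I.mean * total


def R_DI_from_outcome(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
    outcome_dists: dict,
) -> float:
    """Threshold parameter of a second epidemic after a first epidemic.

    ``outcome_dists`` maps n to (P_{n,0}, ..., P_{n,n}), the household
    outcome proportions of the first epidemic; individuals infected in the
    first epidemic are immune.  Evaluated with the *unreduced* lambda_G.
    """
    sb = dist.size_biased()
    phi = T_I.phi
    mu_cache = {0: 0.0}
    total = 0.0
    for n in sb.sizes:
        a = sb.probs[n - 1]
        if a <= 0.0:
            continue
        n = int(n)
        P = np.asarray(outcome_dists[n], dtype=float)
        inner = 0.0
        for v in range(n + 1):
            if P[v] <= 0.0:
                continue
            k = n - v
            if k not in mu_cache:
                mu_cache[k] = single_household_mean_size(k, lambda_L, phi)
            inner += P[v] * (k / n) * mu_cache[k]
        total += a * inner
    return lambda_G * T_I.mean * total


# ---------------------------------------------------------------------------
# growth rate and calibration (Markov laws)
# ---------------------------------------------------------------------------


def _household_infective_transform(
    n: int, lambda_L: float, gamma: float, delta: float | None, r: float
) -> float:
    """int_0^inf e^{-rt} E[I_n(t)] dt for a single-household Markov epidemic.

    The household epidemic starts with one newly infected member (exposed if
    a latent stage is present, else infectious) and evolves by local
    infection (rate lambda_L s i), latency progression (delta e) and
    recovery (gamma i).  With generator Q and weight vector w(state) = i,
    the transform is w^T (rI - Q)^{-1} applied to the initial distribution.
    """
    # enumerate states (s, e, i); r-compartment implicit
    if delta is None:
        states = [(s, 0, i) for s in range(n + 1) for i in range(n + 1 - s)]
    else:
        states = [
            (s, e, i)
            for s in range(n + 1)
            for e in range(n + 1 - s)
            for i in range(n + 1 - s - e)
        ]
    index = {st: k for k, st in enumerate(states)}
    m = len(states)
    Q = np.zeros((m, m))
    for (s, e, i), k in index.items():
        if delta is not None and e > 0:
            rate = delta * e
            Q[k, k] -= rate
            Q[index[(s, e - 1, i + 1)], k] += rate
        if i > 0:
            rate = gamma * i
            Q[k, k] -= rate
            Q[index[(s, e, i - 1)], k] += rate
        if s > 0 and i > 0 and lambda_L > 0:
            rate = lambda_L * s * i
            Q[k, k] -= rate
            if delta is None:
                Q[index[(s - 1, 0, i + 1)], k] += rate
            else:
                Q[index[(s - 1, e + 1, i)], k] += rate
    p0 = np.zeros(m)
    if delta is None:
        p0[index[(n - 1, 0, 1)]] = 1.0
    else:
        p0[index[(n - 1, 1, 0)]] = 1.0
    w = np.array([st[2] for st in states], dtype=float)
    # transform = w . (rI - Q)^{-1} p0  (column-vector ODE dp/dt = Q p)
    sol = np.linalg.solve(r * np.eye(m) - Q, p0)
    return float(w @ sol)


def _euler_transform(
    dist: HouseholdSizeDistribution, lambda_L: float, gamma: float, delta: float | None, r: float
) -> float:
    sb = dist.size_biased()
    total = 0.0
    for n in sb.sizes:
        a = sb.probs[n - 1]
        if a > 0.0:
            total += a * _household_infective_transform(int(n), lambda_L, gamma, delta, r)
    return total


def growth_rate(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    gamma: float,
    delta: float | None = None,
) -> float:
    """Early exponential growth rate r of the Markov households model.

    Solves the household Lotka-Euler equation
    lambda_G * sum_n alpha~_n L_n(r) = 1, where L_n is the Laplace transform
    of the expected number of infectives in a size-n household epidemic.
    ``delta=None`` selects the SIR model (no latent stage).  r > 0 iff
    R_* > 1.  Requires exponential periods (Markov dynamics).
    """
    if math.isinf(lambda_L):
        raise ValueError("growth rate requires a finite local infection rate")

    def f(r: float) -> float:
        return lambda_G * _euler_transform(dist, lambda_L, gamma, delta, r) - 1.0

    # f is strictly decreasing in r; bracket the root
    rates = [gamma] + ([delta] if delta is not None else [])
    lo = -0.999 * min(rates)
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
    flo = f(lo)
    while flo < 0:
        lo = (lo - min(rates)) / 2.0 if lo > -min(rates) else lo  # pragma: no cover
        flo = f(lo)
        if lo <= -min(rates) * 0.9999999:
            break
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)


def r_from_R0BBT(R0BBT: float, gamma: float, delta: float) -> float:
    """Growth rate implied by a homogeneous/multitype SEIR R0 value.

    Inverts R0 = (1 + r/delta)(1 + r/gamma): the root r > -min(gamma, delta)
    of the quadratic, positive exactly when R0BBT > 1.
    """
    if R0BBT <= 0:
        raise ValueError("R0BBT must be positive")
    # r^2/(gamma delta) + r (1/gamma + 1/delta) + 1 - R0BBT = 0
    a = 1.0 / (gamma * delta)
    b = 1.0 / gamma + 1.0 / delta
    c = 1.0 - R0BBT
    disc = b * b - 4.0 * a * c
    return (-b + math.sqrt(disc)) / (2.0 * a)


def calibrate_lambda_G(
    dist: HouseholdSizeDistribution,
    lambda_L: float,
    gamma: float,
    delta: float | None,
    r_target: float,
) -> float:
    """Global rate lambda_G for which the model's early growth rate is r_target.

    The Lotka-Euler transform does not involve lambda_G, so the calibration
    is the direct reciprocal lambda_G = 1 / sum_n alpha~_n L_n(r_target).
    """
    if r_target <= 0:
        raise ValueError("target growth rate must be positive")
    L = _euler_transform(dist, lambda_L, gamma, delta, r_target)
    return 1.0 / L
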