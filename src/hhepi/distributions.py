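"""Household-size distributions and infectious/latent period laws.

A household-size distribution assigns probability ``alpha_n`` to a household
(chosen uniformly at random) having size ``n``.  Much of the theory of
household epidemic models is driven instead by the *size-biased* distribution
``H~`` — the size of the household of an individual chosen uniformly at
random from the population — with probabilities ``alpha~_n = n alpha_n / mu_H``.

This module provides:

* :class:`HouseholdSizeDistribution` and :class:`SizeBiasedDistribution`,
  with moments, factorial moments and probability-generating functions;
* named constructors (common size, two sizes, logarithmic households whose
  size-biased version is geometric);
* a seeded synthetic-distribution generator targeting a given mean and
  variance of the size-biased distribution;
* infectious-period laws (exponential, fixed, Erlang) exposing the mean
  ``E[T_I]`` and the Laplace transform ``phi(theta) = E[exp(-theta T_I)]``.

``lambda_L = inf`` (the highly locally infectious regime, in which a single
within-household introduction infects the whole household) is represented
throughout the package by the float ``inf`` and routed to closed-form
branches; it is never approximated by a large finite rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "HouseholdSizeDistribution",
    "SizeBiasedDistribution",
    "InfectiousPeriodLaw",
    "ExponentialLaw",
    "FixedLaw",
    "ErlangLaw",
    "size_bias",
    "factorial_moment",
    "geometric_size_biased",
    "random_household_distribution",
    "common_size",
    "two_point_tilde",
]

#: absolute tolerance for "probabilities sum to one" after renormalisation
_SUM_TOL = 1e-12


@dataclass(frozen=True)
class HouseholdSizeDistribution:
    """Distribution ``alpha_n`` of the size of a uniformly chosen household.

    Parameters
    ----------
    probs
        Array of length ``n_max`` with ``probs[i] = alpha_{i+1}``; must be
        non-negative and sum to one (renormalised on construction if the
        deviation is small).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("household size distribution must be a non-empty 1-d array")
        if np.any(p < -1e-15):
            raise ValueError("negative household-size probability")
        p = np.clip(p, 0.0, None)
        total = p.sum()
        if not math.isfinite(total) or total <= 0:
            raise ValueError("household size probabilities must have positive total mass")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"household size probabilities sum to {total}, not 1")
        p = p / total
        # trim trailing zero mass so that n_max is the largest size with alpha_n > 0
        nz = np.nonzero(p)[0]
        p = p[: nz[-1] + 1]
        object.__setattr__(self, "probs", p)
        assert abs(p.sum() - 1.0) <= _SUM_TOL

    # -- basic descriptors -------------------------------------------------
    @property
    def n_max(self) -> int:
        return int(self.probs.size)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def mean(self) -> float:
        """Mean household size mu_H."""
        return float(np.dot(self.sizes, self.probs))

    def pgf(self, s: float) -> float:
        return float(sum(self.probs[n - 1] * s**n for n in self.sizes))

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_mapping(cls, probs: Mapping[int, float]) -> "HouseholdSizeDistribution":
        if not probs:
            raise ValueError("empty household size distribution")
        n_max = max(probs)
        arr = np.zeros(n_max)
        for n, a in probs.items():
            if n < 1:
                raise ValueError("household sizes must be >= 1")
            arr[n - 1] = a
        return cls(arr)

    @classmethod
    def from_counts(cls, counts: Mapping[int, float]) -> "HouseholdSizeDistribution":
        """Counts-form input (size -> number of households), normalised."""
        total = sum(counts.values())
        return cls.from_mapping({n: c / total for n, c in counts.items()})

    @classmethod
    def read_csv(cls, path) -> "HouseholdSizeDistribution":
        """Two-column CSV ``size,probability`` (or ``size,count``)."""
        import pandas as pd

        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("expected a two-column CSV (size, probability)")
        sizes = df.iloc[:, 0].astype(int)
        weights = df.iloc[:, 1].astype(float)
        return cls.from_counts(dict(zip(sizes, weights)))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"size": self.sizes, "probability": self.probs}).to_csv(path, index=False)

    def size_biased(self) -> "SizeBiasedDistribution":
        return size_bias(self)


@dataclass(frozen=True)
class SizeBiasedDistribution:
    """Distribution of the household size of a uniformly chosen individual."""

    probs: np.ndarray  # probs[i] = alpha~_{i+1}

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0 or np.any(p < -1e-15):
            raise ValueError("invalid size-biased distribution")
        p = np.clip(p, 0.0, None)
        total = p.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError("size-biased probabilities must sum to 1")
        object.__setattr__(self, "probs", p / total)

    @property
    def n_max(self) -> int:
        return int(self.probs.size)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def mean(self) -> float:
        """mu_H~ = E[H~]."""
        return float(np.dot(self.sizes, self.probs))

    @property
    def var(self) -> float:
        m = self.mean
        return float(np.dot(self.sizes**2, self.probs) - m * m)

    def pgf(self, s: float) -> float:
        """Probability-generating function f_H~(s) = sum alpha~_n s^n."""
        return float(sum(self.probs[n - 1] * s**n for n in self.sizes))

    def pgf_deriv(self, s: float, order: int = 1) -> float:
        """order-th derivative of the pgf at s."""
        total = 0.0
        for n in self.sizes:
            if n >= order:
                total += self.probs[n - 1] * math.perm(n, order) * s ** (n - order)
        return float(total)

    def factorial_moment(self, i: int) -> float:
        return factorial_moment(self, i)

    def geometric_reference_moment(self, i: int) -> float:
        """i-th factorial moment of Geom(1/mu_H~): i! mu (mu-1)^(i-1)."""
        if i == 0:
            return 1.0
        mu = self.mean
        return math.factorial(i) * mu * (mu - 1.0) ** (i - 1)

    def unbias(self) -> HouseholdSizeDistribution:
        """Recover the household distribution: alpha_n proportional to alpha~_n / n."""
        w = self.probs / self.sizes
        return HouseholdSizeDistribution(w / w.sum())


def size_bias(dist: HouseholdSizeDistribution) -> SizeBiasedDistribution:
    """Size-bias a household distribution: alpha~_n = n alpha_n / mu_H."""
    w = dist.sizes * dist.probs
    return SizeBiasedDistribution(w / w.sum())


def factorial_moment(sb: SizeBiasedDistribution, i: int) -> float:
    """E[H~ (H~-1) ... (H~-i+1)]; equals 1 for i = 0 and mu_H~ for i = 1."""
    if i < 0:
        raise ValueError("factorial moment order must be >= 0")
    if i == 0:
        return 1.0
    total = 0.0
    for n in sb.sizes:
        if n >= i:
            total += sb.probs[n - 1] * math.perm(n, i)
    return float(total)


def common_size(n: int) -> HouseholdSizeDistribution:
    """All households of size n."""
    if n < 1:
        raise ValueError("household size must be >= 1")
    p = np.zeros(n)
    p[-1] = 1.0
    return HouseholdSizeDistribution(p)


def two_point_tilde(n: int, p: float) -> HouseholdSizeDistribution:
    """Household distribution with size-biased law P(H~=n)=p, P(H~=1)=1-p.

    A fraction ``p`` of *individuals* live in households of size ``n`` and
    the rest live alone; the household-level probabilities are
    ``alpha_1 = n(1-p) / (n(1-p) + p)`` and ``alpha_n = p / (n(1-p) + p)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 2:
        raise ValueError("n must exceed 1")
    tilde = np.zeros(n)
    tilde[0] = 1.0 - p
    tilde[n - 1] = p
    return SizeBiasedDistribution(tilde).unbias()


def geometric_size_biased(mu: float, n_max: int = 30) -> HouseholdSizeDistribution:
    """Logarithmic household distribution whose size-biased version is geometric.

    ``H~ ~ Geom(1/mu)`` (support 1, 2, ...) truncated at ``n_max`` and
    renormalised; the returned household distribution satisfies
    ``alpha_n proportional to alpha~_n / n``.  For ``mu = 1`` this is a point
    mass at size 1.  The untruncated geometric is the unique size-biased law
    for which disease-induced and vaccine-induced herd immunity coincide for
    every global infection rate in the highly locally infectious regime.
    """
    if mu < 1.0:
        raise ValueError("mu must be >= 1")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if mu == 1.0:
        return common_size(1)
    theta = 1.0 / mu
    n = np.arange(1, n_max + 1)
    tilde = theta * (1.0 - theta) ** (n - 1)
    truncated_mass = 1.0 - tilde.sum()
    dist = SizeBiasedDistribution(tilde / tilde.sum()).unbias()
    # expose the truncated tail mass as metadata for callers that care
    object.__setattr__(dist, "truncated_mass", float(truncated_mass))
    return dist


def _tilde_feasible_var(mean: float, n_max: int) -> tuple[float, float]:
    """Variance range attainable on integer support {1..n_max} at given mean."""
    lo_floor = math.floor(mean)
    var_min = (mean - lo_floor) * (lo_floor + 1 - mean) if mean != lo_floor else 0.0
    var_max = (mean - 1.0) * (n_max - mean)
    return var_min, var_max


def random_household_distribution(
    seed: int,
    n_max: int,
    target_mean_tilde: float,
    target_var_tilde: float,
    tol: float = 1e-6,
) -> HouseholdSizeDistribution:
    """Synthetic household distribution with prescribed size-biased moments.

    Construction (in size-biased space): an exact base distribution is built
    as a mixture of the minimal-variance two-point law on the adjacent
    integers bracketing the target mean and the maximal-variance two-point
    law on {1, n_max}, with the mixing weight chosen so that the mean and
    variance of ``H~`` match the targets exactly.  A seeded Dirichlet
    perturbation is then blended in, its weight halved until the moments are
    within ``tol`` of the targets, which keeps the output deterministic for
    a given seed while varying the shape beyond the two-point skeleton.
    """
    m, v = float(target_mean_tilde), float(target_var_tilde)
    if not (1.0 <= m <= n_max):
        raise ValueError(f"target size-biased mean must lie in [1, {n_max}]")
    var_min, var_max = _tilde_feasible_var(m, n_max)
    if not (var_min - 1e-12 <= v <= var_max + 1e-12):
        raise ValueError(
            f"target size-biased variance {v} infeasible for mean {m} on "
            f"support 1..{n_max}; feasible range is [{var_min}, {var_max}]"
        )

    def two_point(lo: int, hi: int) -> np.ndarray:
        p = np.zeros(n_max)
        if hi == lo:
            p[lo - 1] = 1.0
        else:
            w_hi = (m - lo) / (hi - lo)
            p[lo - 1] = 1.0 - w_hi
            p[hi - 1] = w_hi
        return p

    if m == math.floor(m):
        base_narrow = two_point(int(m), int(m))
    else:
        base_narrow = two_point(math.floor(m), math.floor(m) + 1)
    base_wide = two_point(1, n_max) if n_max > 1 else two_point(1, 1)

    def tilde_moments(p: np.ndarray) -> tuple[float, float]:
        n = np.arange(1, n_max + 1)
        mean = float(np.dot(n, p))
        return mean, float(np.dot(n**2, p) - mean * mean)

    v_narrow = tilde_moments(base_narrow)[1]
    v_wide = tilde_moments(base_wide)[1]
    if abs(v_wide - v_narrow) < 1e-15:
        w = 0.0
    else:
        w = (v - v_narrow) / (v_wide - v_narrow)
    w = min(max(w, 0.0), 1.0)
    exact = (1.0 - w) * base_narrow + w * base_wide

    rng = np.random.default_rng(seed)
    noise = rng.dirichlet(np.ones(n_max))
    eta = 0.1
    candidate = exact
    while eta > 1e-18:
        trial = (1.0 - eta) * exact + eta * noise
        tm, tv = tilde_moments(trial)
        if abs(tm - m) <= tol and abs(tv - v) <= tol:
            candidate = trial
            break
        eta *= 0.5
    return SizeBiasedDistribution(candidate).unbias()


# ---------------------------------------------------------------------------
# infectious / latent period laws
# ---------------------------------------------------------------------------


class InfectiousPeriodLaw:
    """Law of the infectious period T_I.

    Subclasses expose the mean, the variance and the Laplace transform
    ``phi(theta) = E[exp(-theta T_I)]``, which is all the final-outcome
    theory requires.  ``phi`` is 1 at 0, strictly decreasing and convex.
    """

    kind: str = "abstract"

    @property
    def mean(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def var(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def phi(self, theta: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size: int):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def is_markov(self) -> bool:
        return isinstance(self, ExponentialLaw)


@dataclass(frozen=True)
class ExponentialLaw(InfectiousPeriodLaw):
    """Exponential period with rate gamma, mean 1/gamma."""

    gamma: float = 1.0
    kind: str = field(default="exponential", init=False)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("rate must be positive")

    @property
    def mean(self) -> float:
        return 1.0 / self.gamma

    @property
    def var(self) -> float:
        return 1.0 / self.gamma**2

    def phi(self, theta: float) -> float:
        if math.isinf(theta):
            return 0.0
        return self.gamma / (self.gamma + theta)

    def sample(self, rng: np.random.Generator, size: int):
        return rng.exponential(self.mean, size)


@dataclass(frozen=True)
class FixedLaw(InfectiousPeriodLaw):
    """Non-random period of fixed duration."""

    duration: float = 1.0
    kind: str = field(default="fixed", init=False)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def mean(self) -> float:
        return self.duration

    @property
    def var(self) -> float:
        return 0.0

    def phi(self, theta: float) -> float:
        if math.isinf(theta):
            return 0.0
        return math.exp(-theta * self.duration)

    def sample(self, rng: np.random.Generator, size: int):
        return np.full(size, self.duration)


@dataclass(frozen=True)
class ErlangLaw(InfectiousPeriodLaw):
    """Erlang (gamma with integer shape) period."""

    shape: int = 2
    rate: float = 2.0
    kind: str = field(default="erlang", init=False)

    def __post_init__(self) -> None:
        if self.shape < 1 or self.rate <= 0:
            raise ValueError("shape must be >= 1 and rate positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def var(self) -> float:
        return self.shape / self.rate**2

    def phi(self, theta: float) -> float:
        if math.isinf(theta):
            return 0.0
        return (self.rate / (self.rate + theta)) ** self.shape

    def sample(self, rng: np.random.Generator, size: int):
        return rng.gamma(self.shape, 1.0 / self.rate, size)
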