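"""Event-driven stochastic simulation of the SEIR households model.

Used to validate the analytic final-size machinery: the per-household
outcome proportions, the population final size z, threshold behaviour and
the empirical disease-induced herd immunity level along a single
realisation.

Two simulation engines are provided behind one interface:

* a Gillespie (exact event-time) engine when both periods are exponential
  (Markov dynamics), which can also record the trajectory of the household
  census needed for the empirical residual threshold R_V^(m)(t);
* a Sellke-threshold engine for arbitrary period laws (fixed, Erlang, ...):
  each susceptible draws an Exp(1) infection-pressure threshold and becomes
  infected when its accumulated exposure (global pressure integrated over
  the whole population plus local pressure from infectious housemates)
  exceeds it.  Only final outcomes are reported in this mode.

``lambda_L = inf`` is honoured exactly: a household is fully infected as
soon as any member is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .distributions import (
    ExponentialLaw,
    HouseholdSizeDistribution,
    InfectiousPeriodLaw,
)

__all__ = [
    "Population",
    "build_population",
    "SimulationOutcome",
    "simulate",
    "empirical_household_outcomes",
    "empirical_h_D",
]


@dataclass(frozen=True)
class Population:
    """Fixed household structure: sizes of the m households."""

    sizes: np.ndarray

    @property
    def m(self) -> int:
        return int(self.sizes.size)

    @property
    def N(self) -> int:
        return int(self.sizes.sum())

    def size_counts(self) -> dict:
        vals, counts = np.unique(self.sizes, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def build_population(
    dist: HouseholdSizeDistribution,
    m: int,
    mode: str = "exact",
    seed: Optional[int] = None,
) -> Population:
    """Construct m households with sizes from dist.

    ``mode='exact'`` rounds m * alpha_n with a largest-remainder correction,
    so empirical frequencies match the distribution as closely as integers
    allow; ``mode='sampled'`` draws sizes i.i.d. with the given seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        sizes = rng.choice(dist.sizes, size=m, p=dist.probs)
    elif mode == "exact":
        quota = m * dist.probs
        counts = np.floor(quota).astype(int)
        remainder = quota - counts
        short = m - counts.sum()
        for idx in np.argsort(-remainder)[:short]:
            counts[idx] += 1
        sizes = np.repeat(dist.sizes, counts)
    else:
        raise ValueError("mode must be 'exact' or 'sampled'")
    return Population(sizes=np.sort(sizes)[::-1].copy())


@dataclass
class SimulationOutcome:
    """Result of one epidemic realisation."""

    infected_per_household: np.ndarray
    sizes: np.ndarray
    final_fraction: float
    trajectory: Optional[list] = None  # [(t, S_frac, RV)] for Markov runs

    def per_size_histogram(self, n: int) -> np.ndarray:
        mask = self.sizes == n
        counts = np.bincount(self.infected_per_household[mask], minlength=n + 1)
        return counts[: n + 1]


def _gillespie(
    pop: Population,
    lambda_G: float,
    lambda_L: float,
    gamma: float,
    delta: Optional[float],
    rng: np.random.Generator,
    track_rv: bool,
    rv_weights: Optional[np.ndarray],
    mu_H: float,
    mean_TI: float,
) -> SimulationOutcome:
    sizes = pop.sizes
    m, N = pop.m, pop.N
    local_inf = math.isinf(lambda_L)
    S = sizes.astype(np.int64).copy()
    E = np.zeros(m, dtype=np.int64)
    I = np.zeros(m, dtype=np.int64)

    # initial infective uniformly at random in the population
    h0 = rng.choice(m, p=sizes / N)
    S[h0] -= 1
    if local_inf:
        # whole household becomes infectious on introduction
        I[h0] += 1 + S[h0]
        S[h0] = 0
    else:
        I[h0] += 1

    t = 0.0
    traj = [] if track_rv else None

    def record() -> None:
        S_frac = S.sum() / N
        RV = lambda_G * mean_TI * float(rv_weights[S].sum()) / m / mu_H
        traj.append((t, S_frac, RV))

    if track_rv:
        record()

    total_I = int(I.sum())
    total_E = int(E.sum())
    while total_I + total_E > 0:
        rate_global = lambda_G * total_I * S.sum() / N
        rate_local = 0.0 if local_inf else lambda_L * float((S * I).sum())
        rate_latent = (delta or 0.0) * total_E
        rate_recover = gamma * total_I
        rate_total = rate_global + rate_local + rate_latent + rate_recover
        t += rng.exponential(1.0 / rate_total)
        u = rng.uniform() * rate_total
        if u < rate_global:
            # global contact with a uniformly chosen susceptible
            w = S.astype(float)
            h = rng.choice(m, p=w / w.sum())
            _infect(S, E, I, h, delta, local_inf)
        elif u < rate_global + rate_local:
            w = (S * I).astype(float)
            h = rng.choice(m, p=w / w.sum())
            _infect(S, E, I, h, delta, local_inf)
        elif u < rate_global + rate_local + rate_latent:
            w = E.astype(float)
            h = rng.choice(m, p=w / w.sum())
            E[h] -= 1
            I[h] += 1
        else:
            w = I.astype(float)
            h = rng.choice(m, p=w / w.sum())
            I[h] -= 1
        total_I = int(I.sum())
        total_E = int(E.sum())
        if track_rv:
            record()

    infected = sizes - S
    return SimulationOutcome(
        infected_per_household=infected.astype(int),
        sizes=sizes,
        final_fraction=float(infected.sum()) / N,
        trajectory=traj,
    )


def _infect(S, E, I, h, delta, local_inf) -> None:
    S[h] -= 1
    if local_inf:
        extra = S[h]
        S[h] = 0
    else:
        extra = 0
    if delta is None:
        I[h] += 1 + extra
    else:
        E[h] += 1 + extra


def _sellke(
    pop: Population,
    lambda_G: float,
    lambda_L: float,
    T_E_law: Optional[InfectiousPeriodLaw],
    T_I_law: InfectiousPeriodLaw,
    rng: np.random.Generator,
) -> SimulationOutcome:
    """Sellke-threshold construction (final outcome only, any period laws).

    The final outcome depends only on the Exp(1) thresholds and the
    infectious periods, not on event timing, so infections are processed in
    vectorised cascade rounds: each round applies the full global and local
    exposure of the newly infected batch and recruits every susceptible
    whose threshold is exceeded.  The latent period plays no role in the
    final outcome and is not sampled.
    """
    sizes = pop.sizes
    m, N = pop.m, pop.N
    local_inf = math.isinf(lambda_L)

    offsets = np.concatenate([[0], np.cumsum(sizes)])
    house_of = np.repeat(np.arange(m), sizes)
    thresholds = rng.exponential(1.0, N)
    periods = np.asarray(T_I_law.sample(rng, N), dtype=float)
    infected = np.zeros(N, dtype=bool)
    pressure = np.zeros(N)

    active = np.array([rng.integers(N)], dtype=int)
    infected[active] = True
    while active.size:
        if local_inf:
            # whole households of active cases become infected immediately
            extra = []
            for j in active:
                lo, hi = offsets[house_of[j]], offsets[house_of[j] + 1]
                fresh = np.arange(lo, hi)[~infected[lo:hi]]
                infected[fresh] = True
                extra.append(fresh)
            if extra:
                active = np.concatenate([active] + extra)
        # global exposure from the batch
        pressure += lambda_G * periods[active].sum() / N
        # local exposure, per household of each active case
        if not local_inf and lambda_L > 0:
            for j in active:
                lo, hi = offsets[house_of[j]], offsets[house_of[j] + 1]
                pressure[lo:hi] += lambda_L * periods[j]
        newly = (~infected) & (pressure > thresholds)
        infected |= newly
        active = np.nonzero(newly)[0]

    per_house = np.add.reduceat(infected.astype(int), offsets[:-1])
    return SimulationOutcome(
        infected_per_household=per_house.astype(int),
        sizes=sizes,
        final_fraction=float(infected.sum()) / N,
    )


def simulate(
    pop: Population,
    lambda_G: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
    T_E: Optional[InfectiousPeriodLaw] = None,
    seed: Optional[int] = None,
    track_rv: bool = False,
    engine: str = "auto",
) -> SimulationOutcome:
    """Run one epidemic with a single uniformly chosen initial infective.

    ``engine='auto'`` uses the Gillespie engine for Markov laws (exponential
    periods, or no latency) and the Sellke construction otherwise;
    ``engine='sellke'`` forces the (much faster, final-outcome-only) Sellke
    cascade, which is valid for any laws.  ``track_rv`` (Markov/Gillespie
    only) records (t, S fraction, R_V^(m)(t)) at every event for the
    empirical herd-immunity computation.
    """
    rng = np.random.default_rng(seed)
    markov = isinstance(T_I, ExponentialLaw) and (T_E is None or isinstance(T_E, ExponentialLaw))
    if track_rv and (not markov or engine == "sellke"):
        raise ValueError("trajectory tracking requires Markov (exponential) laws")
    if engine not in ("auto", "gillespie", "sellke"):
        raise ValueError("engine must be 'auto', 'gillespie' or 'sellke'")
    if engine == "gillespie" and not markov:
        raise ValueError("the Gillespie engine requires Markov laws")
    if markov and engine != "sellke":
        from .final_size import single_household_mean_size

        mu_s = np.array(
            [
                single_household_mean_size(s, lambda_L, T_I.phi)
                for s in range(int(pop.sizes.max()) + 1)
            ]
        )
        rv_weights = np.arange(len(mu_s)) * mu_s
        mu_H = pop.N / pop.m
        delta = T_E.gamma if T_E is not None else None
        return _gillespie(
            pop,
            lambda_G,
            lambda_L,
            T_I.gamma,
            delta,
            rng,
            track_rv,
            rv_weights,
            mu_H,
            T_I.mean,
        )
    return _sellke(pop, lambda_G, lambda_L, T_E, T_I, rng)


def empirical_household_outcomes(outcomes: list, n: int, cutoff: float) -> np.ndarray:
    """Empirical (P_{n,v}) among major outbreaks (final fraction > cutoff)."""
    major = [o for o in outcomes if o.final_fraction > cutoff]
    if not major:
        raise ValueError("no major outbreaks above the classification cutoff")
    hist = np.zeros(n + 1)
    for o in major:
        hist += o.per_size_histogram(n)
    return hist / hist.sum()


def empirical_h_D(
    pop: Population,
    lambda_G: float,
    lambda_L: float,
    T_I: ExponentialLaw,
    T_E: Optional[ExponentialLaw] = None,
    seed: Optional[int] = None,
    cutoff: float = 0.05,
) -> Optional[float]:
    """Empirical disease-induced herd immunity level along one realisation.

    Tracks the empirical residual threshold R_V^(m)(t) (piecewise constant
    between events) and returns 1 - S^(m)(T_*) at its first crossing of
    one.  Minor outbreaks (final fraction below the cutoff) return None.
    """
    out = simulate(pop, lambda_G, lambda_L, T_I, T_E, seed=seed, track_rv=True)
    if out.final_fraction <= cutoff:
        return None
    for t, S_frac, RV in out.trajectory:
        if RV <= 1.0:
            return 1.0 - S_frac
    return None
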