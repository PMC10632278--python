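"""Deterministic (many-households) limit of the SIR/SEIR households model.

The state is the density ``h_{s,e,i,r}(t)`` of households with s
susceptible, e exposed, i infectious and r recovered members
(1 <= s+e+i+r <= n_max; the SIR variant lives on the e = 0 slice of the
state space and is integrated on its own, smaller system).  The dynamics
combine latency progression (rate delta e), recovery (rate gamma i),
global infection of a susceptible (rate kappa lambda_G i_bar(t) s, with
i_bar the population density of infectives) and local infection
(rate lambda_L s i):

    dh/dt = delta(-e h_{s,e,i,r} + (e+1) h_{s,e+1,i-1,r})
          + gamma(-i h_{s,e,i,r} + (i+1) h_{s,e,i+1,r-1})
          + kappa lambda_G i_bar(t) (-s h_{s,e,i,r} + (s+1) h_{s+1,e-1,i,r})
          + lambda_L (-s i h_{s,e,i,r} + (s+1) i h_{s+1,e-1,i,r}),

with out-of-range states treated as zero.  Mass within each household-size
class is conserved.

The disease-induced herd immunity level h_D is read off the trajectory: the
residual threshold parameter of a fresh epidemic among the remaining
susceptibles is

    R_V(t) = (lambda_G E[T_I] / mu_H) sum_states h_{s,e,i,r}(t) s mu_s(lambda_L)

(each of the s remaining susceptibles in such a household would, if
contacted, start a local epidemic among those s members; exposed, infective
and recovered members are immune to the second epidemic).  h_D is
1 - S(T_*) where T_* is the first time R_V crosses one.  Integrating with a
reduced global rate kappa lambda_G, while evaluating R_V with the full
lambda_G, gives the level under constant global restrictions, h^_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .distributions import ExponentialLaw, HouseholdSizeDistribution
from .final_size import single_household_mean_size
from .herd_immunity import HerdImmunityResult

__all__ = [
    "build_state_space",
    "HouseholdODESystem",
    "HouseholdStateDensity",
    "TrajectoryResult",
    "initial_condition",
    "integrate",
    "R_V",
    "h_D",
    "h_D_L",
    "h_hat_D",
    "susceptible_household_profile",
]

_STOP_MASS = 1e-12
_T_MAX = 1e4


def build_state_space(n_max: int, model: str = "SIR") -> list:
    """Ordered list of household states (s, e, i, r), 1 <= s+e+i+r <= n_max.

    The SIR model uses the e = 0 slice.  Ordering is deterministic
    (lexicographic in (n, s, e, i)).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if model not in ("SIR", "SEIR"):
        raise ValueError("model must be 'SIR' or 'SEIR'")
    states = []
    for n in range(1, n_max + 1):
        for s in range(n + 1):
            if model == "SIR":
                for i in range(n - s + 1):
                    states.append((s, 0, i, n - s - i))
            else:
                for e in range(n - s + 1):
                    for i in range(n - s - e + 1):
                        states.append((s, e, i, n - s - e - i))
    return states


@dataclass(frozen=True)
class HouseholdStateDensity:
    """Density over household configurations at a fixed time."""

    states: tuple
    values: np.ndarray
    time: float = 0.0

    def as_dict(self) -> dict:
        return {st: float(v) for st, v in zip(self.states, self.values)}

    def size_mass(self, n: int) -> float:
        mask = [sum(st) == n for st in self.states]
        return float(self.values[np.asarray(mask)].sum())


@dataclass(frozen=True)
class TrajectoryResult:
    """Dense trajectory summary of the deterministic households model."""

    times: np.ndarray
    densities: np.ndarray  # shape (n_states, n_times)
    S: np.ndarray
    i_bar: np.ndarray
    R_V: np.ndarray
    T_star: Optional[float]
    states: tuple
    sol: object = None  # scipy OdeSolution for dense evaluation


class HouseholdODESystem:
    """Precompiled right-hand side of the households ODE on a flat state vector."""

    def __init__(
        self,
        dist: HouseholdSizeDistribution,
        lambda_G: float,
        lambda_L: float,
        gamma: float,
        delta: Optional[float] = None,
    ) -> None:
        self.dist = dist
        self.lambda_G = lambda_G
        self.lambda_L = lambda_L
        self.gamma = gamma
        self.delta = delta
        self.model = "SIR" if delta is None else "SEIR"
        self.states = tuple(build_state_space(dist.n_max, self.model))
        self.index = {st: k for k, st in enumerate(self.states)}
        m = len(self.states)

        # linear part: latency, recovery, local infection (constant rates)
        A = np.zeros((m, m))
        # bilinear part: global infection, to be scaled by kappa*lambda_G*i_bar(t)
        B = np.zeros((m, m))
        for (s, e, i, r), k in self.index.items():
            if self.model == "SEIR" and e > 0:
                rate = delta * e
                A[k, k] -= rate
                A[self.index[(s, e - 1, i + 1, r)], k] += rate
            if i > 0:
                rate = gamma * i
                A[k, k] -= rate
                A[self.index[(s, e, i - 1, r + 1)], k] += rate
            if s > 0 and i > 0 and lambda_L > 0:
                rate = lambda_L * s * i
                A[k, k] -= rate
                tgt = (s - 1, e + 1, i, r) if self.model == "SEIR" else (s - 1, e, i + 1, r)
                A[self.index[tgt], k] += rate
            if s > 0:
                B[k, k] -= s
                tgt = (s - 1, e + 1, i, r) if self.model == "SEIR" else (s - 1, e, i + 1, r)
                B[self.index[tgt], k] += s
        self.A = A
        self.B = B
        self.w_i = np.array([st[2] for st in self.states], dtype=float)
        self.w_s = np.array([st[0] for st in self.states], dtype=float)
        self.w_ei = np.array([st[1] + st[2] for st in self.states], dtype=float)
        self.mu_H = dist.mean
        # s * mu_s(lambda_L) weights for the residual threshold parameter
        phi = ExponentialLaw(gamma).phi
        mu_s = [single_household_mean_size(s, lambda_L, phi) for s in range(dist.n_max + 1)]
        self.w_RV = np.array([st[0] * mu_s[st[0]] for st in self.states])

    def rhs(self, kappa: float):
        # force of infection on one susceptible: (lambda_G / N) * (total
        # infectives) = lambda_G * i_bar / mu_H with i_bar per household
        A, B, w_i = self.A, self.B, self.w_i
        c = kappa * self.lambda_G / self.mu_H

        def f(t, h):
            return A @ h + (c * (w_i @ h)) * (B @ h)

        return f

    def derivative(self, density: HouseholdStateDensity, kappa: float = 1.0) -> np.ndarray:
        """Instantaneous rate of change at a given state density."""
        return self.rhs(kappa)(density.time, density.values)

    def S_of(self, h: np.ndarray) -> float:
        """Susceptible fraction of the population."""
        return float(self.w_s @ h) / self.mu_H

    def R_V_of(self, h: np.ndarray) -> float:
        """Residual threshold parameter, always with the unreduced lambda_G."""
        return self.lambda_G * (1.0 / self.gamma) * float(self.w_RV @ h) / self.mu_H


def initial_condition(
    dist: HouseholdSizeDistribution, epsilon: float, model: str = "SIR"
) -> HouseholdStateDensity:
    """Seed a fraction epsilon of households (of the largest size) with one infective."""
    n_max = dist.n_max
    alpha_top = dist.probs[n_max - 1]
    if not 0.0 <= epsilon < alpha_top:
        raise ValueError(f"epsilon must lie in [0, alpha_nmax = {alpha_top})")
    states = build_state_space(n_max, model)
    index = {st: k for k, st in enumerate(states)}
    h = np.zeros(len(states))
    for n in dist.sizes:
        h[index[(int(n), 0, 0, 0)]] = dist.probs[n - 1]
    h[index[(n_max, 0, 0, 0)]] -= epsilon
    h[index[(n_max - 1, 0, 1, 0)]] += epsilon
    return HouseholdStateDensity(states=tuple(states), values=h, time=0.0)


def integrate(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    gamma: float,
    delta: Optional[float] = None,
    epsilon: float = 1e-5,
    kappa: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    t_max: float = _T_MAX,
    n_eval: int = 400,
) -> TrajectoryResult:
    """Integrate the households ODE until the epidemic burns out.

    The global infection rate is kappa * lambda_G; the recorded residual
    threshold R_V(t) always uses the unreduced lambda_G.  T_star is the
    first time R_V crosses one (located on the dense interpolant), or None
    if R_V stays above one for the whole trajectory or starts below it.
    """
    system = HouseholdODESystem(dist, lambda_G, lambda_L, gamma, delta)
    model = system.model
    ic = initial_condition(dist, epsilon, model)
    f = system.rhs(kappa)

    def extinct(t, h):
        return float(system.w_ei @ h) - _STOP_MASS

    extinct.terminal = True
    extinct.direction = -1

    def rv_cross(t, h):
        return system.R_V_of(h) - 1.0

    rv_cross.terminal = False
    rv_cross.direction = -1

    sol = solve_ivp(
        f,
        (0.0, t_max),
        ic.values,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=[extinct, rv_cross],
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    t_end = sol.t[-1]
    times = np.linspace(0.0, t_end, n_eval)
    H = sol.sol(times)
    S = np.array([system.S_of(H[:, j]) for j in range(H.shape[1])])
    i_bar = system.w_i @ H
    RV = np.array([system.R_V_of(H[:, j]) for j in range(H.shape[1])])
    T_star = float(sol.t_events[1][0]) if len(sol.t_events[1]) else None
    return TrajectoryResult(
        times=times,
        densities=H,
        S=S,
        i_bar=i_bar,
        R_V=RV,
        T_star=T_star,
        states=system.states,
        sol=sol,
    )


def R_V(density: HouseholdStateDensity, dist, lambda_G, lambda_L, gamma) -> float:
    """Residual threshold parameter of a fresh epidemic at a given state."""
    system = HouseholdODESystem(dist, lambda_G, lambda_L, gamma)
    if density.states != system.states:
        # allow SEIR densities against an SEIR system
        system = HouseholdODESystem(dist, lambda_G, lambda_L, gamma, delta=1.0)
        if density.states != system.states:
            raise ValueError("state density does not match the system's state space")
    return system.R_V_of(density.values)


def _level_from_trajectory(traj: TrajectoryResult, system: HouseholdODESystem, kind: str, kappa=None) -> HerdImmunityResult:
    if traj.T_star is None:
        raise RuntimeError(
            "R_V never crossed one before epidemic extinction; "
            "herd immunity not reached along this trajectory"
        )
    h_at = traj.sol.sol(traj.T_star)
    S = system.S_of(h_at)
    return HerdImmunityResult(
        level=1.0 - S,
        kind=kind,
        kappa_hat=kappa,
        residual_R=system.R_V_of(h_at),
    )


def h_D(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    gamma: float,
    epsilon: float = 1e-5,
    **kw,
) -> HerdImmunityResult:
    """Disease-induced herd immunity level of the deterministic SIR model."""
    system = HouseholdODESystem(dist, lambda_G, lambda_L, gamma)
    traj = integrate(dist, lambda_G, lambda_L, gamma, epsilon=epsilon, **kw)
    return _level_from_trajectory(traj, system, "h_D")


def h_D_L(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    gamma: float,
    delta: float,
    epsilon: float = 1e-5,
    **kw,
) -> HerdImmunityResult:
    """Disease-induced herd immunity level of the deterministic SEIR model."""
    system = HouseholdODESystem(dist, lambda_G, lambda_L, gamma, delta)
    traj = integrate(dist, lambda_G, lambda_L, gamma, delta=delta, epsilon=epsilon, **kw)
    return _level_from_trajectory(traj, system, "h_D_L")


def h_hat_D(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    gamma: float,
    delta: Optional[float] = None,
    kappa: float = 1.0,
    epsilon: float = 1e-5,
    **kw,
) -> HerdImmunityResult:
    """Herd immunity level with constant global restrictions of strength kappa.

    The first epidemic runs with global rate kappa * lambda_G; R_V is
    evaluated with the unreduced lambda_G.  Raises if the restrictions are
    so severe (kappa <= kappa^) that R_V never reaches one.
    """
    if not 0.0 < kappa <= 1.0:
        raise ValueError("kappa must lie in (0, 1]")
    system = HouseholdODESystem(dist, lambda_G, lambda_L, gamma, delta)
    traj = integrate(dist, lambda_G, lambda_L, gamma, delta=delta, epsilon=epsilon, kappa=kappa, **kw)
    kind = "h_hat_D" if kappa < 1.0 else ("h_D" if delta is None else "h_D_L")
    return _level_from_trajectory(traj, system, kind, kappa=kappa)


def susceptible_household_profile(density: HouseholdStateDensity, size: Optional[int] = None) -> np.ndarray:
    """Marginal distribution of the number of susceptibles per household.

    With ``size`` given, conditions on households of that size (entries
    0..size); otherwise marginalises over all households (entries 0..n_max).
    """
    states = density.states
    n_max = max(sum(st) for st in states)
    if size is None:
        out = np.zeros(n_max + 1)
        for st, v in zip(states, density.values):
            out[st[0]] += v
    else:
        out = np.zeros(size + 1)
        for st, v in zip(states, density.values):
            if sum(st) == size:
                out[st[0]] += v
    total = out.sum()
    if total <= 0:
        raise ValueError("empty profile")
    return out / total
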