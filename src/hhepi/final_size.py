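"""Final-outcome algebra for household epidemics.

Single-household quantities
---------------------------
For a household of size ``n`` with person-to-person local infection rate
``lambda_L`` and infectious-period Laplace transform ``phi``, the mean final
size (including the initial case) of a local epidemic started by one
introduced infective is

    mu_n(lambda_L) = n - sum_{k=1}^{n-1} C(n-1, k) beta_k phi(k lambda_L)^{n-k},

where the Gontcharoff-type coefficients ``beta_k`` solve the unit
lower-triangular system sum_{i<=k} C(k,i) beta_i phi(i lambda_L)^{k-i} = k.
With ``Bin(n, 1-pi)`` members infected from outside (each member escaping
global infection independently with probability ``pi``) the mean final size
is

    mu~_n(lambda_L, pi) = n - sum_{k=1}^{n} C(n, k) phi(k lambda_L)^{n-k} pi^k beta_k.

Population fixed point
----------------------
In the many-households limit, the fraction ``z`` infected by a major
outbreak solves

    z = sum_n alpha~_n mu~_n(lambda_L, pi) / n,   pi = exp(-lambda_G E[T_I] z),

with ``z = 0`` the disease-free solution and a second root in (0,1) exactly
when the household reproduction number R_* exceeds one.  The per-household
outcome proportions ``P_{n,v}`` (fraction of size-n households with v
ultimately infected) solve a triangular system due to Addy, Longini and
Haber, solved here by forward substitution in ``v``.

``lambda_L = inf`` is dispatched to closed forms: the whole household is
infected as soon as any member is (mu_n = n, mu~_n = n(1 - pi^n),
P_{n,0} = pi^n, P_{n,n} = 1 - pi^n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .distributions import HouseholdSizeDistribution, InfectiousPeriodLaw

__all__ = [
    "beta_coefficients",
    "single_household_mean_size",
    "mixed_initial_mean_size",
    "household_outcome_distribution",
    "final_size",
    "FinalSizeSolution",
]

#: tolerated negativity in triangular-system solutions before clipping
_NEG_TOL = 1e-9


def beta_coefficients(lambda_L: float, phi, k_max: int) -> np.ndarray:
    """Solve the beta recursion by forward substitution; returns beta_1..beta_k_max."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if math.isinf(lambda_L):
        # phi(i*inf) = 0 for i >= 1, so only the i = k term survives: beta_k = k
        return np.arange(1, k_max + 1, dtype=float)
    beta = np.zeros(k_max + 1)  # beta[0] unused
    for k in range(1, k_max + 1):
        acc = float(k)
        for i in range(1, k):
            acc -= math.comb(k, i) * beta[i] * phi(i * lambda_L) ** (k - i)
        beta[k] = acc  # coefficient of beta_k is C(k,k) phi(...)^0 = 1
    return beta[1:]


def single_household_mean_size(n: int, lambda_L: float, phi) -> float:
    """Mean final size mu_n(lambda_L) with one initial infective; mu_0 = 0."""
    if n < 0:
        raise ValueError("household size must be non-negative")
    if n == 0:
        return 0.0
    if lambda_L == 0.0:
        return 1.0
    if math.isinf(lambda_L):
        return float(n)
    beta = beta_coefficients(lambda_L, phi, max(n - 1, 1))
    total = float(n)
    for k in range(1, n):
        total -= math.comb(n - 1, k) * beta[k - 1] * phi(k * lambda_L) ** (n - k)
    return total


def mixed_initial_mean_size(n: int, lambda_L: float, phi, pi: float) -> float:
    """Mean final size mu~_n(lambda_L, pi) with Bin(n, 1-pi) introductions."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if n == 0:
        return 0.0
    if pi == 0.0:
        return float(n)
    if math.isinf(lambda_L):
        return n * (1.0 - pi**n)
    beta = beta_coefficients(lambda_L, phi, n)
    total = float(n)
    for k in range(1, n + 1):
        total -= math.comb(n, k) * phi(k * lambda_L) ** (n - k) * pi**k * beta[k - 1]
    return total


def household_outcome_distribution(n: int, lambda_L: float, phi, pi: float) -> np.ndarray:
    """Outcome proportions (P_{n,0}, ..., P_{n,n}) among size-n households.

    Solves the Addy–Longini–Haber triangular system
    sum_{i<=v} C(n-i, v-i) P_{n,i} / (phi((n-v) lambda_L)^i pi^{n-v}) = C(n, v)
    forward in v.  Entries are clipped to [0, 1]; negativity beyond a small
    tolerance (ill-conditioning at large n / extreme parameters) raises.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if n < 1:
        raise ValueError("household size must be >= 1")
    P = np.zeros(n + 1)
    if pi == 0.0:
        P[n] = 1.0
        return P
    if math.isinf(lambda_L):
        P[0] = pi**n
        P[n] = 1.0 - pi**n
        return P
    for v in range(n + 1):
        phi_v = phi((n - v) * lambda_L)
        acc = float(math.comb(n, v))
        for i in range(v):
            acc -= math.comb(n - i, v - i) * P[i] / (phi_v**i * pi ** (n - v))
        P[v] = acc * phi_v**v * pi ** (n - v)
    if np.any(P < -_NEG_TOL):
        raise FloatingPointError(
            f"outcome distribution for n={n} severely negative "
            f"(min {P.min():.3e}); system ill-conditioned"
        )
    P = np.clip(P, 0.0, 1.0)
    return P / P.sum()


@dataclass(frozen=True)
class FinalSizeSolution:
    """Law-of-large-numbers final outcome of a households epidemic.

    Attributes
    ----------
    z
        Fraction of the population ultimately infected.
    pi
        Probability of avoiding global infection, exp(-lambda_G_eff E[T_I] z).
    outcome_dists
        Mapping size n -> array (P_{n,0}, ..., P_{n,n}).
    """

    z: float
    pi: float
    outcome_dists: dict


def final_size(
    dist: HouseholdSizeDistribution,
    lambda_G_effective: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
) -> FinalSizeSolution:
    """Largest root z in [0, 1) of the household final-size fixed point.

    ``lambda_G_effective`` is the global contact rate actually operating
    during the epidemic (e.g. kappa * lambda_G under restrictions).
    Returns z = 0 (pi = 1) when the epidemic is subcritical.
    """
    from .reproduction import R_star  # local import to avoid a cycle

    sb = dist.size_biased()
    phi = T_I.phi
    mean_TI = T_I.mean
    rate = lambda_G_effective * mean_TI

    def rhs(z: float) -> float:
        pi = math.exp(-rate * z)
        total = 0.0
        for n in sb.sizes:
            a = sb.probs[n - 1]
            if a > 0.0:
                total += a * mixed_initial_mean_size(n, lambda_L, phi, pi) / n
        return total

    R = R_star(dist, lambda_G_effective, lambda_L, T_I)
    if R <= 1.0:
        z = 0.0
    else:
        f = lambda z: rhs(z) - z
        lo = 1e-10
        hi = 1.0 - 1e-14
        # f(lo) > 0 for supercritical epidemics, f(hi) < 0 always (rhs < 1)
        if f(lo) <= 0.0:  # pragma: no cover - defensive; R_* > 1 guarantees f(lo) > 0
            z = 0.0
        else:
            z = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    pi = math.exp(-rate * z)
    outcome = {
        int(n): household_outcome_distribution(int(n), lambda_L, phi, pi)
        for n in sb.sizes
        if sb.probs[n - 1] > 0.0
    }
    return FinalSizeSolution(z=float(z), pi=float(pi), outcome_dists=outcome)
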