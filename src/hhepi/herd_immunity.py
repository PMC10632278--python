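"""Vaccine-induced and (approximate) disease-induced herd immunity levels.

The vaccine-induced level ``h_C`` is the uniform coverage with a perfect
vaccine at which the post-vaccination threshold parameter R^_U equals one.
The approximate disease-induced level ``h~_D`` is obtained by running a
first epidemic whose global rate is scaled by the smallest factor kappa^
that leaves a second, unrestricted epidemic among the survivors exactly
critical, and reporting the final size of that first epidemic.

In the highly locally infectious regime (lambda_L = inf) both levels have
closed forms driven by the probability-generating function f_H~ of the
size-biased household size distribution:

    h_C   : root of h(1-h) + mu_H~ (1-h)^2 = 1/(lambda_G E[T_I]),
    h~_D  = 1 - f_H~(pi),  with pi solving pi f_H~'(pi) = 1/(lambda_G E[T_I]).

The module also hosts the ordering classifiers comparing h~_D and h_C in
the just-supercritical, high-global and weak-local limits; all three reduce
to comparing moments of H~ with those of the geometric distribution with
the same mean, the unique size-biased law for which h~_D = h_C for every
global rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .distributions import (
    HouseholdSizeDistribution,
    InfectiousPeriodLaw,
    ExponentialLaw,
    SizeBiasedDistribution,
)
from .final_size import final_size
from .reproduction import R0, R_DI_from_outcome, R_star, R_U_hat

__all__ = [
    "HerdImmunityResult",
    "OrderingVerdict",
    "h_C",
    "h_C_highly_local",
    "h_tilde_D",
    "h_tilde_D_highly_local",
    "lambda_G_star_two_sizes",
    "ordering_just_supercritical",
    "ordering_high_global",
    "weak_local_difference",
    "argmax_difference_over_lambda_G",
]

#: relative tolerance for declaring factorial moments equal to the geometric reference
_GEOM_TOL = 1e-9


@dataclass(frozen=True)
class HerdImmunityResult:
    """A herd immunity level together with solver diagnostics."""

    level: float
    kind: str  # "h_C" | "h_tilde_D" | "h_D" | "h_D_L" | "h_hat_D"
    kappa_hat: Optional[float] = None
    pi: Optional[float] = None
    z: Optional[float] = None
    residual_R: Optional[float] = None
    subcritical: bool = False

    def __float__(self) -> float:
        return self.level


@dataclass(frozen=True)
class OrderingVerdict:
    """Outcome of an ordering classifier for h~_D versus h_C."""

    verdict: str  # "h_tilde_D > h_C" | "h_tilde_D < h_C" | "equality" | "inconclusive"
    witness_index: Optional[int] = None
    witness_value: Optional[float] = None
    reference_value: Optional[float] = None


def _degenerate_level(lambda_G: float, mean_TI: float) -> float:
    """Homogeneous-population level 1 - 1/(lambda_G E[T_I])."""
    return 1.0 - 1.0 / (lambda_G * mean_TI)


def h_C(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
) -> HerdImmunityResult:
    """Vaccine-induced herd immunity level: unique c with R^_U(c) = 1."""
    R = R_star(dist, lambda_G, lambda_L, T_I)
    if R <= 1.0:
        return HerdImmunityResult(level=0.0, kind="h_C", residual_R=R, subcritical=True)
    if dist.n_max == 1:
        lvl = _degenerate_level(lambda_G, T_I.mean)
        return HerdImmunityResult(level=lvl, kind="h_C", residual_R=1.0)
    f = lambda c: R_U_hat(dist, lambda_G, lambda_L, T_I, c) - 1.0
    c = brentq(f, 0.0, 1.0, xtol=1e-13, rtol=8.9e-16)
    return HerdImmunityResult(level=float(c), kind="h_C", residual_R=f(c) + 1.0)


def h_C_highly_local(
    dist: HouseholdSizeDistribution, lambda_G: float, T_I: InfectiousPeriodLaw
) -> float:
    """Closed-form h_C in the highly locally infectious regime.

    Root in (0,1) of h(1-h) + mu_H~ (1-h)^2 = 1/(lambda_G E[T_I]); collapses
    to the homogeneous level when mu_H~ = 1.
    """
    mu = dist.size_biased().mean
    x = 1.0 / (lambda_G * T_I.mean)
    if lambda_G * T_I.mean * mu <= 1.0:
        raise ValueError("subcritical: R_* <= 1 in the highly local regime")
    if mu == 1.0:
        return _degenerate_level(lambda_G, T_I.mean)
    return 1.0 - (math.sqrt(1.0 + 4.0 * (mu - 1.0) * x) - 1.0) / (2.0 * (mu - 1.0))


def h_tilde_D(
    dist: HouseholdSizeDistribution,
    lambda_G: float,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
    kappa_tol: float = 1e-10,
) -> HerdImmunityResult:
    """Final-size approximation to the disease-induced herd immunity level.

    Nested solve: for each global-rate scaling kappa, compute the final
    outcome of the reduced epidemic; find kappa^ at which the residual
    threshold parameter of a second, unrestricted epidemic equals one; the
    level is the final size z(kappa^) of the reduced epidemic.
    """
    R = R_star(dist, lambda_G, lambda_L, T_I)
    if R <= 1.0:
        return HerdImmunityResult(level=0.0, kind="h_tilde_D", residual_R=R, subcritical=True)
    if dist.n_max == 1:
        lvl = _degenerate_level(lambda_G, T_I.mean)
        pi = 1.0 - lvl
        return HerdImmunityResult(level=lvl, kind="h_tilde_D", kappa_hat=None, pi=pi, z=lvl, residual_R=1.0)
    if math.isinf(lambda_L):
        return h_tilde_D_highly_local(dist, lambda_G, T_I)

    def residual(kappa: float) -> float:
        sol = final_size(dist, kappa * lambda_G, lambda_L, T_I)
        return R_DI_from_outcome(dist, lambda_G, lambda_L, T_I, sol.outcome_dists) - 1.0

    lo = 1.0 / R + 1e-12
    hi = 1.0
    # residual is decreasing in kappa: larger first epidemic -> fewer susceptibles
    if residual(hi) > 0.0:
        raise RuntimeError("second epidemic remains supercritical even at kappa = 1")
    kappa_hat = brentq(residual, lo, hi, xtol=kappa_tol, rtol=8.9e-16)
    sol = final_size(dist, kappa_hat * lambda_G, lambda_L, T_I)
    return HerdImmunityResult(
        level=sol.z,
        kind="h_tilde_D",
        kappa_hat=float(kappa_hat),
        pi=sol.pi,
        z=sol.z,
        residual_R=residual(kappa_hat) + 1.0,
    )


def h_tilde_D_highly_local(
    dist: HouseholdSizeDistribution, lambda_G: float, T_I: InfectiousPeriodLaw
) -> HerdImmunityResult:
    """Closed-form h~_D for lambda_L = inf.

    Solve pi f_H~'(pi) = 1/(lambda_G E[T_I]) on (0,1) and return
    1 - f_H~(pi).  The implied restriction factor kappa^ follows from
    pi = exp(-kappa^ lambda_G E[T_I] z).
    """
    sb = dist.size_biased()
    c = 1.0 / (lambda_G * T_I.mean)
    if sb.mean <= c:
        raise ValueError("subcritical: R_* <= 1 in the highly local regime")
    if dist.n_max == 1:
        lvl = _degenerate_level(lambda_G, T_I.mean)
        return HerdImmunityResult(level=lvl, kind="h_tilde_D", pi=1.0 - lvl, z=lvl, residual_R=1.0)
    g = lambda p: p * sb.pgf_deriv(p, 1) - c
    # g(0) = -c < 0, g(1) = mu - c > 0, and g is strictly increasing on (0,1)
    pi = brentq(g, 0.0, 1.0, xtol=1e-14, rtol=8.9e-16)
    z = 1.0 - sb.pgf(pi)
    kappa_hat = -math.log(pi) / (lambda_G * T_I.mean * z) if z > 0 else None
    return HerdImmunityResult(
        level=float(z), kind="h_tilde_D", kappa_hat=kappa_hat, pi=float(pi), z=float(z), residual_R=1.0
    )


def lambda_G_star_two_sizes(n: int, p: float, mean_TI: float = 1.0) -> Optional[float]:
    """Crossover global rate for the {1, n} mixture in the highly local regime.

    With a fraction p of individuals in households of size n (the rest
    alone), h~_D > h_C below the returned rate and h~_D < h_C above it.
    Returns None when no crossover exists (n = 2, or p <= (n-2)/(2(n-1))):
    then the ordering has one sign for every supercritical lambda_G.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    if n < 2:
        raise ValueError("n must exceed 1")
    if n == 2 or p <= (n - 2) / (2.0 * (n - 1)):
        return None
    f = lambda x: x ** (n / 2.0 - 1.0) - p * x ** (n - 1) - (1.0 - p)
    pi_hat = brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16)
    return 1.0 / (mean_TI * pi_hat * (1.0 - p + n * p * pi_hat ** (n - 1)))


def _is_geometric_shape(sb: SizeBiasedDistribution, rtol: float = _GEOM_TOL) -> bool:
    """True when alpha~_n has the geometric form theta (1-theta)^{n-1}.

    A geometric truncated at n_max and renormalised keeps exactly constant
    successive ratios, while its high factorial moments deviate from the
    untruncated reference by truncation error alone; classifying on the
    shape avoids mistaking that truncation error for a genuine deviation.
    """
    p = sb.probs
    if sb.n_max == 1:
        return True
    if np.any(p <= 0):
        return False
    ratios = p[1:] / p[:-1]
    return bool(np.all(np.abs(ratios - ratios[0]) <= rtol * max(ratios[0], 1.0)))


def ordering_just_supercritical(sb: SizeBiasedDistribution) -> OrderingVerdict:
    """Ordering of h~_D and h_C for just-supercritical, highly local epidemics.

    Compares factorial moments of H~ with the geometric reference
    k! mu (mu-1)^{k-1}; the first deviating order decides: smaller moment
    means h~_D > h_C.  Distributions whose probabilities are geometric in
    shape (the exact-equality law, possibly truncated) return equality.
    """
    if _is_geometric_shape(sb):
        return OrderingVerdict(verdict="equality")
    for k in range(2, sb.n_max + 1):
        mk = sb.factorial_moment(k)
        ref = sb.geometric_reference_moment(k)
        scale = max(abs(ref), 1.0)
        if abs(mk - ref) > _GEOM_TOL * scale:
            verdict = "h_tilde_D > h_C" if mk < ref else "h_tilde_D < h_C"
            return OrderingVerdict(verdict=verdict, witness_index=k, witness_value=mk, reference_value=ref)
    return OrderingVerdict(verdict="equality")


def ordering_high_global(sb: SizeBiasedDistribution) -> OrderingVerdict:
    """Ordering of h~_D and h_C for highly local *and* highly global epidemics.

    Based on the derivatives at 0 of
    G(pi) = f(1-f) + mu f^2 - pi f', with f = f_H~:
    G^(n)(0)/n! = (1-n) a~_n + (mu-1) sum_k a~_{n-k} a~_k.  The first n with
    G^(n)(0) != 0 decides, with G^(n*)(0) < 0 giving h~_D > h_C (equivalently
    a~_{n*} above its geometric reference a~_1^{n*} (mu-1)^{n*-1}).
    Geometric-shaped distributions return equality, as above.
    """
    if _is_geometric_shape(sb):
        return OrderingVerdict(verdict="equality")
    mu = sb.mean
    a = np.concatenate([[0.0], sb.probs])  # a[n] = alpha~_n
    for n in range(2, sb.n_max + 1):
        conv = sum(a[n - k] * a[k] for k in range(1, n))
        g_n = (1.0 - n) * a[n] + (mu - 1.0) * conv
        if abs(g_n) > _GEOM_TOL:
            verdict = "h_tilde_D > h_C" if g_n < 0.0 else "h_tilde_D < h_C"
            ref = a[1] ** n * (mu - 1.0) ** (n - 1)
            return OrderingVerdict(verdict=verdict, witness_index=n, witness_value=float(a[n]), reference_value=ref)
    return OrderingVerdict(verdict="equality")


def weak_local_difference(sb: SizeBiasedDistribution, lambda_G: float, lambda_L: float) -> float:
    """Leading-order h~_D - h_C as lambda_L -> 0 (E[T_I] = 1 normalisation).

    Equals 2 lambda_L^2 pi0^2 (1-pi0) [E[H~ - 1] - var(H~)] with
    pi0 = 1/lambda_G; positive variance-deficit means households push the
    disease-induced level above the vaccine-induced one.
    """
    if lambda_G <= 1.0:
        raise ValueError("requires lambda_G > 1 (supercritical with E[T_I] = 1)")
    pi0 = 1.0 / lambda_G
    return 2.0 * lambda_L**2 * pi0**2 * (1.0 - pi0) * ((sb.mean - 1.0) - sb.var)


def argmax_difference_over_lambda_G(
    dist: HouseholdSizeDistribution,
    lambda_L: float,
    T_I: InfectiousPeriodLaw,
    lambda_G_bounds: Optional[tuple] = None,
) -> tuple:
    """Global rate maximising h~_D - h_C, and the rank-generation R0 there.

    For lambda_L = 0 the difference is identically zero and the maximiser is
    flagged as undefined.  The supercritical range of lambda_G is bracketed
    automatically unless bounds are supplied.
    """
    if lambda_L == 0.0:
        raise ValueError("h~_D - h_C is identically 0 at lambda_L = 0; maximiser undefined")
    mean_TI = T_I.mean
    sb = dist.size_biased()
    if lambda_G_bounds is None:
        # supercritical iff lambda_G > 1 / (E[T_I] sum alpha~_n mu_n)
        lam_c = 1.0 / (R_star(dist, 1.0, lambda_L, T_I))
        lambda_G_bounds = (lam_c * (1.0 + 1e-6), lam_c * 50.0)

    def neg_diff(lam: float) -> float:
        if math.isinf(lambda_L):
            hd = h_tilde_D_highly_local(dist, lam, T_I).level
            hc = h_C_highly_local(dist, lam, T_I)
        else:
            hd = h_tilde_D(dist, lam, lambda_L, T_I).level
            hc = h_C(dist, lam, lambda_L, T_I).level
        return -(hd - hc)

    res = minimize_scalar(neg_diff, bounds=lambda_G_bounds, method="bounded", options={"xatol": 1e-10})
    lam_hat = float(res.x)
    return lam_hat, R0(dist, lam_hat, lambda_L, T_I)
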