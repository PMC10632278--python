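# Methods

This note records the model, the numerical methods, the defaults and the
design choices behind `hhepi`, at the level a maintainer or reviewer needs
to judge what a passing test suite does and does not establish.

## Model and assumptions

The population is partitioned into households; household sizes are i.i.d.
from (α_n) with finite maximum size n_max (all series over n are therefore
finite sums and are truncated *exactly*). An infective makes global
contacts with any given individual at rate λ_G/N and local contacts with
each housemate at rate λ_L, through an infectious period T_I; newly
contacted susceptibles pass through a latent period T_E where relevant.
All contact processes and periods are mutually independent. Asymptotics
are in the number of households m → ∞; everything the package computes is
a law-of-large-numbers limit except the stochastic simulator, which works
at finite m.

Final-outcome quantities (R\*, R̂_U, z, π, P_{n,v}, h_C, h̃_D) depend on
T_I only through its mean and Laplace transform φ(θ) = E[e^{−θT_I}] and are
invariant to the latent period; the exponential, fixed and Erlang laws are
provided. Trajectory quantities (h_D, h_D^L, ĥ_D, growth rate) require
Markov dynamics (exponential T_I, exponential T_E) and are implemented for
those laws only.

λ_L = ∞ ("highly locally infectious": one introduction infects the whole
household) is represented by the float `inf` and dispatched to closed
forms — μ_n = n, μ̃_n = n(1−π^n), P_{n,0} = π^n, P_{n,n} = 1−π^n,
h_C from a quadratic in μ_H̃, h̃_D from π f′_H̃(π) = 1/(λ_G E[T_I]) — never
approximated by a large finite rate.

## Numerical methods

**Triangular systems.** The Gontcharoff-type coefficients β_k and the
household outcome proportions P_{n,v} solve unit-lower-triangular systems,
computed by forward substitution in increasing k (resp. v). The
alternating sums degrade for large households or extreme parameters;
entries of P_{n,v} below −10⁻⁹ raise rather than being silently clipped
(smaller negativity is clipped and the vector renormalised). Conditioning
beyond n ≈ 25 is untested territory.

**Final-size fixed point.** z solves z = Σ_n α̃_n μ̃_n(λ_L, e^{−λ_G E[T_I] z})/n.
z = 0 always solves; a second root in (0,1) exists iff R\* > 1. The solver
returns 0 when R\* ≤ 1 and otherwise brackets the positive root on
[10⁻¹⁰, 1) with Brent's method (xtol 10⁻¹⁴).

**h_C.** R̂_U(c) is continuous and strictly decreasing from R\* to 0, so
h_C is a bracketed root on [0, 1]. Populations of all-size-1 households
short-circuit to 1 − 1/(λ_G E[T_I]).

**h̃_D.** Nested solve: the outer variable is the global-rate scaling κ on
(1/R\*, 1]; for each κ the inner fixed point gives (z, π, P_{n,v}) of the
reduced epidemic and the residual threshold R̂_DI of an unrestricted second
epidemic; R̂_DI is decreasing in κ, and κ̂ with R̂_DI(κ̂) = 1 is found by
Brent (tol 10⁻¹⁰ on κ; the inner root at 10⁻¹⁴). In the λ_L = ∞ branch the
solve is done directly in π, avoiding the nesting.

**Rank generations.** The mean size μ_i^{(k)} of the i-th generation
(shortest-path layer) of the within-household infection digraph is
computed by an exact frontier recursion rather than enumeration of joint
out-sets: conditional on T, an infective contacts each housemate
independently with probability 1 − e^{−λ_L T}, so the probability that all
f infectives of the current frontier miss a given m-set of unreached
members is φ(mλ_L)^f; inclusion–exclusion gives the law of the number of
new members reached, and the (unreached, frontier) pair is a Markov chain
on O(k²) states. This is exact for every household size at negligible
cost, so no Monte Carlo fallback is needed (the test suite still checks it
against simulated digraphs). R₀ is then the unique positive root of
1 − λ_G E[T_I] Σ_i μ_i λ^{−(i+1)} = 0, bracketed and solved by Brent; the
left side is monotone in λ.

**Deterministic ODEs.** The household-state densities h_{s,e,i,r} evolve
on the state space 1 ≤ s+e+i+r ≤ n_max (SIR uses its own e ≡ 0 slice
rather than a stiff δ → ∞ limit). The right-hand side is assembled once as
a constant matrix (latency, recovery, local infection) plus a bilinear
global term; the per-susceptible force of infection is λ_G ī(t)/μ_H with ī
the per-household infective density, which is the normalisation implied by
the per-pair global rate λ_G/N (this choice reproduces the analytic final
size to the integrator tolerance; the per-household-normalised alternative
does not). Integration uses LSODA with rtol 10⁻¹⁰ / atol 10⁻¹²; mass
within each size class is conserved to < 10⁻⁸ along trajectories. The
run stops when exposed+infective mass < 10⁻¹² or t > 10⁴.

**h_D and restrictions.** Seeding puts a fraction ε = 10⁻⁵ (default) of
households of the largest size in state (n_max−1, 0, 1, 0), the rest fully
susceptible. The residual threshold R_V(t) = (λ_G E[T_I]/μ_H) Σ h·s·μ_s(λ_L)
treats currently exposed/infective members as immune to the second
epidemic; its first crossing of 1 is located by the integrator's event
root-finding on the dense interpolant, and h_D = 1 − S(T_*). For ĥ_D the
first epidemic runs at κλ_G while R_V keeps the unreduced λ_G; κ ≤ κ̂
leaves R_V above 1 until extinction and raises. h_D is ε-robust: moving ε
from 10⁻⁵ to 10⁻⁶ changes levels by < 10⁻³ on the tested grids.

**Growth rate and calibration.** The early exponential growth rate solves
the household Lotka–Euler equation λ_G Σ_n α̃_n L_n(r) = 1, where
L_n(r) = ∫ e^{−rt} E[I_n(t)] dt is obtained from the within-household
Markov generator Q by the linear solve w·(rI − Q)⁻¹p₀. This is the
standard branching-process construction for household models; it reduces
to (1 + r/δ)(1 + r/γ) = λ_G/γ for size-1 households, the same r–R₀
relation used by homogeneous and multitype SEIR models, which is what
makes growth-rate calibration comparable across household structures.
Since L_n does not involve λ_G, calibrating λ_G to a target r is the
direct reciprocal 1/Σ_n α̃_n L_n(r), not a root find.

## Ordering classifiers

Whether h̃_D exceeds h_C in the λ_L = ∞ regime reduces to comparing H̃
with the geometric distribution of the same mean (the unique size-biased
law giving equality for every λ_G; the household law is then logarithmic):

- *just supercritical* (R\* ↓ 1): the first factorial moment order k ≥ 2
  with μ_H̃^[k] ≠ k!μ(μ−1)^{k−1} decides; a smaller moment gives
  h̃_D > h_C. The k = 2 case is the variance criterion
  var(H̃) ≶ E[H̃]E[H̃−1].
- *highly global* (π ↓ 0): the first n ≥ 2 with G^{(n)}(0) ≠ 0 decides,
  where G^{(n)}(0)/n! = (1−n)α̃_n + (μ−1)Σ_k α̃_{n−k}α̃_k; G^{(n*)}(0) < 0
  gives h̃_D > h_C. (Equivalently α̃_{n*} above its geometric reference
  value α̃_1^{n*}(μ−1)^{n*−1}; the sign convention is fixed by requiring
  consistency with the common-household-size result, where h̃_D > h_C
  always holds.)
- *weakly local* (λ_L ↓ 0, E[T_I] = 1): the leading term of h̃_D − h_C is
  2λ_L²π₀²(1−π₀)[E[H̃−1] − var(H̃)] with π₀ = 1/λ_G; its sign is the
  variance criterion var(H̃) ≶ E[H̃−1], and it is extremised at π₀ = 2/3,
  i.e. λ_G = 1.5.

A distribution truncated from a geometric keeps exactly geometric-shaped
probabilities but its high factorial moments differ from the untruncated
reference by truncation error, so a literal moment scan misreads
truncation as a genuine deviation. Both classifiers therefore first test
whether the successive probability ratios are constant (relative tolerance
10⁻⁹) and return the equality verdict if so; otherwise they scan as above.
Strictly, any finite-support distribution deviates from the geometric at
some order, so "equality" means "indistinguishable from a truncated
geometric at this tolerance".

## Synthetic distribution generator

`random_household_distribution(seed, n_max, mean, var)` targets the mean
and variance of the *size-biased* distribution, the two moments that drive
the ordering results. The exact skeleton is a mixture of the
minimal-variance two-point law on the adjacent integers bracketing the
target mean and the maximal-variance two-point law on {1, n_max}, both
with the target mean, mixed to hit the target variance exactly; a seeded
Dirichlet perturbation is blended in, its weight halved until the moments
are within 10⁻⁶ of target. Output is deterministic given the seed, and
infeasible targets raise with the feasible variance range. The generator
emulates the (μ_H̃, σ²_H̃) plane spanned by real-world household size
distributions; it does not attempt to match higher moments or the shape of
any particular country's census, so tests built on it probe the
moment-driven theory, not goodness-of-fit to real demography.

## Stochastic simulator

The Gillespie engine simulates the full Markov jump process on the
household census (counts suffice by exchangeability) and can record the
empirical residual threshold R_V^(m)(t) at event times (piecewise
constant), giving the single-realisation herd immunity level
1 − S^(m)(T_*^(m)). The Sellke engine assigns each susceptible an Exp(1)
infection-pressure threshold; because the final outcome depends only on
thresholds and periods, not timing, infections are processed in vectorised
cascade rounds, which makes final-size validation at m = 10⁴ take well
under a second per replicate, for arbitrary period laws. Major outbreaks
are classified by final fraction > max(0.1·z, 20/N), which separates the
bimodal final-size distribution in the supercritical regime. Stochastic
tests compare means within 3 standard errors plus a small O(1/N) allowance
for finite-population bias.

## Problem sizes and defaults

Defaults: truncation n_max = 30 for logarithmic/geometric constructions
(truncated mass reported); ε = 10⁻⁵ seeding; integrator tolerances as
above; Monte Carlo oracles use 10⁵ household digraphs; population-level
simulation checks use m up to 10⁴ households with ~10–16 replicates.
Deterministic h_D computations for household sizes up to 5 take well under
a second each; the SEIR state space grows like n_max⁴/24, and h_D^L beyond
n_max ≈ 10 becomes expensive — the final-size route h̃_D has no such limit.

## Known limitations

- h_D/h_D^L require exponential periods; non-exponential trajectory
  dynamics (method of stages) are out of scope because the state space
  becomes infeasible at realistic n_max.
- Restriction scenarios cover a constant global scaling κ only, not
  time-varying schedules κ(t), and restrictions never act on λ_L.
- The triangular outcome system is unvalidated beyond n ≈ 25.
- The common-size inequality h̃_D > h_C for 0 < λ_L < ∞ is proved only for
  n ∈ {2, 3}; for larger n the package verifies it numerically on grids,
  which supports but does not prove the general statement.
- λ_L is assumed independent of household size; for countries with very
  large households a size-dependent local rate would be more realistic.
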