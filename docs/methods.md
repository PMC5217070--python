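# Methods

## Model

The package fits single-trait animal models with one additive genetic random
term and i.i.d. residuals. Writing λ = σ²_E/σ²_A, the mixed-model equations
for y = Xβ + Wν + e with Var(ν) = σ²_A **K** are

```
[ X′X   X′W        ] [β̂]   [X′y]
[ W′X   W′W + λK⁻¹ ] [ν̂] = [W′y]
```

Three parameterizations share this machinery:

* **basic** — ν = a, K⁻¹ = A⁻¹. One base population, mean breeding value 0.
* **explicit groups** — group means g enter X as fixed regressions on the
  columns of ZQ (Q's reference column dropped), ν = a, K⁻¹ = A⁻¹.
* **implicit groups** — ν = u with E(u) = Qg, K⁻¹ = A* with the r group
  equations first; the reference group's equation is deleted (its effect
  constrained to 0). Group solutions are read off the group positions.

Group means are not separately identifiable from the intercept, only their
contrasts; the reference group (by default the true-founder group) is
constrained to zero in both parameterizations, which makes them the same
statistical model with identical ĝ. Conversions u = Qg + a and a = u − Qg
are applied exactly, so either fit reports both breeding values and total
additive genetic effects.

## Matrix construction

* **A** (dense, oracle): tabular method, A_ii = 1 + ½A(d,s),
  A_ij = ½(A(j,d) + A(j,s)), unknown parents contributing 0. Dense
  allocations are refused above n = 5000 unless overridden — A and T are
  O(n²) and exist for validation and small problems, never for fitting.
* **F**: Meuwissen & Luo-style ancestor traversal (numba-compiled, near
  linear on shallow pedigrees), cross-checked in the test suite against a
  pure recursive-kinship oracle to 1e-12. Phantom parents are outbred and
  unrelated, so F = 0 whenever a parent is unknown.
* **D**: d_ii = ½ − ¼(F_s + F_d), ¾ − ¼F_p, or 1 for two/one/zero known
  parents. **T**: unit lower triangular parent-average recursion, giving
  A = TDT′.
* **A⁻¹** (sparse, always): per-individual update with δ_i = 1/d_ii — δ_i on
  the diagonal, −δ_i/2 to each known parent, δ_i/4 among known parents — at
  most 9 stored entries per individual.
* **Q**: q_i = ½q_dam + ½q_sire, an unknown slot contributing ½ × its group
  membership vector. Equivalently the first r columns of T with the groups
  prepended as founders; the tests assert both routes agree.
* **A***: the A⁻¹ update with each unknown slot replaced by its group
  code(s). δ_i is unchanged from A⁻¹ — group pseudo-parents carry no
  Mendelian sampling variance of their own — and fuzzy slots split each
  parent-level contribution across groups by membership weight. The group
  block accumulates only δ/4 terms, so every A* row sums to zero and A* is
  singular by construction; the reference-group constraint restores a
  nonsingular system. A⁻¹ and A* accumulate duplicate entries in an
  identical deterministic order, so deleting the group rows/columns of A*
  reproduces A⁻¹ bitwise.

Fuzzy membership rows are validated to be non-negative, non-zero, and within
1e-6 of unit sum; accepted rows are rescaled to sum exactly to one (a
documented adjustment, never a silent renormalization of materially
mis-specified rows). A hard assignment is stored as the unit vector.

## REML

With a single variance ratio, the REML log-likelihood is profiled over λ:
σ̂²_E(λ) = (y′y − θ̂′r)/(N − p) in closed form, and

−2ℓ_R(λ) = (N−p)[ln 2π + ln σ̂²_E + 1] + ln|C| − q ln λ − ln|K⁻¹|,

with ln|C| from one sparse LU factorization of the coefficient matrix (q =
number of random effects). A 15-point log-spaced grid on λ ∈ [1e−3, 1e3]
brackets the optimum, refined by bounded scalar minimization on log λ to
absolute tolerance 1e−6; the procedure is derivative-free, deterministic,
and validated against a dense ln|V|-based evaluation in the tests. A
grid-boundary optimum is returned flagged (`converged=False`,
`boundary=True`) rather than extrapolated. The implicit (A*) model is
estimated through its equivalent explicit representation — the individual
block of A* (which is exactly A⁻¹) plus fixed regressions on Q — because
the two parameterizations share one likelihood while A* itself has no
log-determinant. Group-effect standard errors, when requested, come from
the corresponding diagonal entries of C⁻¹ times σ̂²_E (Wald contrasts).

Note that σ²_A and σ²_E are only jointly identifiable when the pedigree
links phenotyped relatives; on founders-only data the profile is flat in λ
and only σ²_A + σ²_E is estimable.

## Simulator

The generator emulates a closed, unselected population with discrete
non-overlapping generations and immigrant gene flow:

* 15 cohorts × 400 individuals (6000 total) by default; cohort 1 is all
  founders with u ~ N(0, σ²_A); cohorts 2–15 hold 360 locally bred offspring
  plus 40 immigrants with u ~ N(immigrant_mean, σ²_A), immigrant_mean = 3.
  That yields 560 immigrants and a 16% unknown-parent fraction.
* Sexes alternate within cohorts; random monogamous pairs form within the
  parental cohort (immigrants join the pool of their arrival cohort), with
  offspring distributed near-equally among pairs, remainder at random; an
  unequal sex count is resolved by mating each surplus individual to a
  random member of the other sex (a triad), logged.
* Offspring u = midparent u + Mendelian deviation
  ~ N(0, ½σ²_A(1 − (F_s+F_d)/2)), with parental F tracked exactly through a
  within-cohort relationship recursion (all parents of a cohort belong to
  the previous cohort; immigrants are unrelated to everyone).
* Phenotypes y = u + e, e ~ N(0, σ²_E), μ = 0. Breeding values are reported
  as deviations from group means, a = u − Q·g with g = (0, immigrant_mean).
* All randomness flows from one `numpy` generator seeded by `SimParams.seed`.

Immigrants arrive without recorded parents, so the observed (masked)
pedigree codes them as parent-unknown; `mask_immigrant_parents` is the
general operation that clears recorded parents of immigrant-flagged records
in user pedigrees.

What the simulator does *not* emulate: selection, assortative mating,
environmental trends or shared environments, overlapping generations,
sex-linked or maternal effects, heterogeneous σ²_A between groups, or
related/inbred phantom parents. Passing tests therefore demonstrate correct
model algebra and unbiased recovery under the stated infinitesimal-model
conditions, not robustness of genetic-group models to those realities of
field data.

## Problem sizes and numerical choices

The end-to-end validation study runs the default 6000-individual population
across five seeds (both in `tests/test_acceptance.py` and
`scripts/acceptance.py`); unit tests use populations of tens to hundreds.
The known-variance REML recovery check uses six group-free replicates of
1000 individuals. Dense-oracle comparisons (A⁻¹ vs inv(A), T·D·T′ vs A, Q vs
augmented-T) run at n ≤ 200 with tolerances 1e−8/1e−10/1e−12 respectively.
Trend diagnostics regress cohort-mean predictions on cohort index and are
assessed across seeds against their Monte-Carlo standard errors.

Sparse systems are solved by SuperLU factorization; the coefficient matrix
is SPD after constraints, so |C| is taken from the U diagonal. Topological
ordering is stable (input order breaks ties) and idempotent. Missing-parent
codes default to {NA, 0, *, empty}; a parent id referenced but absent from
the records is appended as a founder with a warning, which is logged
distinctly from explicitly coded unknowns. An id appearing as both dam and
sire is permitted (selfing/hermaphrodites) but logged.

## Known limitations

* Single trait, Gaussian response, one additive random term; no maternal
  genetic effects, dominance, or multivariate extensions.
* Phantom parents are assumed outbred and unrelated within and across
  groups; σ²_A is homogeneous across groups.
* The per-unknown-parent phantom-ancestor construction (unique phantom
  identities traced back generations) is not implemented.
* Prediction-error variances of â/û are computed only on request and only
  for systems small enough to invert (n ≤ 5000).
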