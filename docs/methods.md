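# Methods

## Model

The immune system is treated as a binary signal detector. Specificity
`s_p` (probability of correctly ignoring a benign self signal) and
sensitivity `s_e` (probability of correctly responding to a parasite
signal) are tied together along a receiver-operating-characteristic curve

    s_e = 1 − exp(−γ (1 − s_p)),

where γ > 0 is a discrimination coefficient: larger γ means less overlap
between self and parasite signal distributions, so sensitivity is cheaper
in specificity terms. The pair is never stored independently — `s_e` is
always derived from `s_p`, which makes inconsistent strategies
unrepresentable.

For one age class with infection probability `i_r`, background mortality
hazard `μ_b`, immunopathology hazard `μ_i` (false-positive response while
uninfected), undetected-infection mortality `μ_d` and detected-infection
mortality `μ_id`, the total per-class hazard is

    h = μ_b + (1 − i_r) μ_i (1 − s_p) + i_r μ_d (1 − s_e) + i_r μ_id s_e,

and class survival is `s_x = exp(−h)`. Hazards are instantaneous rates per
one-year age class; there is no sub-annual structure and no within-year
multiple-infection model. `i_r` simply weights the infected branch of the
mortality mixture.

Survivals and a fertility schedule assemble into a Leslie matrix
(fertilities in the first row, survivals on the subdiagonal, a terminal
self-loop describing the last class and all older individuals). Fitness is
the dominant eigenvalue λ of that matrix. The model contains no density
dependence and no transmission feedback, so optimizing λ (rather than an
invasion/ESS analysis) is the appropriate criterion. The optimal strategy
is found by brute-force grid search over `s_p ∈ {0, 0.001, …, 1}` (1001
points, both endpoints included); exact ties go to the smallest `s_p`,
which is only reachable when the objective is flat (no epidemiological
mortality at all).

Because a Leslie matrix is nonnegative, its spectral radius is itself an
eigenvalue (Perron–Frobenius); λ is computed as the largest *real*
eigenvalue, never the max-modulus one — for periodic matrices (e.g. strict
semelparity with a zero terminal loop) the spectrum contains ±ρ and a
modulus criterion would tie-break arbitrarily. The grid search normally
insists on a primitive life cycle and names the failed check otherwise; an
explicit `check_primitive=False` opt-out exists because λ remains well
defined (just not dynamics-describing) for periodic cycles, which the
λ-equalization utility can encounter.

## Schedules and scenarios

Risk varies with age in a *stepped* mode (one jump at reproductive
maturity) or a *smoothed* mode (linear from class 1 to class D, endpoints
exact). Exactly one of `i_r` or `μ_d` varies; the others stay constant.
Named presets: A1 (0.6→0.2), A2 (0.2→0.6), B1 (0.45→0.2), B2 (0.7→0.45),
B3 (0.7→0.2), B4 (0.525→0.375), each with constants μ_b = 0.15, μ_i = 0.1,
μ_id = 0.01, γ = 4 and μ_d = 0.3 (for the `i_r`-varying family) or
i_r = 0.4 (for the `μ_d`-varying `*_mud` family).

The five reproductive schedules default to maturity at class 3 on a
10-class demography: Baseline/High/Low constant at 1.0/1.5/0.5 offspring
per class, Rising linear 0.5→1.5 across the reproductive classes and
Declining its mirror. The source analyses do not print the fertility
magnitudes, so these defaults were chosen once so that Rising, Declining
and Baseline share the same mean output — level effects (High vs Low) and
shape effects (Rising vs Declining) then separate cleanly. All levels are
overridable.

λ-equalization replaces `μ_b` with a single uniform value (age-constant,
as in the experiments it serves) and bisects on the strictly decreasing
map μ_b → λ_opt, re-optimizing `s_p` at every trial, to tolerance 1e−4 on
λ. Classes with an infinite `μ_b` sentinel (zero terminal survival) stay
pinned.

## Projection-matrix pipeline

Empirical-style matrices are filtered on six named checks: Leslie
structure (zeros off the first row/subdiagonal/terminal corner), positive
subdiagonal, at least one positive fertility, irreducibility (strong
connectivity of the life-cycle digraph), primitivity (boolean matrix
powers up to the Wielandt bound D² − 2D + 2 — exact and cheap at these
dimensions), and ergodicity (unique eigenvalue of maximal modulus).

Life-history statistics are computed from the *original* matrix:

- age class of first reproduction m = first column with positive fertility
  (1-based);
- reproductive life expectancy = expected total years spent in classes ≥ m
  entering at class m, from the fundamental matrix N = (I − U)⁻¹ of the
  survival-only transitions (counts the year of arrival; requires terminal
  self-loop < 1);
- mean reproductive rate = arithmetic mean fertility over classes ≥ m;
- generation time = mean age of mothers, T = λ (v·w)/(v·Fw), with w, v the
  stable-age and reproductive-value eigenvectors and F the fertility-only
  matrix.

The reproductive-life-expectancy and generation-time formulas are the
standard matrix-intrinsic choices; where a different monotone recoding of
the same quantities exists in the literature, the downstream regression is
only affected up to its log–Z-score transform.

The matrix is then resized to D* = round(m + reproductive life
expectancy), rounding half up, floored at 2. Expansion duplicates the
terminal class (new classes copy terminal fertility and survival; the
self-loop moves to the new corner) and is exactly λ-preserving. Collapsing
merges classes D*..D into one terminal class whose fertility and outgoing
survival are stable-age-weighted means of the merged classes; the
transition *into* the merged block is kept unchanged (the weighted
alternative is not used; this choice is order-independent for a single
terminal block). A consequence worth stating: with stable-age weights the
collapsed stable-age vector remains an eigenvector at the same λ, so
collapsing is λ-preserving to machine precision — comfortably inside the
"small perturbation" contract the pipeline assumes, and the acceptance
script measures it rather than asserting it.

Background mortality is recovered from the resized matrix as
μ_b[x] = −ρ ln(s_x) with ρ = 0.75 by default (the fraction of observed
mortality attributed to non-disease causes). A terminal self-loop of
exactly 0 would give an infinite hazard; it is carried as a `+inf`
sentinel that pins reconstructed terminal survival to 0 instead of
propagating an infinity through arithmetic. With ρ = 1 and all
epidemiological risks zero, the reconstruction reproduces the resized
survivals exactly (a tested identity).

Stepped scenarios jump at the matrix's own class of first reproduction;
smoothed scenarios run from class 1 to the resized terminal class, so the
*total* change in risk over a lifetime is identical for every matrix
regardless of dimension.

## Meta-regression

Predicted optima are regressed on log-transformed, Z-scored traits
(sample sd, n−1 denominator):

    sp* ~ Normal(α + Xβ, σ),  α ~ Normal(0.5, 0.15),
    β_k ~ Normal(0, 0.1),     σ ~ Exponential(1).

The response stays unstandardized (a unitless fraction that never
approaches its [0, 1] bounds in practice). The σ prior is a weakly
informative default chosen here (the residual sd these fits produce,
~0.03–0.04, sits far inside its bulk) and is overridable. Generation time,
when used, is fit alone — it is strongly collinear with the other three
traits.

Sampling uses an affine-invariant ensemble sampler (32 walkers) with
differential-evolution moves, which mix markedly faster on this posterior
than the default stretch move (integrated autocorrelation ≈ 17 steps);
1000 warm-up steps, then 3000 steps thinned by 12, retaining exactly 2000
draws by default. Convergence is checked with the rank-normalized
split-chain scale-reduction factor (threshold 1.01) treating walkers as
chains, and flagged on the result object rather than silently accepted.
Summaries are posterior mean, sd, and the 89% highest-posterior-density
interval (shortest contiguous window of sorted draws containing ⌈0.89 n⌉
points).

The scenario sweep tiles an 11 × 11 grid of (pre-maturity, post-maturity)
infection risks, 0.2–0.7 by 0.05 by default (endpoints overridable). On
the diagonal risk is age-constant; demography then cannot influence the
optimum, so the coefficients are pinned to 0 by construction with no model
fit. A failing off-diagonal cell is tagged and skipped, never fatal.

## Synthetic ensemble

The generator emulates an age-classified animal matrix database without
any download. Per matrix: age at first reproduction m ∈ {1..5};
reproductive span 2–12 yearly classes (D = m + span); a two-phase survival
curve (juvenile survival 0.3–0.9, adult survival 0.5–0.95 with an optional
Gompertz-like hazard increase at rate 0–0.15/class); a terminal self-loop
drawn in 0.05–0.9 (strictly < 1 so life expectancy is finite); fertility
level log-uniform on 0.2–6 offspring/class (spanning over an order of
magnitude, as real taxa do) with constant, rising, or declining shape.
Every emitted matrix passes the structural filter. Randomness flows from a
single seed through named spawned substreams, so identical seeds give
bitwise-identical ensembles.

What the ensemble does *not* emulate: taxon identity, phylogenetic
correlation among matrices, the exact trait distribution of any real
database, and measurement error in fertilities or survivals. Passing tests
therefore demonstrate that the pipeline recovers structure *planted by the
generator* (e.g. the sign flip of the reproduction–specificity
relationship between declining and rising risk), not that any particular
empirical coefficient is reproduced.

The regression-data generator draws correlated standardized predictors
(pairwise correlation 0.3 by default, mimicking trait collinearity) and a
Gaussian linear response; it is the oracle for parameter-recovery and
HPDI-coverage checks.

## Problem sizes and numerical choices

The shipped checks use a 10-class demography for the five-schedule
experiments; 50 random matrices up to 8 × 8 for the eigen-machinery
oracles (elasticities vs central log-finite-differences at h = 1e−6,
tolerance 1e−5; λ vs power iteration at 1e−8 relative); 100 synthetic
matrices for the resizing contracts; 298 observations and 50 replicate
datasets for Bayesian recovery and coverage; and a 300-matrix ensemble for
the end-to-end meta-regression. Eigenvalues over the specificity grid are
computed as one batched dense eigendecomposition per optimization.

Known limitations: no transmission dynamics or host–parasite coevolution;
no stage-structured (non-yearly) matrices — they are filtered out, not
converted; no age-varying specificity within one organism; reproductive
life expectancy and generation time follow the closed-form conventions
above, which may differ from other published operationalizations by a
monotone recoding.
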