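# Methods

## The model

`cascademc` models a stationary biological cascade — an ordered chain of
measurable endpoints X → Y₁ → … → Yₙ, such as receptor activity → enzyme
activity → hormone concentration → biomarker concentration → fecundity —
under a Markov assumption: the joint density of input and output factorizes
as p(y | yₙ) p(yₙ | yₙ₋₁) ⋯ p(y₁ | x). Rather than evaluating the nested
integral of that factorization, the package reconstructs the conditional
output distribution by Monte Carlo: sample a parameterization of every
edge, push the input value through the chain, repeat.

Each edge's mean relationship is a Hill-type sigmoid,

    increasing:  y(x) = y_max (x/K)^h / (1 + (x/K)^h)
    decreasing:  y(x) = y_max / (1 + (x/K)^h)

with y_max the saturating child activity (child units), K the half-maximal
parent activity (parent units), and h a dimensionless steepness exponent.
All three are constrained positive. The direction is chosen from Kendall's
tau-b on the raw paired data: τ > 0 selects the increasing form, τ ≤ 0
(including the all-tied degenerate case) the decreasing one. The tie-adjusted
tau-b variant is used because dose-response tables routinely repeat x levels.
The two forms are complementary — for identical coefficients they sum to
y_max at every x — and for h = 1 both are Möbius (fractional-linear) maps,
so a fixed-parameter h = 1 chain composes to another rational map; the test
suite exploits that closed form as an independent oracle for the propagation
engine.

## Edge fitting

Coefficients are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`, TRF, analytic Jacobian, positivity bounds).
Starting values follow standard Hill-fit practice: y_max⁰ = max|y|, K⁰ = the
x at which the data first crosses half of y_max⁰ (linear interpolation,
median x as fallback), h⁰ = 1 with restarts at h⁰ ∈ {0.5, 2, 4}; the
converged restart with the lowest sum of squared residuals wins. At x = 0
the power (x/K)^h is defined by its limit, 0, for all h > 0. Convergence
tolerances are 1e-10: tight enough that noise-free data reproduce true
coefficients to ~1e-6, loose enough that ridge-shaped objectives — which
arise whenever the data never approach saturation, leaving only the ratio
y_max/K^h identified — still terminate at the (legitimately enormous)
coefficient values the resampling distribution implies, instead of being
miscounted as failures.

## Residual bootstrap

Uncertainty is quantified by resampling residuals with replacement: for each
of m resamples (default m = 999), ŷᵢ = f(xᵢ) + r_j with r_j drawn uniformly
from the fitted residuals, and the sigmoid is refit to (xᵢ, ŷᵢ) with the
direction held fixed. The m bootstrap coefficient vectors are pooled with
the original fit, each coefficient column is sorted ascending, and the
(m+1)·0.025-th and (m+1)·0.975-th order statistics (1-based) are the 95%
interval — exactly ranks 25 and 975 of the 1000 pooled values at m = 999.
For m where the ranks are non-integral the lower rank is floored and the
upper ceiled, which can only widen the interval. Refits that fail to
converge are skipped and counted; more than 20% failures raises an error,
because quantile positions in a heavily censored pool stop meaning 2.5%.

A known limitation, quantified in this package's own calibration runs: the
plain percentile interval undercovers its nominal 95% at the sparse sizes
the method targets. With 12 points per edge and homoscedastic Gaussian
noise, the 95% interval for K covers the true K in roughly 86–89% of
simulated datasets (82% at n = 8, ~90% at n = 24, ~92% at n = 40), with an
independent cold-start refit oracle reproducing the same rates. The driver
is familiar: residuals of a 3-coefficient fit to n points carry only
(n−3)/n of the noise variance, and no inflation or bias correction is part
of the procedure. Users needing calibrated intervals at small n should
collect more points per edge or treat the intervals as approximate.

## Monte Carlo propagation

Each bootstrap interval is converted to the Gaussian "underlying" a 95% CI:
mean = (upper + lower)/2, sd = (upper − lower)/(2 × 1.959964). By default
only K and h are sampled; y_max stays at its point estimate (configurable).
Draws are rejected until positive (capped at 1000 attempts) rather than
clipped, to avoid a point mass at zero. One coefficient set is drawn per
edge per (replicate, input-level) evaluation, so the replicate columns at
different input levels are independent ensembles — the structure the
per-level KS comparisons below assume. An alternative "bootstrap-curve"
mode draws whole stored bootstrap coefficient vectors uniformly instead,
preserving the joint (and possibly skewed or multimodal) shape of the
resampling distribution; it is off by default. The midpoint/width Gaussian
is a deliberate symmetrization: when an edge is nonidentifiable and its
bootstrap distribution heavy-tailed, the Gaussian's mean is dragged far
from the point estimate, and the bootstrap-curve mode is the more faithful
choice.

The default ensemble is 1000 replicates per input level over a 25-point
grid. With all sds zero the propagation is deterministic and every
replicate identical.

## Impact thresholds

For a chosen node (default: the leaf), the replicate distribution at each
input level is compared with the distributions at the lowest and highest
levels using the two-sample Kolmogorov–Smirnov test with the asymptotic
critical value D > c(α)·√((n+m)/(n·m)), c(α) = √(−½ ln(α/2)), α = 0.05 by
default (c ≈ 1.358102, critical ≈ 0.0607 at n = m = 1000). Empirical CDFs
are right-continuous and D is taken over the pooled support, so ties are
handled exactly. The scan moves away from each reference — the reference
column itself is excluded — and the first rejecting level on each side
defines the bound, even if rejection is non-contiguous further along. The
lower bound separates "no impact" from "weak but statistically significant
impact"; the upper bound separates weak from strong. A flat response yields
no rejections and undefined bounds. No multiple-testing correction is
applied across the grid; the procedure is a scan, not a family of
simultaneous tests. Calibration: over 2000 same-distribution pairs at
n = m = 1000 the rule rejects at ~5%, inside [0.03, 0.07] — the asymptotic
critical value is approximate at finite n.

## Density clouds

The conditional response distribution is summarized as a cloud: per input
level, the replicate values are binned (default 100 bins spanning the
node's ensemble-wide range) and normalized into a probability mass
function, reported as log₁₀ probabilities. Normalization is per input
column — the probability of a response given that input — so each column
sums to one. Empty bins are undefined (NaN), not −∞, and render as
background. A zero-range (fully deterministic) node degenerates to a single
bin with log₁₀ p = 0.

## Synthetic data

The fixtures module generates the kind of data the method is built for:
sparse response-response tables (default 12 points per edge) whose mean
follows a known sigmoid with additive homoscedastic Gaussian noise (default
sd = 10% of the edge's y_max, a realistic mid-range for averaged in vivo
endpoint tables). Chained edges share a common exposure series: each edge's
x values are the previous edge's noise-free outputs at the design points
(a noisy-x switch exists for robustness studies). The default 4-edge
cascade mimics an abridged reproductive adverse-outcome chain — receptor
activation (fold change, 0.25–6) suppressing an enzyme-like activity that
drives hormone-, biomarker-, and fecundity-like endpoints — with every
edge's K placed mid-range of its actual input span and near-saturation
reached at both ends, so each edge is identifiable from its own data. What
the generator does not emulate: heteroscedastic or correlated noise,
non-monotone relationships, measurement error in x, and between-study batch
effects; passing tests therefore demonstrate correctness of the machinery
under the model's own assumptions, not robustness to violations of them.

## Reproducibility and problem sizes

One master seed drives everything: `numpy.random.SeedSequence` spawns
independent substreams for bootstrapping and simulation, so changing the
replicate count does not perturb fitted CIs, and identically-seeded runs
produce byte-identical numeric artifacts (plots excluded). The bundled test
and acceptance runs use 200 calibration datasets with m = 199 resamples
((m+1)·0.025 = 5, integral), 2000 KS calibration trials, and full pipeline
runs at R = 1000, m = 999 — sizes chosen so a complete check runs on a
single CPU in a few minutes while keeping Monte Carlo error well inside the
asserted tolerances.
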