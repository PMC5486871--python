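# Methods

This note documents the models, procedures, and numerical choices behind
`corrlaw`, and what its simulations can and cannot say about real
observers.

## The two laws and their link

The package is organized around two empirical laws for the perception of
Pearson correlation *r* in scatterplots, coupled by a single bias
parameter *b* ∈ (0, 1):

* **Discrimination (Weber).** The just-noticeable difference — the
  correlation difference discriminated correctly 75% of the time — is
  linear in the distance from *r* = 1:
  `JND(r) = k (1/b − r)`, equivalently `JND(u) = k·u` with `u = 1 − b r`.
* **Magnitude (Fechner).** Perceived correlation is logarithmic in the
  same quantity: `g(r) = ln(1 − b r) / ln(1 − b)`, with `g(0) = 0`,
  `g(1) = 1`, convex, so intermediate correlations are underestimated.

If every JND spans the same subjective increment (the Fechner
assumption), the two laws share the bias: `b_disc = b_est`.

## Simulated observer

Humans are replaced by a two-parameter observer: perceived magnitude
`g(r; b)` plus additive gaussian noise of sd `σ_g` **on the magnitude
scale**, drawn fresh at every look (mirroring the regeneration of plots
after every response). This is the minimal noise model under which the
Fechner assumption holds exactly: a two-alternative forced choice
between two independent noisy percepts is correct with probability
`Φ(Δg / (σ_g √2))`, so the 75% threshold corresponds to a fixed
subjective increment `Δg* = √2 Φ⁻¹(0.75) σ_g` and the JND from above is
exactly `k (1/b − r)` with `k = 1 − (1 − b)^{Δg*}`. The calibration
`σ_g = ln(1 − k) / (√2 Φ⁻¹(0.75) ln(1 − b))` maps a desired (b, k) pair
to a noise level. Where the noise lives (magnitude scale vs correlation
scale) is a modeling choice, not an empirical fact; everything
downstream inherits it.

Two parametrizations of "k" coexist and are easy to conflate. A
threshold measured at base *r* is conventionally plotted at the
*adjusted* correlation `r_A = r ± JND/2` (the mean of the two plot
correlations), which symmetrizes above- and below-direction runs. For
this observer the r_A-space line is again exactly linear with the same
intercept 1/b but slope magnitude `k′ = k / (1 − k/2)`, identically for
both directions. `lawfit` reports the conventional r_A-space slope;
`weber_slope_to_base_k` / `base_k_to_weber_slope` convert exactly
between the two. Parameter-recovery analyses compare generative and
recovered values in the same parametrization.

## Stimuli

Gaussian clouds: two independent normal sequences are standardized and
mixed, `y′ = (λx + (1−λ)y)/√(λ² + (1−λ)²)`, with the mixing weight in
the singularity-free form `λ = r/(r + √(1−r²))` (the textbook expression
`(r² − √(r²−r⁴))/(2r²−1)` is 0/0 at 2r² = 1 but agrees elsewhere to
1e-12). Points beyond 2.5 sd of the mean are replaced by fresh draws;
if the realized sample correlation then misses the target by more than
the tolerance (default 0.005), the target is imposed exactly by residual
orthogonalization (regress y on x, standardize the residual, recombine
as `r·x + √(1−r²)·e`), which preserves marginal shape closely; the cloud
is finally rescaled to the configured mean and sd exactly (population
convention, ddof = 0). The clip bound is enforced on the *final*
coordinates; violations trigger regeneration (bounded at 50 attempts).
Aspect ratio κ = σ_y/σ_x compresses x.

Uniform clouds: a sorted list of uniform draws is paired with a
scrambled copy of itself and partially re-ordered by a comb sort
(shrink factor 1.3) halted at the first swap that brings the sample
correlation inside the tolerance band. Because x is ascending and y is
a permutation of x, every executed swap raises the correlation, so the
sweep is monotone and a full sort ends at r = 1. Scrambles whose
initial correlation already exceeds the band are rejected and redrawn
(sorting can only raise r). The marginal sd is the uniform value
range/√12 ≈ 0.29 of the unit range.

Coordinates live in abstract cloud units; dot size and rendering are
not modeled, since all downstream analysis depends only on the
coordinates.

## Staircase

JNDs are measured by an asymmetric up-down staircase: start offset 0.1
from the base, −0.01 after a correct response, +0.03 after an error
(steady state at exactly 75% correct), differences clamped between 0.01
(one down-step; a zero difference would make the trial undefined) and
the distance to the range limit. Convergence is tested after every
trial from trial 24 on, over the most recent 24 differences split into
three sub-windows of eight: the variance (ddof = 1) of the sub-window
means divided by the mean within-sub-window variance; the run halts
when this ratio is ≤ 0.25 or at 52 trials, and the JND is the mean of
the three final sub-window means. Zero within-variance means the
staircase is pinned and counts as converged. Below-direction runs are
excluded for bases under 0.3 (floor effects). Under the default
calibration the simulated runs average ≈ 39 trials with ≈ 30%
non-convergence.

**Known limitation — anchoring.** With these constants the staircase is
not an unbiased estimator of the observer's threshold: estimates are
pulled toward the 0.1 start offset. At (b = 0.90, k = 0.21) the
measured-to-true JND ratio runs from ≈ 0.84 at base 0.0 (the staircase
cannot climb from 0.1 to the true 0.23 within the trial cap) to ≈ 1.15
at base 0.9 (the final window still carries the descent from 0.1).
This flattens the fitted Weber line and biases the fitted `b_disc`
downward (e.g. cohort estimates ≈ 0.73–0.78 for a generative b = 0.90),
increasingly so at larger k. The effect is a property of the procedure
itself, not of the simulation: any observer measured with this
staircase, human or simulated, is measured through this filter, so
fitted parameters from staircase data should be read as
procedure-relative. The bisection-side bias estimate `b_est` is not
affected and recovers its generative value to ≈ ±0.02 at realistic
noise, which also means the simulated pipeline reproduces the
*systematicity* claim (b_disc = b_est) only approximately: the
staircase side sits systematically below the estimation side.

## Bisection

Perceived-magnitude levels g = 1/8 … 7/8 are measured by three rounds of
recursive bisection: round 1 finds the point perceived halfway between
r = 0 and r = 1 (g = 1/2, four reps averaged), round 2 recurses into the
two half-intervals (1/4, 3/4), round 3 fills in the eighths. For a
noiseless observer the recursion's fixed points are available in closed
form: `r* = (1 − √((1 − b·lo)(1 − b·hi)))/b`, evaluated in the
cancellation-free form `(lo + hi − b·lo·hi)/(1 + √((1−b·lo)(1−b·hi)))`
so the b → 0 limit (arithmetic midpoint) is exact.

The human "adjust until satisfied" loop is replaced by a policy: the
test starts 0.1 inside a random reference and steps toward the
perceived midpoint (fresh noisy percepts of test and both references at
every adjustment) with a random step size in (0, (hi−lo)/10]. The
default policy runs 160 adjustments and returns the mean test position
after a 40-step burn-in — a time average of the walk's stationary
distribution, which centers on the perceived midpoint (measured bias
≤ 0.011 across the calibration grid, shrinking with noise). A
reversal-counting variant (stop after 6 reversals, average the last 4)
is available but not default: at realistic noise it terminates near the
start point and drags estimates toward the references. The fixed point,
not the path, carries the scientific content; only the fixed point is
asserted in tests.

## Analysis pipeline

Per-cell JNDs are log-averaged (geometric mean) across observers and
plotted at r_A. A range constraint drops any cell whose test
correlation, mean ± 2.5 sd across observers, crosses 0 or 1. The Weber
line is ordinary least squares of JND on r_A (k = −slope, b_disc =
−slope/intercept capped at 0.99; slope CI by Student-t, bias CI by the
delta method). The Fechner curve is a bounded one-dimensional least
squares over b ∈ (0, 0.99] (1e-4 grid plus bounded refinement).
Biases are averaged on the probit scale (capped at 0.99) to tame skew;
the discrimination/estimation comparison is a paired t-test on that
scale. Cohort screening mirrors the human protocol's replacement rule:
observers whose k or b lies more than 2.5 sd from the mean of the
others (leave-one-out) are excluded from per-observer summaries, and
individually inadmissible fits (non-positive intercepts, possible at
high noise) are dropped.

## Entropy theory

The theoretical account treats perception as reading the width of the
isofraction ellipse of the inferred bivariate-gaussian dot density
(level set at fraction `e^{−K1²}` of the peak; default K1 = √ln 2, the
half-maximum contour — b is invariant to K1 at fixed residual ratio).
The closed-form width, its equal-σ reduction `2√2 K1 σ √(1−r)`, the
residual-width bias `b = 1/(c² + 1)` with c = w_res/K2 inversely
proportional to σ, the differential entropy
`H = n ln(2πe σ_x σ_y √(1−r²))` (nats), the ellipse area and the exact
identity `H = n ln(A e/K1²)`, the unequal-σ forms
`g = ln(1−br²)/ln(1−b)` and `JND = k′(1/(br) − r)`, and the
information-per-JND link `k = −I₇₅ ln(1−b)` are all implemented as pure
functions and verified against independent oracles (eigen-structure
contour search, 2-D quadrature). The comparison between the Fechner
curve and the exact-entropy family is operationalized as fitting the
entropy family to the Fechner curve with the basic-condition bias
b = 0.90 on a dense grid — an approximation to fitting both to raw
data, adopted because the Fechner curve fits those data with RMSE an
order of magnitude below the inter-family distance.

## Model zoo

Candidate magnitude laws are ranked by RMSE against the seven measured
levels within strata of free-parameter count. Implemented families:
variance (r²), powers of distance-from-1 and of the iso-density axis
ratio √((1−r)/(1+r)), the Fechner law, the exact-entropy law, and two
two-parameter generalizations. The two-parameter power of
distance-from-1 is implemented as `g = (1 − (1−r)^c)^a` — the obvious
affine normalization of `1 − a(1−r)^c` collapses onto the one-parameter
family, so the exponent form is used to keep a genuine second parameter
while preserving g(0) = 0, g(1) = 1 and nesting the one-parameter
family at a = 1. Families whose constants are defined only in their
original sources are deliberately not hard-coded; they can be supplied
as sympy expressions via a YAML config.

## Design metrics and the quick protocol

A display design with Weber parameters (k, b) is scored by
`S = k(1/b − 1/2)` (mean JND over [0, 1]; precision) and
`E = 1/b − 1/2 + 1/ln(1−b)` (mean underestimation; accuracy), both
exact integrals of the two laws. The reduced protocol measures JNDs
from above at three bases (default 0.3, 0.6, 0.9) and fits the Weber
line; two-base designs are allowed with a warning.

## Experiment presets and problem sizes

Presets `exp1`–`exp4` pair the four stimulus conditions (100-dot
gaussian; 25-dot; 2:1 aspect; uniform) with 20-observer cohorts whose
(b, k) default to the values measured for each condition (0.90/0.21,
0.91/0.30, 0.89/0.22, 0.94/0.24). Each observer runs the full battery
(17 staircases: 10 bases from above, 7 from below) plus the bisection
protocol, from an independent child of the experiment seed, making runs
bitwise reproducible and order-independent. A full condition runs in
about a second; the parameter-recovery analyses use 5 seeds per
parameter-grid cell, which resolves the recovery biases described above
far beyond their magnitude.

## What the simulations do and do not show

The synthetic observer realizes the two laws *by construction*; green
tests therefore validate the procedures, the fitting pipeline, and the
theory's internal identities — they are evidence about the artifact,
not about human vision. Features of real data deliberately not
emulated: lapses and attention drift, learning across a session,
response-time structure, heterogeneity of b and k across a cohort
(observers share parameters by default; heterogeneity hooks exist in
the config), and any rendering-level effect (dot size, color, axes).
The staircase anchoring analysis above is the clearest example of what
the simulation *can* show: a measurement procedure faithfully
implemented can be a biased estimator of the very parameters it is used
to report.
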