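# Methods

## The branching model of abortive colony formation

A plated cell starts a synchronized binary Galton–Watson process: a cell of
generation *g* undergoes reproductive cell death (RCD) with probability
*P₁(g)* or divides into two generation-(g+1) cells with probability
*1 − P₁(g)*. RCD cells persist physically but never divide again (the
process is absorbing), so an abortive colony is a finite binary lineage
tree whose leaves are RCD cells: size *n* ⇔ *n* leaves ⇔ *n − 1* divisions.

For constant *P₁ = p* the size pmf is the Catalan closed form
`f_n = C(n−1) pⁿ (1−p)ⁿ⁻¹`, evaluated in log-space with `gammaln` so it is
stable for large *n*. For a schedule *P₁(g)* the pmf of the subtree rooted
at generation *g* satisfies the convolution recursion

    q_g(1) = P₁(g),  q_g(n) = (1 − P₁(g)) Σ_{k=1}^{n−1} q_{g+1}(k) q_{g+1}(n−k),

evaluated top-down from the horizon. **Truncation**: the assay scores
colonies at a fixed time (~13 days, ≤ 16 divisions), so colonies that still
contain a proliferative cell at `g_max` are excluded from the abortive pmf
without renormalization; the returned frequencies are unconditional. The
missing mass is reported by `survivor_mass`, computed with the exact
backward extinction recursion `e_g = P₁(g) + (1 − P₁(g)) e_{g+1}²`
(survivor mass `1 − e_0`). We deliberately avoid summing the pmf to
convergence here: near the critical point *p = 1/2* the size distribution
has an `n^(−3/2)` tail and partial sums converge far too slowly, while the
recursion is exact and O(`g_max`).

Convergence caveat worth knowing: extinction-by-horizon approaches the
closed-form extinction probability `min(1, p/(1−p))` geometrically at rate
`2·min(p, 1−p)` for *p ≠ 1/2*, but only as O(1/g) at the critical point —
at `g_max = 30` the critical process still has ≈ 5.5 % of lineages alive.
Long-horizon comparisons against the closed form are therefore meaningful
only away from *p = 1/2*.

### The unobserved 1-cell class

Single cells are not scored in the assay. The 1-cell frequency is inferred
from the 2-cell class by assuming the same death probability for the first
two generations: `f₂ = (1−p)p²` with `f₁ = p`. The cubic has two roots in
(0, 1) whenever `0 < f₂ < 4/27`; both are always reported, and the smaller
root is returned by default (consistent with observed sub-50 % 1-cell
frequencies); callers can request the larger branch.

## Regression conventions

Both line families — log-linear (`log y = a·n + b`, exponential decay) and
log-log (`log y = a·log n + b`, power-law decay) — are ordinary least
squares on **decadic** logs of the frequencies (slopes and intercepts of
colony-size data are conventionally reported on base-10 axes). R² is
computed on the transformed scale; flat data take the R² = 0 convention.

AIC uses the least-squares form `AIC = N·ln(RSS/N) + 2K` with K = 3 (slope,
intercept, residual variance), computed on the log scale. The inferred
1-cell point may enter the *fit* but is always excluded from the *AIC*,
since it is model-derived rather than observed; selections are only allowed
between fits sharing the same AIC point set, and exact ties go to the first
family in caller order (flagged). Absolute AIC values depend on the
observation set, so only within-data comparisons are meaningful.

Confidence limits are Student-t bands for the mean response on the
transformed scale with N − 2 degrees of freedom (narrowest at the design
centroid), back-transformed to frequencies. Mean-response rather than
prediction bands: the band is used to propagate uncertainty of the *smoothed
curve*, not of individual future observations.

## Inverting for P₁(g)

The inversion matches the branching pmf to a regression-smoothed size
distribution on *n* = 1..15. Frequencies are treated as percentages of all
colonies (including the inferred 1-cell class) and divided by 100; this is
configurable. Size classes above 15 are statistically unreliable in
practice, so only the head *P₁(0..5)* is estimated, with the tail pinned at
*P₁(g > 5) = P₁(5)* during inversion — which is also why *P₁(5)* is the
most uncertain entry (flagged on the estimate).

Two modes are provided because the system is over-determined (15 size
classes, 6 unknowns):

* **lsq** (default): bounded least squares on log₁₀ frequencies over all of
  *n* = 1..15 (trust-region reflective, bounds (0, 1), uniform weights by
  default). Uses all information and degrades gracefully when the smoothed
  curve is not exactly branching-consistent — e.g. high-dose power-law fits
  whose percentages sum above 100, which no pmf can match.
* **sequential**: solves size class *n = g + 1* for *P₁(g)* one generation
  at a time by bracketed scalar root finding (each `q(g+1)` is monotone in
  `P₁(g)`), clamping to the boundary when a target is unattainable. Exact
  on consistent data; used internally to initialize the lsq mode.

95 % limits are propagated by re-running the inversion on the band's lower
and upper frequency curves and taking the elementwise envelope with the
point estimate; this mirrors the visual construction of dotted confidence
curves without bootstrap machinery. A residual-bootstrap mode (200
replicates, quantile limits) is provided but off by default.

The **excess probability** is defined as irradiated minus unirradiated at
the same generation, so that radiation-induced persistent RCD is positive;
limits combine by interval arithmetic (conservative). Note the opposite
verbal convention ("control minus irradiated") appears in the assay
literature even where the plotted excess is positive for irradiated cells.

Known bias: a two-parameter log-log smoother cannot follow the exact pmf's
curvature, so inversion of the *fitted* curve inherits a systematic error
of up to about 0.03–0.05 at *g* = 0 (the intercept pulls `f̂(1)` below the
true 1-cell frequency). Inverting empirical frequencies directly avoids
this at the cost of noise sensitivity.

## Full schedules and the tail slope c

Simulation needs *P₁* out to `g_max = 16`. The tail is the straight line
from (5, *P₁(5)*) to (16, (1 − c)·*P₁(5)*): `c = 0` holds the tail flat,
`c = 1` drives it to zero. `P1Schedule` validates the line when `c` is
declared. Sweeping `c` is the standard probe of long-lasting RCD: abortive
bins (≤ 15 cells) are robust to it, the clonogenic (≥ 50 cells) frequency —
hence the surviving fraction — is highly sensitive.

## The lattice simulator

Square grid, 31.6 µm pitch (1,000 µm² cell footprint — a flat fibroblast
monolayer), one cell per site. One step = one doubling time (20 h); the
13-day window gives ceil(15.6) = 16 steps, capped at `g_max`. Update rule
per step:

1. **Fate phase.** The cells present at step entry are visited in a fresh
   uniformly random permutation (avoids spatial bias; daughters created
   this step draw no fate). A proliferative cell with ≥ 1 free site among
   its 8 neighbors dies with *P₁(g)* or divides: the divider is replaced by
   two generation-(g+1) daughters, one in place and one on a uniformly
   random free neighbor — matching the lineage-tree semantics in which
   internal nodes are divisions. A fully surrounded cell is
   contact-inhibited: it draws *no* fate that step (fate deferral). The
   alternative — death still possible when blocked — is available as
   `blocked_can_die`.
2. **Movement phase.** Every cell with a free neighbor relocates to a
   uniformly random free neighbor with probability `p_move` (default 0.25
   per step; cell motility exists in these assays but no rate is
   established, so the default is a modest choice and is exposed in the
   configuration for sensitivity analysis).

Invariants: occupancy is exclusive; cell count never decreases; RCD is
absorbing; with `p_move = 0` the colony stays 8-connected. Colonies smaller
than 9 cells can never contain a fully surrounded cell, so sizes 1–8 follow
the analytic branching pmf exactly — the simulator is validated against the
Catalan closed form on exactly that range.

Implementation notes: kernels are numba-compiled; every colony is seeded
explicitly from a `SeedSequence`-spawned stream (results are
bit-reproducible from one master seed and independent of execution order,
and derived seeds stay below 2³¹). Since a colony grown for *s* steps has
Chebyshev radius ≤ 2s from the center (division + movement), single-colony
runs use a working grid of that reach when the configured grid is larger;
the configured boundary is then unreachable and the boundary-contact flag
is unaffected. Batch defaults follow assay-scale practice: 10,000 inocula
per set, 5 sets (50,000 plated cells).

The growth-curve mode seeds the grid Bernoulli(density) per site and
reports daily counts (sampled at the nearest step): early exponential
doubling, then saturation as contact inhibition exhausts free sites — the
designed confluence behavior, which the tests check.

## Summaries and statistics

Colonies are classified single (1 cell) / abortive (2–49) / clonogenic
(≥ 50). Binned comparisons use the fixed classes 2–7, 8–15, 16–49, ≥ 50 as
percentages of ≥ 2-cell colonies (singles are unscored; including the
inferred 1-cell class is available for model-side distributions). The SQD
discrepancy is `Σ_bins ((f_sim − f_obs)/f_obs · 100)²` — asymmetric by
construction (observation sets the denominator), undefined on zero observed
bins unless the caller opts into skipping them.

Surviving fraction is the ratio of clonogenic colony counts
(irradiated / unirradiated), with per-set paired ratios retained for
dispersion. Experimental surviving fractions (plating-efficiency based)
enter only as comparison columns; they are never recomputed. The chi-square
test scales simulated bin proportions to the observed total and uses
bins − 1 degrees of freedom, treating simulated proportions as fixed
(simulated totals are tens of times larger than observed ones, so their
sampling error is negligible); Bonferroni correction multiplies the raw
p-value by the caller-declared family size, capped at 1.

## Synthetic data

`generate_synthetic_counts` emulates a scored assay table: a multinomial
draw of N colonies over sizes 1–49 from the branching pmf, with all
remaining mass (clonogenic and still-growing colonies) pooled into the
≥ 50 class (`n = 50` in the table), or alternatively actual lattice runs.
Default generating conditions used in the tests: 50,000 colonies (the
batch scale of the simulator), heads in the 0.1–0.6 range typical of
0–8 Gy estimates, and the linear tail at `c = 0.4` (the tail-slope value
that model selection favors for these data). The generator reproduces
multinomial scoring noise only; it does **not** emulate plate-to-plate
variability, counting/segmentation error of large colonies, dose-rate
effects, or cell-cycle asynchrony — so passing recovery tests demonstrate
statistical identifiability under the model, not robustness to those
real-data effects.

## Numerical choices

* pmf truncation returns unconditional frequencies; no renormalization.
* Inversion bounds (0, 1) with probabilities floored at 1e-300 inside logs;
  scalar roots via Brent (xtol 1e-12); lsq tolerances 1e-14.
* `estimate_f1_from_f2` accepts `f₂` up to 4/27 + 1e-12 and clamps to the
  maximizer *p* = 2/3 at the boundary; larger values raise.
* Degenerate inputs raise typed errors (`DomainError`, `NoRootError`,
  `InsufficientDataError`, `IncomparableFitsError`, `FormatError`) rather
  than returning NaNs.
* Problem sizes in the test-suite simulations (10,000 inocula for pmf
  validation, 2,000 × 5 for the c-sweep sensitivity check, 50,000-colony
  synthetic tables) were chosen to keep Monte Carlo error a few times
  smaller than the effects under test.

## Known limitations

* Synchronized generations: no continuous-time age structure, cell-cycle
  variability, or asymmetric division.
* The inversion estimates only *P₁(0..5)*; everything beyond is a one-
  parameter linear tail.
* Critical-point comparisons with infinite-horizon closed forms are
  intrinsically slow to converge (see above).
* The movement rule (who moves, when, at what rate) is a modelling choice,
  not an established quantity; conclusions sensitive to `p_move` should be
  checked across its range.
* 2-D monolayer only; no 3-D colonies or off-lattice mechanics.
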