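# Methods

## The measurement problem

A urease-modified platinum electrode produces a current when urea is
hydrolysed; the current depends on urea concentration `Ca` (mM), buffer
concentration `Cb` (mM) and pH. Exploring all 3³ = 27 combinations of
three candidate levels per factor is wasteful, so the calibration study
behind this package measured only the 9 runs of a Taguchi L9 orthogonal
array and modelled the rest.

## L9 construction

An L9(3³) array is a set of 9 level-index triples in which every ordered
pair of levels of every pair of columns occurs exactly once. All such
arrays are equivalent up to row order, column order and level relabelling,
but *which* 9 of the 27 factorial cells they select depends on the
realization. `build_l9` therefore uses the affine lattice

    rows = { (i, j, (i + j + 1) mod 3) : i, j ∈ {0,1,2} }

which is the realization whose condition triples coincide exactly with
the 9 measured calibration runs (the more common textbook realization
`k = (i + j) mod 3` selects a different, disjoint-in-part set of cells).
Orthogonality holds by construction — fixing any two coordinates
determines the third — and is additionally verified by explicit pair
counting in `validate_orthogonality`.

Main effects assume a balanced table (each level in exactly n/3 rows);
unbalanced input is rejected rather than reweighted. Additive prediction
returns `grand_mean + Σ_f (level_mean_f − grand_mean)`. Degenerate factor
specifications (≠ 3 levels) are rejected rather than generalized: the L9
is meaningful only for three 3-level factors.

## Response surface

    EF = a0 + a1·pH^a2 + a3·Cb^a4 + a5·Ca        [EF in nA]

Urea enters linearly; pH and buffer through power terms with free
exponents. Two textual conventions circulate for which concentration is
"urea" in this formula; this package assigns `Ca` = urea (linear term)
and `Cb` = buffer (power term), the assignment under which the reference
coefficient vector reproduces measured runs 1, 3 and 6 to better than
0.005 nA (the swapped assignment misses them by 0.1–0.5 nA). The tests
assert this reconciliation directly.

Domain: `Cb > 0` and `pH > 0` (non-integer powers of non-positive bases
are undefined; fitted exponents may be negative), `Ca ≥ 0`. Grids that
conceptually start at zero buffer use a configurable floor (default
1e−6 mM). Power-term exponents `|a·ln(base)| > 700` would overflow
float64 and raise a dedicated `OverflowSignal`; the fitting objective
converts it to a finite penalty `1e12 + |exponent|` so the optimizer can
rank infeasible candidates, while direct callers get the error.

The canonical current unit is nA throughout (the source tables' unit);
µA figures quoted alongside them are treated as typographical
inconsistency.

With the reference vector the surface *increases* with pH (a1, a2 > 0 —
asserted as a monotonicity test) but *decreases* with buffer and with
urea (a3·Cb^a4 more negative as Cb grows; a5 < 0). Narrative claims of
increasing current with buffer and urea are therefore not asserted; the
measured level means side with the model for buffer (highest current at
the lowest buffer level).

## CMA-ES

`ureafit.cmaes` implements the Covariance Matrix Adaptation Evolution
Strategy as a general bounded minimizer: sample λ candidates from
N(m, σ²C), select the best μ, update the mean with the weighted step ȳ,
the step size via the conjugate path p_σ, and the covariance via the
rank-one path p_c plus the rank-μ term. Initial state is C = I,
p_σ = p_c = 0.

Strategy constants for dimension n (all overridable):

| constant | default | note |
|---|---|---|
| λ | 4 + ⌊3 ln n⌋ | 9 at n = 6 |
| μ | ⌊λ/2⌋ | a 25%-selection variant is available via `mu=` |
| w_i | ∝ ln(μ + ½) − ln i | gives μ_w ≈ 0.3 λ |
| c_σ, c_c | 4/n | cumulation rates |
| c_1 | 2/n² | rank-one learning rate |
| c_μ | min(μ_w/n², 1 − c_1) | rank-μ learning rate |
| d_σ | 1 + √(μ_w/n) | step-size damping |
| χ_n | √n (1 − 1/(4n) + 1/(21n²)) | E‖N(0, I_n)‖ |

Design choices worth noting:

- **No h_σ stall indicator.** The update equations are applied exactly as
  written, without the stall correction canonical implementations add to
  p_c after large step-size jumps. At the small dimensions this package
  targets the practical effect is negligible (the sphere benchmark
  converges in 20/20 seeds), but it is a documented deviation from modern
  practice.
- **Bounds by resampling.** An out-of-box candidate is redrawn up to 10
  times, then clamped to the boundary with its y-step recomputed, which
  preserves the sampling distribution near the interior without penalty
  tuning.
- **C^(−1/2) by eigendecomposition every generation.** No staleness or
  lazy-update logic; at n = 6 the cost is irrelevant. Eigenvalues within
  float roundoff of zero (relative to the largest) are clamped to a tiny
  positive floor; a genuinely negative spectrum raises a state-corruption
  error.
- **Stopping.** Budget exhaustion, best-value stagnation (< 1e−12
  improvement over 50 generations), or σ < 1e−14.
- Under a constant objective the selection is uniform and σ performs an
  unbiased random walk (the step-size rule is designed to be neutral
  under random selection); the run terminates through the stagnation
  rule. σ does not decrease monotonically in this case, and the tests do
  not pretend it does.

## Calibration

The loss is the unweighted sum of squared residuals on the 9 measured
runs (no row weighting or robust loss; nothing suggests one), over the
box [−100, 100]⁶, which contains the reference vector. The 18 externally
predicted runs never enter the default fit; a configuration switch can
include any table for sensitivity analysis.

The SSE landscape is multimodal and contains severely ill-conditioned
valleys: when an exponent is near zero its power term degenerates toward
a constant and trades off against the offset, and a quarter-box initial
step size almost always collapses into a linear-subspace local minimum
(SSE ≈ 0.187 on the measured runs, against ≈ 0.031 at the best basin
found). `fit` therefore alternates two restart plans:

1. **Global ladder** — start at the box centre with initial step sizes
   cycling 50, 6.25, 0.78, 0.098 (quarter box width divided by 8^k): the
   useful coefficients live on a much finer scale than the box.
2. **Exponent profiling** — the model is linear in (a0, a1, a3, a5) once
   (a2, a4) are fixed, so ordinary least squares over a coarse exponent
   grid (−2 to 2, step 0.5; variable-projection style) yields cheap
   near-optimal starts that CMA-ES polishes with a small (0.3) initial
   step.

Restart seeds derive from the configuration seed via `SeedSequence.spawn`,
making the whole fit deterministic. Fits on tables with fewer rows than
coefficients proceed but are flagged `underdetermined`.

## Synthetic data and recovery

`simulate_table` draws `ef = surface(condition) + N(0, noise_sd)` per
replicate over an L9, a 27-cell factorial, or an explicit condition list.
The default noise (0.05 nA, homoscedastic) matches the residual scale of
the reference calibration on the measured runs (RMSE ≈ 0.087 nA). The
generator emulates the *statistical* structure the calibration assumes —
a smooth surface plus independent Gaussian noise. It does not emulate
electrochemical drift, electrode fouling, replicate correlation or
pH-dependent heteroscedasticity, so passing recovery tests validate the
fitting machinery, not the adequacy of the model for any particular real
sensor.

Random generator vectors for recovery studies are drawn from moderate
ranges (exponents in [−2, 2], term scales within a few nA) and accepted
only if the total surface *and each individual term* stay within 10 nA
over the evaluation grid: measured currents are on the ~1 nA scale, and
surfaces assembled from huge mutually cancelling terms correspond to no
measurable system.

Because (a0, a3, a4) trade off, recovery is scored on predictions — RMSE
between fitted and generator surfaces on a 5×5×5 grid over urea 0–10 mM,
buffer 0.01–0.5 mM, pH 5–8 — never on coefficient identity.

## Problem sizes used in the shipped checks

Chosen as a balance of statistical resolution and quick iteration:
refit dominance over the reference vector uses 20 seeds × 30,000
evaluations (4 restarts × 7,500); the sphere benchmark 20 seeds × 20,000
evaluations; noise-free recovery 6 random generators at 6 restarts ×
10,000 evaluations; noisy recovery 20 seeds at 4 restarts × 6,000
evaluations. The full suite runs in about a minute on one CPU.

## Known limitations

- The two power terms make the model non-identifiable in places; only
  predictions, not coefficients, are meaningful fit outputs.
- The additive Taguchi prediction and the parametric surface disagree
  with the 18 shipped externally predicted currents (e.g. 0.949 vs 1.17
  at the first unrun cell); those values' provenance is unpublished, so
  they are carried as reference data and excluded from every oracle.
- The headline 0.215 µA maximum attributed to this model is three orders
  of magnitude above anything the reference surface produces on the
  stated ranges; it is documented in the comparison report, not modelled.
- No confidence intervals or bootstrap on coefficients, and no
  alternative functional forms; the package calibrates exactly the
  surface above.
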