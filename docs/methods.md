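# Methods

## Generating process

Latent predictors are i.i.d. N(3, 1); observed predictors are
`clip(ceil(x), 1, 5)`. Ceiling-then-clip is the stated "rounding up"
convention; under it the cell probabilities are Φ(v−3) − Φ(v−4) for
v = 2..4 with the tail mass absorbed at 1 and 5, so the code
distribution is left-skewed relative to nearest-integer rounding
(`likertize(..., method="round")` is available for sensitivity analysis
but is not a study condition). Outcomes are always computed from the
latent values; the discretization is the only predictor error.

Nine formulas (complexity × number of items) define the signal. Two
printed quirks are implemented literally rather than "repaired": the
high-complexity 5-item formula reuses its first nonlinear coefficient
for both interaction terms (four distinct nonlinear coefficients, five
nonlinear terms), and the high-complexity 10-item formula ends in a
plain `conf5·x9` main-effect term carrying a nonlinear-level
coefficient. A formula registry keeps variants pluggable if a corrected
reading is ever wanted.

Coefficients are drawn independently per term: linear from U[0.1, 0.3]
("small") or U[0.5, 1] ("large"), nonlinear likewise, noise multiplier
fixed at 1, 4 or 10 by the cell. The full grid is 3×3×2×2×3 = 108
cells; condition ids follow the canonical row order of the published
results table (complexity fastest, then nonlinear level, linear level,
noise level, items slowest). One master seed namespaces per-condition
coefficient streams and per-replication data streams through
`numpy.random.SeedSequence` spawn keys, so any condition or replication
can be recomputed in isolation and results are independent of execution
order.

## Reference quantities

Rt² and Rl² are in-sample OLS R² on a dedicated n = 100,000 sample per
condition (Rt²: all generating terms of the Likert codes; Rl²: all main
effects). In-sample optimism at that n is negligible relative to the
0.1-width criterion. Computing the references once per condition, not
per replication, stabilizes the denominator of the ratio criterion;
per-replication network estimates may therefore exceed Rt² by sampling
error, which matches the published intervals whose upper percentiles
exceed 1.

For 3-item cells a semi-analytic oracle computes the exact population R²
of the best linear predictor over the generating terms: all moments
factor across the independent coordinates into 5-cell sums
(Likert side), closed-form normal moments of x^k·e^{cx} (latent side),
and truncated-normal cell moments (mixed). It agrees with the Monte
Carlo Rt² to ~0.001 and serves as the independent check that the
estimator and the generating code mean the same thing. 10-item cells
would need 5¹⁰ cells and are out of scope for validation.

## Network harness

Fully connected ReLU MLPs with a single linear output, trained by
minibatch Adam on MSE. The backend is scikit-learn's `MLPRegressor`
driven one epoch at a time (`partial_fit`) against an explicit
validation set: no improvement in validation MSE for `patience` epochs
stops training and the best epoch's weights are restored. The epoch cap
defaults to 200 (configurable); in practice early stopping binds first.
Activation and input scaling are unstated upstream, so the field
defaults are used: ReLU, raw 1..5 codes (a `standardize` switch exists,
default off). Splits are 64/16/20 train/validation/test by seeded
permutation. Grid search fits every combination once (a `repeats`
option fits each several times and keeps the best validation loss;
experiments showed best-of-10 does not change conclusions because
selection noise on a 160-row validation set dominates), selects the
lowest validation MSE, and breaks ties toward the earlier combination in
canonical order (shape, learning rate, patience, batch size).

## Decision rules

The stability criterion is evaluated on the ratio scale Rn²/Rt²: the
interval between the 2.5th and 97.5th percentiles (linear interpolation
between order statistics) must be strictly narrower than 0.1. The
literal R²-scale reading is available via `on_ratio_scale=False`, but
only the ratio reading reproduces the published unattainable decisions.
The outperformance criterion requires the proportion of replications
with Rn² > Rl² to be strictly greater than 0.8: the strict inequality is
deliberate, because the published decisions leave a printed proportion
of exactly 0.8000 below threshold. Rt² ≤ 0 leaves the stability
criterion undefined, reported as unattainable. Summaries with more than
5% failed replications (non-finite losses, degenerate test sets) are
rejected rather than silently truncated.

## Scaled-down testing and what it shows

The full design (108 conditions × 1000 replications × 81 combinations ×
the 11-rung ladder) is a multi-day server computation and is not run in
the test suite. The suite instead uses: exact decision replay on the
published summary columns; the quadrature-vs-Monte-Carlo cross-check;
monotonicity of Rt² in the noise level; and one scaled-down stochastic
run (condition 1 analogue: 30 replications, a reduced 8-combination
grid over 2 shapes × 2 learning rates × 2 batch sizes at patience 5,
n = 1000, ~90 s). Passing these shows the machinery is faithful at
desk scale; it does not certify the full-scale tables, and the
generator's idealized independence (uncorrelated items, no
self-correlation or reliability structure of real psychometric scales)
limits what any pass says about real data.

## Known discrepancies

Two published values are not reproduced, and the corresponding tests are
expected to fail honestly rather than being loosened:

1. **Rt² = 0.9009 for the printed coefficient cell.** Under
   ceiling-and-clip the estimate concentrates at 0.876 (quadrature:
   0.8759). Nearest-integer rounding yields 0.8996 ≈ 0.9009, so the
   published pipeline most likely rounded to nearest despite describing
   rounding up — or the printed coefficients are illustrative rather
   than the saved draws. The stated convention is kept.
2. **Scaled-down outperformance > 0.5.** With mid-range redrawn
   coefficients the nonlinear gap Rt²−Rl² (~0.015) is the same size as
   the network's validation-selection deficit, and ~35% of replications
   beat the linear benchmark. The published proportion for this cell
   (0.626 at n = 1000) evidently rests on a more favorable coefficient
   draw; the bound is not met under redrawn mid-range coefficients.

Related print inconsistencies handled in code: the published "144
conditions" is an arithmetic slip for 108; condition 19's published
stability MSSR (10,000) contradicts its own published widths (20,000
under the strict rule); and the published meta-analysis, though
described as Spearman, matches raw-value Pearson correlations to the
fourth decimal on the stability criterion (both estimators are
exposed; the rank-based one is the statistically appropriate choice for
these heavily tied ordinal codes).

## Limitations

Single imputation-free continuous outcome only; no reliability
manipulations beyond discretization; no convolutional/recurrent
architectures, regularization search, or k-fold cross-validation (the
single-split protocol is implemented as specified); quadrature oracle
restricted to 3 items. MSSR decisions at small replication counts are
noisy — the defaults (1000 replications) are the study conditions, and
desk-scale runs should be read as smoke tests, not planning advice.
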