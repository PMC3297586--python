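# Methods

## Fitness from growth curves

A well's fitness is the natural logarithm of the area under its OD600
time series. The area is computed by composite Simpson's rule applied
to consecutive interval pairs (the three-point formula is evaluated in
its non-uniform form, so irregular grids are handled); when the number
of intervals is odd the final interval uses the trapezoid rule rather
than discarding a point. With the standard design — readings every
30 min over 24 h, i.e. 49 samples and 48 intervals — the odd-interval
branch is never taken. Natural log is used; the base is a joint
rescaling of all effects and cancels from every contrast.

Plate effects are removed by an additive shift on the log scale: each
record is moved by (grand wild-type mean − its plate's wild-type mean),
which makes every plate's wild-type mean equal to the grand mean
exactly, preserves within-plate differences, and is idempotent. Plates
without wild-type wells cannot be normalized and are an error. Missing
OD cells are rejected rather than interpolated — silent interpolation
would bias the area. No blank-well background subtraction is applied;
raw OD is integrated. Wells are normalized individually, before any
averaging of technical replicates.

## The interaction model

Fitness is modelled as Y = μ + α_i + β_j + ε_ij + error over wild-type,
single-mutant and double-mutant wells, with ε_ij = 0 under additive
neutrality. Because every parameter corresponds to one design cell the
model is saturated and the least-squares solution is the cell-mean
estimator (μ̂ = WT mean, α̂_i = single-i mean − μ̂, β̂_j = single-j
mean − μ̂, ε̂_ij = double mean − single means + μ̂). The error variance
is pooled across all cells (s² = within-cell SS / (N − #cells)); the
per-cell alternative was considered and rejected because three-replicate
cells make per-cell variances extremely noisy. Standard errors follow
the four-cell contrast form, t = ε̂/SE is referred to a t distribution
on the residual degrees of freedom, p-values are two-sided (the screen
reports signed statistics in both directions), and the Bonferroni
family is all pairs tested at one temperature, since analyses at
different growth temperatures are run separately and in parallel.

Degenerate designs are handled without failing the fit: if the residual
degrees of freedom are below one, or the pooled variance is exactly
zero (noise-free data), estimates are returned with SE/t/p absent.

Classification: a pair whose double mutant is inviable under
random-spore double selection is synthetic lethal (SL) and needs no
growth estimate; a viable pair is synthetic sick (SS) iff ε̂ < 0 and
its (optionally Bonferroni-corrected) p-value clears the significance
threshold. Positive-ε̂ (alleviating) pairs produce no edge. When a
gene was assayed with multiple alleles at one temperature the most
negative ε̂ is kept; across temperatures the more significant result
wins (no cross-temperature pooling rule is defined by the assay design,
so the merge keeps the smaller p-value).

## Screen filter cascade

SGA candidates are reduced in a fixed order: (i) negative score with
p < 0.05, (ii) score < −0.3, (iii) gene hit by ≥ 2 distinct query
genes, (iv) gene has a human homolog with BLAST expect < 1e-5. All
comparisons are strict ("less than"), so boundary values are excluded.
Each filter is a contraction and idempotent; only the multi-query
filter is order-sensitive because it counts queries in its own input,
which is why the cascade order is fixed. Homology is consumed as a
precomputed best-expect table; genes absent from it are treated as
no-match and logged. Validation merging computes
final = candidates − unconfirmed + newly-identified and reports the
counts; reported percentages are rounded half-up to integers.

## Worm additive-expectation test

For a binary phenotype scored in wild-type and mutant animals with and
without RNAi, the additive prediction is the sum of the two background
frequencies plus the RNAi effect on wild type, which simplifies
algebraically to mutant_control + wt_treated (the literal triple sum
would double-count the wild-type background). Frequencies are clamped
to [0, 1]; count phenotypes such as apoptotic corpses per gonad arm use
the same expectation without the upper clamp. Frequencies carry
binomial SEMs, √(f(1−f)/n), and the prediction's SEM pools its two
contributing terms. An interaction is called when the observed excess
exceeds k pooled SEMs; k defaults to 2 — matching SEM-error-bar
reading of assay figures and giving a one-sided false-call rate near
2.5% — and is configurable. Brood summaries report per-animal means
with SEM = sd/√n and pooled binomial rates for embryonic arrest and
male frequency.

## Synthetic data

The generator emulates the plate assay: logistic growth with a lag
phase (OD held at the inoculum density until lag, then rising to the
carrying capacity), defaults initial OD 0.15, K = 1.2, rate 0.01/min,
lag 60 min; 15 wild-type wells per plate, 3 wells per mutant strain;
readings every 30 min for 24 h. Fitness effects are injected on the
log-AUC scale — the scale the model estimates on — by multiplicatively
scaling the noise-free curve so its log area hits the target exactly,
making truth directly comparable to estimates. Measurement noise is
i.i.d. Gaussian on OD (default sd 0.01, typical plate-reader
repeatability), floored at zero; with the default geometry the floor is
never active, so log-AUC noise is effectively Gaussian and
homoscedastic across cells. One global seed drives everything through
deterministic per-plate substreams, so outputs are reproducible
bitwise.

What the generator does not emulate: heteroscedastic noise at high
density, well position / edge effects, condensation artifacts, robot
pinning variation, or RNAi dilution kinetics. Passing tests therefore
demonstrate correctness of the estimators and calibration under the
stated error model, not robustness to every failure mode of real
plate-reader data.

SGA tables are simulated as null records (score ~ N(0, 0.1), p ~
U(0,1)) plus declared true hits passed through verbatim; worm assays as
binomial draws per condition.

## Calibration and test sizes

The null calibration simulates 1000 independent plate sets (2 queries ×
2 genes, one plate, noise sd 0.02 OD) and pools the four pair tests per
set; the p < 0.05 rejection rate is required to lie in [0.03, 0.07].
Parameter recovery runs 200 seeded simulations of an injected
ε = −0.4 under the 15/3 replicate design and requires coverage of the
3·SE interval in ≥ 95% of runs. The worm calibration uses 500 seeds at
n = 100 animals per condition: ≤ 5% false calls at zero excess, ≥ 90%
detection at excess 0.3. These sizes give the rates sampling errors
small against their acceptance bands while keeping the default test run
fast.

## Known limitations

- The SGA E−C score is consumed as given; its upstream normalization
  from colony sizes is out of scope.
- Homology is binary at the expect threshold; paralog resolution and
  bidirectional-best logic are not modelled.
- No shrinkage or empirical-Bayes moderation of variances; with
  three-replicate cells the pooled-variance t-test is the deliberate
  choice.
- Only the additive definition of neutrality is implemented (no
  multiplicative or minimum-based epistasis definitions).
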