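# Methods

This note records the models implemented in `codmedia`, the numerical
and design choices behind them, and what the validation does and does
not establish. The system under study is the production of cholesterol
oxidase (COD, U/mL) by a *Streptomyces* soil isolate in shake-flask
culture, as a function of five medium components: soybean meal,
glycerol, maltose, MgSO₄ and NaCl (g per 50 mL; glycerol in mL per
50 mL).

## Central composite design

The design space is parameterized per factor by a center, a factorial
half-range, a star distance α in coded units, and a lower floor:

| factor   | center | half-range | ±1 levels      | star levels        |
|----------|--------|------------|----------------|--------------------|
| soybean  | 0.75   | 0.375      | 0.375 / 1.125  | 0.0005 / 1.5       |
| glycerol | 0.75   | 0.375      | 0.375 / 1.125  | 0.0005 / 1.5       |
| maltose  | 0.75   | 0.375      | 0.375 / 1.125  | 0.0005 / 1.5       |
| MgSO₄    | 0.025  | 0.0125     | 0.0125 / 0.0375| 0.0005 / 0.05      |
| NaCl     | 0.15   | 0.075      | 0.075 / 0.225  | 0.0005 / 0.3       |

α = 2 is inferred from the printed star-to-factorial spacing (e.g.
(1.5 − 0.75)/0.375 = 2); the source table never states it. Low star
levels that would reach zero concentration are floored at the printed
0.0005 — a medium with a strictly zero component is not the same
experiment as a trace one, and the floor (`low_clip`) reproduces the
printed levels exactly. The factorial core is the resolution-V half
fraction generated by x₅ = x₁x₂x₃x₄, whose 16 rows match the printed
run order (standard binary order, first factor slowest); star points
follow per factor (low then high), then the 10 center replicates.
Coded and uncoded units convert exactly through the affine map above,
and `code(decode(z)) = z` holds to machine precision above the floor.

Two cells of the printed table are kept verbatim although they look
like transcription errors: run 24's MgSO₄ = 0.5 (α = 2 implies 0.05)
and run 17's predicted-response value (inconsistent with the published
equation, which gives ≈1.555). The bundled fixture is checksummed so
these quirks cannot drift silently; `analysis/01_reconstruct_design.py`
reports the exact cell-level discrepancies between the regenerated and
the printed design.

## Quadratic response surface

The full second-order model — intercept, 5 linear, 10 pairwise
interaction and 5 square terms — is fit by ordinary least squares on
the 21-column model matrix. Assumptions are the usual ones: additive
homoscedastic errors, no lack-of-fit structure beyond the quadratic.
Implementation notes:

* The published equation is treated as an **uncoded-units** model even
  though its text says "coded values": evaluated with raw
  concentrations it reproduces the printed predicted column (the
  center-point and star-point checks in the acceptance tests), whereas
  coded units do not. The default fitting basis is therefore uncoded;
  fitting in coded units and converting the coefficients (exact affine
  substitution on the quadratic form) gives identical predictions to
  ~1e−10, which is tested.
* Per-term ANOVA uses type-III (drop-one-column) sums of squares,
  F = SS/MS_error with (1, n−21) degrees of freedom. This reproduces
  the published table's F and p for the terms checked (e.g. the
  maltose×MgSO₄ interaction). The published *overall* F (71.07) is not
  reproducible from the standard formula
  F = (SSR/20)/(SSE/15) and is reported as computed, not matched.
* The printed coefficient vector itself is only partially consistent
  with the printed data: the refit reproduces R² = 0.920067 and all ten
  interaction coefficients to every printed digit, but not the
  intercept, linear or square terms, and no examined design variant
  (corrected run 24, exact-zero star levels, coded basis) closes the
  gap. The corresponding fidelity test is left failing by design
  rather than loosened; the package reports its own least-squares
  solution.
* Rank deficiency raises an error naming the collinear columns
  (pivoted QR); p-values are validated in tests against direct
  numerical integration of the F density.

## Feed-forward network

Architecture 5-15-1: tanh ("tansig") hidden units, linear output,
min–max scaling of inputs and response to [−1, 1] computed from the
full design (tanh saturates on raw concentration scales; the response
scaling makes training invariant to affine rescaling of the response,
which is tested). Epoch-wise SSE, and the `goal_sse` stopping
threshold, are therefore on the normalized scale.

Weights initialize uniformly in [−0.5, 0.5] from a seeded generator.
Trainers:

* `gd`: fixed-rate steepest descent on the SSE.
* `gda`: adaptive rate — a step that worsens the SSE is rejected and
  the rate shrinks by `lr_dec` (0.7); after an improving step it grows
  by `lr_inc` (1.05).
* `lm` (default): Levenberg–Marquardt, solving (JᵀJ + μI)δ = Jᵀr on
  the analytic Jacobian of the network outputs, with μ starting at
  10⁻³, ×10 on rejection, ×0.1 on acceptance, and an accepted-step SSE
  that is non-increasing by construction (tested). Training ends at
  `max_epochs` (1000), `goal_sse` (10⁻⁵), μ exceeding 10¹⁰ (converged),
  or validation-based early stopping (patience 6), whichever is first.
  These defaults follow common practice; the source gives none.

**Fitting set.** The network's objective is the SSE over the rows whose
split label is in `train_splits`, which defaults to the union of the
training and test rows (30 runs). The source describes exactly that
("trained with a training data-set comprising 30 experimental runs"),
and its printed network predictions interpolate the observed values on
most test rows, which is only possible if those rows were fit. Only
the 6 validation rows are held out; they drive early stopping (the
weights with the lowest validation SSE are restored) and model
selection across restarts. Set `train_splits=("train",)` to fit on the
24 training rows alone.

With 106 parameters against 30 fitting points the network is heavily
over-parameterized; generalization depends on the initialization and on
early stopping, so split correlations are stochastic across seeds. The
workflow trains several restarts (default 10) and keeps the highest
validation correlation; the acceptance check asserts a 0.90 floor on
training and validation correlations for the best of 10 seeded
restarts, against reported values of roughly 0.96 and 0.94. Exact
replicate-center observations differ, so the training correlation
cannot reach 1 even at interpolation.

## Genetic algorithm

Generational, real-coded, maximizing. Per generation: fitness
evaluation; elitism (`elite_count` = 2 copied unchanged, making the
best-so-far trace non-decreasing); rank scaling 1/√rank (ties broken by
input order); stochastic universal sampling (one uniformly offset comb
of equally spaced pointers — integer expectations are met exactly);
scattered crossover for round(`crossover_fraction`·(pop−elite))
offspring (each gene from either parent with probability ½); Gaussian
mutation (sd = `mutation_sd_fraction` × range, clipped to bounds) for
the remainder. Defaults mirror the reported configuration: population
200, elite 2, crossover fraction 1, 100 generations, stall limit 50,
rank scaling, stochastic-uniform selection, scattered crossover.
Migration settings are recorded but are no-ops for a single population.

Two deliberate deviations:

* With crossover fraction 1 and no named mutation operator the
  population loses diversity quickly, so a per-gene post-crossover
  mutation rate (default 0.01) is applied; set it to 0 for strict
  emulation.
* The fitted surfaces can be multimodal over the design box, and a
  single run may converge to a secondary basin. `optimize_multistart`
  (default 3 seeded restarts, used by the workflows and benchmarks)
  keeps the best run — the source likewise repeated its optimization
  "to ensure the global optima". The GA optimum is cross-checked in
  tests against a 21-points-per-axis exhaustive lattice (≈4.1 M
  evaluations, chunked), with a 0.5% agreement requirement.

Bounds default to the design box ([low star, high star] per factor).
The source's reported optimal compositions lie outside every printed
design bound (e.g. NaCl 0.45 > 0.3) and its reported optimum value
disagrees with its own equation evaluated there, so those two numbers
(6.283 and 9.934 U/mL) are not reproduction targets; the optimizer is
validated against the internal brute-force oracle instead.

## Comparison metrics

`rmse_standard` = √mean((obs−pred)²) in U/mL; `rmse_paper_scale` is
exactly 10× that, because the source's reported RMSE values (4.92 and
4.1) are exactly ten times the standard RMSE of its printed columns —
reproduced, not rationalized (possibly a unit slip). MAPE uses the
observed value as denominator and reproduces the reported 13.52%/7.8%.
R² is 1 − SSE/SST about the observed mean; the report's `r` is the
Pearson correlation of observed and predicted.

## Synthetic data and what passing tests show

`codmedia.synthetic` draws responses from a known truth (the published
quadratic by default, or any network) at the CCD points, adds i.i.d.
homoscedastic Gaussian noise, and assigns a random 24/6/6-proportioned
split per replicate (so network tests do not overfit one fixed
partition). The default noise sd of 0.15 U/mL matches the spread of
the 10 replicated center points in the real table (observed
2.98–3.28 U/mL); the recovery benchmark uses 0.2 U/mL. The recovery
benchmark (200 replicates in the acceptance run) checks OLS coefficient
unbiasedness against Monte-Carlo standard errors and the distance
between the GA optimum of each refit and the truth's grid optimum.

The generator emulates the design structure and an idealized error
model only. Real fermentation data have run-to-run batch effects,
possibly heteroscedastic and non-Gaussian errors, and model
misspecification (the true response is not exactly quadratic); passing
recovery tests therefore validates the estimation machinery, not the
biology. Problem sizes in tests and benchmarks (e.g. 200 replicates,
3–10 restarts, 21-point grids) are the package's chosen defaults and
keep the full validation in the tens of seconds.

## Known limitations

* No lack-of-fit/pure-error decomposition, ridge analysis or stepwise
  term selection (the full 21-term model is always kept, as published).
* No regularization or architecture search for the network beyond a
  configurable hidden width; no constraint handling in the GA beyond
  boxes.
* The printed table's two suspect cells and the printed equation's
  linear part are irreconcilable with each other; the package preserves
  the data verbatim and documents the conflicts rather than guessing a
  correction.
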