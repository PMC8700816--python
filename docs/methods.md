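# Methods

## Scheffé mixture models and transforms

Mixture fractions satisfy `Σ xᵢ = 1`, so a polynomial in the fractions
has no identifiable intercept; the Scheffé canonical forms absorb it into
the linear blending coefficients. `mixsurf` supports linear, quadratic,
special-cubic (`xᵢxⱼxₖ`) and reduced-cubic (`xᵢxⱼ(xᵢ−xⱼ)`) term sets, and
arbitrary subsets of them as long as all q linear terms are present
(dropping a linear term from a no-intercept model silently changes the
meaning of the rest, so `ModelSpec` refuses it).

Responses may be fitted on a transformed scale (`sqrt`, `ln`, `inverse`,
`inverse_sqrt`, `power(λ)`). The transform is part of the model: noise is
assumed additive Gaussian on the transformed scale, all ANOVA sums of
squares live there, and `predict` back-transforms to original units. For
the bundled nanoemulsion study the droplet diameter and IC50 models use
the `sqrt` scale and the two colony-count models the raw scale; the
choice was frozen by comparing each candidate transform's corrected
total sum of squares against the study's printed ANOVA totals (√d3.2
gives 2.065 against a printed 2.07; the raw scale gives 16.6).

## Fitting and fit statistics

Least squares via `numpy.linalg.lstsq` after an explicit rank check: a
reciprocal condition number of the model matrix below 1e-10 raises
instead of silently pseudo-inverting, because a rank-deficient mixture
model usually means the design cannot estimate the requested terms.
Reported statistics:

- `R² = 1 − RSS/SS_corr`, `R²_adj` with the usual df correction;
- `PRESS = Σ (eᵢ/(1−hᵢᵢ))²` via leverages, with the convention that a
  run with leverage 1 and zero residual contributes nothing (the deleted
  fit interpolates it); `R²_pred = 1 − PRESS/SS_corr`;
- `SD = √MSE` and `CV% = 100·SD/mean`, both on the transformed scale.
  Computing CV on the modeling scale is a deliberate choice; it keeps
  the statistic consistent with the MSE it is derived from.

## Mixture ANOVA

Sources follow the convention of mixture-design software:

- **Model**: `SS_corr − RSS`, df = p − 1 (one df absorbed by the
  mixture constraint), F against the residual mean square.
- **Linear Mixture**: Type I (sequential) SS of the q linear terms
  entered immediately after the mean, df = q − 1.
- **Each non-linear term**: partial (drop-one) SS from the full model,
  df = 1. Type I and partial SS answer different questions; the
  per-term rows deliberately use partial SS so each term is judged in
  the presence of all others.
- **Lack of Fit / Pure Error**: pure-error SS is the within-replicate-
  group SS of the transformed response with df `Σ(nₘ − 1)`; lack of fit
  is the remainder, tested against the pure-error mean square. Designs
  without replicates omit the split and set `lof_omitted`.

Additivity (`Model + Residual = Cor Total`, `LOF + PE = Residual`, in SS
and df) is asserted in tests at 1e-8 relative. A numerically perfect fit
caps F ratios at a sentinel (1e12) with p = 0 rather than overflowing.

Backward elimination (`reduce_model`) drops the non-linear term with the
largest partial-F p-value above α, refits, and repeats; linear terms are
never candidates. Note the family-wise consequence: with k null
candidate terms, some interaction survives in up to ~kα of datasets —
the Monte-Carlo test asserts exactly this ceiling rather than a stricter
one no α-level procedure could meet.

## I-optimal design construction

The I-criterion is the average scaled prediction variance
`mean_g f(g)ᵀ(XᵀX)⁻¹f(g)` over a uniform barycentric grid (default step
0.02) of the simplex. Candidate sets are lattice points plus the
centroid and axial check blends. The search is point exchange: from each
random start, swap one design run for one candidate whenever the
criterion strictly decreases, to local convergence; the best of
`n_starts` starts wins. This is the standard greedy realization; it
guarantees no worse a criterion than its initialization and, in tests,
dominates 1000 random subsets of the same size. Replicate augmentation
duplicates the centroid first and then the highest-leverage blends, so
that the augmented design carries pure-error df for the lack-of-fit
test; each added duplicate raises the pure-error df by exactly one.

## Desirability optimization

Derringer–Suich ramps: for a minimize goal with bounds (L, U) and target
T = L, `d = 1` at or below T, `0` at or above U, `((U−ŷ)/(U−T))^w`
between. Defaults chosen for the bundled study: bounds at each
response's observed min/max, weight 1, equal importance — and
predictions better than the observed best saturate at d = 1, which keeps
D ≤ 1 without rewarding extrapolation. Overall desirability is the
importance-weighted geometric mean, so any zero vetoes a blend.

The optimizer evaluates every barycentric grid point (default step
0.005, i.e. 0.5% compositional resolution, ~20k points for q = 3 —
comparable to the precision at which optimal blends are reported), then
polishes the 10 best points with Nelder–Mead in the q−1 free coordinates
projected back onto the simplex. The procedure is deterministic; the
`seed` argument is recorded in the result metadata for replay
bookkeeping. Refining the grid or adding polish can only raise the
returned D (asserted in tests at steps 0.05 → 0.02 → 0.005).

On the bundled study this reproduces the published optimization closely
but not identically: the maximum D is 0.976 (published: 0.97) at
21.2/61.8/17.0% cumin/carvi/coriander (published: 19.07/60.09/20.84).
The desirability surface is nearly flat along a carvi-rich ridge — D at
the published blend is within ~0.006 of the maximum — so the argmax
location is far less stable than the value of D itself, and small
differences in fitted coefficients or optimizer internals move it by a
point or two of composition.

## Bundled dataset and its quirks

The embedded 17-run study (12 distinct blends; centroid ×4 and two
binary blends ×2, giving 5 pure-error df) ships with the four published
model specifications. Refitting reproduces the published coefficients
essentially exactly (e.g. the IC50 linear coefficients 3.26544 / 3.1486
/ 3.98479) and three of the four published R² values within 0.07
points. The published R² for the 9-term droplet-size equation (99.24%)
is *not* reproduced: the same fit that returns the published
coefficients to 4–5 decimals yields R² = 98.49% on the table as printed,
so that one printed value appears to have been computed on unrounded
data. It is reported as a known discrepancy rather than hidden. The
published per-response CV values are likewise not reproducible from the
printed tables under any transform tried; `mixsurf` reports its own
transformed-scale CVs. Colony-count responses are stored as absolute
CFU/mL; their "± SD" companion columns are carried as data and used by
no computation.

## Synthetic data generator

`simulate_responses` draws transformed-scale Gaussian noise around a
known Scheffé surface and back-transforms, which is exactly the
assumption set of the fitting machinery — so noiseless draws refit to
the true coefficients to 1e-8 (asserted for every transform) and noisy
draws exercise model reduction and coverage behaviour with known truth.
Default noise sd 0.05 on the transformed scale gives residual mean
squares comparable to the bundled study's ANOVA (sqrt-scale MS ≈
0.002–0.005). What the generator does *not* emulate: original-scale
heteroscedasticity beyond what the transform implies, run-order drift,
replicate-batch effects, or measurement rounding — so passing tests
demonstrate correctness of the statistical machinery, not robustness to
those real-data features.

## Formulation metrics

Closed forms with input validation: Sauter mean `Σnd³/Σnd²` (bounded by
the min/max diameter, homogeneous of degree 1); DPPH inhibition
`100(A_blank−A_sample)/A_blank`; IC50 by linear interpolation of
inhibition against log₁₀ concentration (serial dilutions are geometric,
so log-concentration is the natural axis), refusing unbracketed levels;
droplet growth ratio `(d_n−d₀)/d₀`; FICI as the sum of combination-to-
solo MIC ratios. FICI categories default to the conventional
checkerboard breakpoints (≤0.5 synergy, ≤1 additive, ≤4 indifferent,
>4 antagonism) but are configurable, since practice varies: indices just
above 0.5 are reported as "synergy" in parts of the literature while the
strict rule calls them additive.

## Known limitations

- Only the unconstrained simplex is supported as a design region; no
  upper/lower component bounds or process variables.
- No Box–Cox λ estimation; transforms are chosen from the named family.
- The desirability optimum carries no uncertainty measure; the flat-
  ridge behaviour above is the practical consequence.
- The combination-index statistic occasionally quoted alongside FICI in
  formulation work has no agreed closed form and is not implemented.
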