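# Methods

This note documents the models and procedures implemented in `adjuscreen`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic cohorts do and do not establish about real data.

## Data model

A screening library of `n` substances is described by three blocks
`X_b ∈ R^{n×p_b}`: human PBMC cytokine concentrations (18 analytes), mouse
splenocyte cytokine concentrations (23 analytes), and the percentage
composition of 16 nanoparticle scatter populations; and by an outcome table
`Y ∈ R^{n×6}` of in-vivo adjuvanticity endpoints: fold-change total IgG,
IgG1 and IgG2c endpoint titers against the antigen-alone group, and
background-subtracted IgE, IL-13 and IFN-γ concentrations. Rows are aligned
across all tables by substance id; particle rows must sum to 100 (±1e-6)
and cytokine entries must be non-negative.

## Preprocessing

**Endpoint titers.** An ELISA dilution series (reciprocal dilutions `d_i`,
strictly increasing; absorbances `OD_i`) is interpolated piecewise linearly
in `(log10 d, OD)`; the endpoint titer is the dilution at which the curve
first crosses the cutoff absorbance 0.2, scanning from the lowest dilution.
"Log-linear" is read as log on the dilution axis because titers are
reported on the dilution scale and ELISA response is near-linear in
log-dilution over the working range. Series entirely below (above) the
cutoff are censored low (high) at the nearest measured dilution and
flagged rather than extrapolated. Non-monotone series crossing more than
once use the first crossing and emit a warning.

**Group summaries.** Fold change is the ratio of arithmetic group means
(group over antigen-alone reference); background subtraction is the
difference of arithmetic means floored at 0, since downstream blocks assume
non-negative concentrations. Per-animal fold changes are out of scope.

**Standardization.** Columns are centered and scaled to unit sample SD
(`n−1` denominator). Zero-variance columns carry no information for any
correlation-based analysis and are dropped with a warning rather than
imputed.

## Scatter gating

The instrument records 4 decades of FSC and SSC intensity. The gate grid
places one bin per decade on each axis (log10 edges 0,1,2,3,4 by default),
giving 16 cells lettered A–P row-major with rows ordered by descending SSC
and columns by ascending FSC: A is the lowest-FSC/highest-SSC cell, D the
highest-FSC/highest-SSC, M the lowest-FSC/lowest-SSC (the smallest,
dimmest particles), P the highest-FSC/lowest-SSC. Cells are half-open
`[low, high)` with the top edge closed; events outside the grid are counted
out-of-range, never clipped. Per-population counts from a paired PBS blank
(same flow rate and duration) are subtracted and clamped at 0 — counts
cannot be negative — and the corrected counts are closed to percentages
over the 16 gates. The denominator is the corrected total, not the raw
event count, so the profile is a true composition; an all-zero corrected
vector yields an all-zero profile flagged degenerate.

## PCA

Principal components are the right singular vectors of the centered
(optionally standardized) matrix. Sign indeterminacy is resolved by making
the largest-magnitude entry of each loading vector positive, so repeated
runs are bit-identical.

## Regularized CCA

Classical CCA maximizes `corr(Xa, Yb)` and requires nonsingular block
covariances (`n > p + q`). The regularized variant replaces the covariances
with `S_xx + λ₁I` and `S_yy + λ₂I`; weights come from the SVD of the
whitened cross-covariance `(S_xx+λ₁I)^{-1/2} S_xy (S_yy+λ₂I)^{-1/2}`. At
λ→0 this is classical CCA; at λ→∞ the weight directions converge to the
singular vectors of the cross-covariance (the PLS solution); for λ>0 it is
well-defined when features outnumber samples. Reported canonical
correlations are the sample correlations of the fitted score pairs,
oriented non-negative — identical to the generalized eigenvalues in the
classical case and always a bona fide correlation under regularization.
Penalties are tuned by grid search (default log grid 1e-4…1) on the
cross-validated correlation of the held-out first score pair (5-fold);
ties resolve to the smallest λ₁+λ₂. The feature-feature similarity matrix
(the heatmap quantity) sums, over latent dimensions, the products of the
correlations of each X and Y feature with the per-dimension average of the
two score vectors; the number of dimensions used is a parameter because
either convention (first-dimension-only or multi-dimension) is defensible.

## Sparse multiblock PLS and its discriminant variant

The sparsity operator `soft_select(v, keep)` zeroes all entries outside the
`keep` largest magnitudes, shrinks survivors by the largest excluded
magnitude (`sign(v)·(|v|−τ)₊`), and L2-normalizes. Boundary ties break
toward the lowest feature index. In the degenerate case where the boundary
tie makes every survivor shrink to exactly zero, survivors keep their
unshrunk values so the selection is preserved; this affects only exact
ties.

Per component, the solver iterates over blocks: block `b`'s weight is
`soft_select` of `Σ_k design[b,k]·X_bᵀt_k`, the design-weighted covariance
with the other blocks' current scores; the outcome matrix participates as
an extra block with dense (normalized) weights. Iteration stops when the
largest L2 change of any score vector falls below `tol` (default 1e-6,
`max_iter` 500; non-convergence raises an error carrying the last iterate).
Deflation is regression-mode: each block is deflated on its own score, the
outcome block on the average of the block scores. The default design
connects the outcome to every block with weight 1 and blocks to each other
with weight 0.1 (favoring discrimination over block-block agreement); it is
configurable since no single design is canonical. With one dense block the
procedure reduces exactly to NIPALS PLS2 (verified against an independent
reference in the tests); with `keepX=1` and a single outcome column it
selects the feature of maximal absolute covariance.

The discriminant variant dichotomizes an outcome at the cohort mean
(strictly above → "high", at or below → "low"; a constant outcome is an
error), joins the column-centered class indicator matrix as the outcome
block, and tags each selected feature with its *dominant class* — the class
with the larger within-class mean of that feature. This tag is what labels
a particle population a *negative* parameter (dominant in the low class).
`keepX` is chosen by repeated stratified cross-validation (default 3
repeats × 5 folds), classifying held-out samples by nearest class centroid
in the averaged block-score space and minimizing balanced error rate; ties
resolve to the smallest total `keepX`. Blocks are re-standardized inside
each training fold and the training scaling applied to the held-out
samples, so tuning never sees test-fold statistics.

All weight vectors have unit norm, all scores are centered, and every sign
indeterminacy is resolved deterministically (largest-magnitude weight entry
positive), making fits bit-reproducible.

## Screening

A positive screen passes values at or above the threshold; a negative
screen passes values strictly below it — the boundary convention is chosen
so a substance sitting exactly at a negative threshold is rejected (the
conservative screen). Auto thresholds are the arithmetic mean over *all*
substances (extracts and controls jointly). The two-step screen is the
logical AND of the negative rule and the positive rule, with step-wise
survivor counts reported; its mask is by construction a subset of the
negative step's. Separation between screened and non-screened groups is an
unpaired two-tailed pooled-variance Student's t-test (Welch available
behind a flag); the two-step p-value compares pass-both against all others
(comparing against step-1 survivors only is exposed by screening the
survivor subset explicitly, without claiming either as canonical).

PCA discrimination standardizes the chosen parameter matrix, splits
component-1 scores at their mean (zero under centering; the threshold is
still computed explicitly), and labels as "screened" the side whose
substances have the higher mean of the designated positive parameters.
Because the orientation anchor is the data itself, globally negating the
input leaves the score partition unchanged while the screened label follows
the positive parameters in the matrix as given; the label cannot be — and
is not claimed to be — invariant under data negation.

## Synthetic cohorts

The generator emulates the statistical skeleton the analysis assumes, not
any particular assay's numbers. Two independent standard-normal latent
factors per substance drive everything: `z_pos` loads (coefficient
`effect_pos`, default 1) on five designated cytokines per species block;
`z_neg` raises the log-abundance of one designated particle population
(default M) while lowering all outcomes. Cytokine concentrations are
exponentiated Gaussians (non-negative, right-skewed, residual SD
`noise_sd` = 0.5 on the log scale); particle profiles are softmax-closed
compositions of Gaussian log-abundances with baseline weights making J, K,
N and H the major populations; outcomes are
`exp(w_pos·z_pos − w_neg·z_neg + noise)` with default `(w_pos, w_neg) =
(1, 0.5)` — the negative factor present but secondary, so the positive
screen is already informative and the negative step refines it. The default
cohort is 73 extracts plus 7 controls, the controls drawn from the same
model with a +1 SD shift on `z_pos` (potent known adjuvants). Two factors
are independent rather than one bipolar factor precisely so that a
two-step screen can beat a one-step screen.

What passing tests on these cohorts show: the solvers recover planted
sparse signals at realistic n/p, the dominant-class tagging identifies a
negative compositional parameter, and pairing it with a positive screen
improves separation in the majority of cohorts (65–75% across seed
batches; the median-p comparison over a 100-cohort batch is also usually
but not invariably in favor, since the two p distributions overlap).
What they do not show: robustness to plate effects, donor variability,
spectral spillover, detection limits, or any calibration to real assay
scales — no distributional summaries of real measurements back the
defaults, which are free knobs chosen once for plausibility.

Fixture generators for the upstream operations are exact by construction:
scatter events are placed uniformly inside their assigned log-grid cell so
re-gating recovers the multinomial draw; dilution curves are built so the
log-linear interpolation crosses 0.2 exactly at the requested titer (the
bracketing pair is solved analytically; remaining points are random but
strictly monotone).

## Numerical choices and limitations

- Problem sizes in tests and the acceptance script: 20 cohorts for
  parameter recovery, 100 cohorts for screening comparisons, 50 repeats
  for PCA discrimination, 5 000 events for gating, 100 titers for the
  interpolation round trip — sizes at which every Monte-Carlo margin is
  wide relative to its threshold while a full run stays under a few
  seconds.
- rCCA uses plain ridge regularization; shrinkage-estimated covariances
  are out of scope. Discrimination is two-class only.
- No multiple-testing correction is applied across endpoints or screens.
- Convergence tolerance 1e-6 suffices for selection stability; oracle
  comparisons at 1e-8 are run at tol 1e-12 since the power iteration's
  terminal error is of the order of the stopping criterion.
- The solvers are deterministic; all stochastic stages (cohort generation,
  CV splits) take explicit seeds and no global random state is touched.
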