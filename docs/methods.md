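# Methods

## Scope

`plmatch` models and analyzes the quantitative side of a TurboID
proximity-labeling experiment: what the streptavidin enrichment measures,
how that measurement depends on the control cell line's TurboID expression,
and how to pick and score controls. It takes protein groups as given (no
protein inference), consumes a long-format precursor report as produced by
DIA search engines, and does not model retention time, ion mobility,
charge-state physics, chimeric spectra, or batch effects.

## Generative model of the experiment

Per protein *i* and sample *s* in group *g* with relative TurboID
expression `E_g`, the expected captured signal is

    S_is = B_i + E_g * A_i * P_ig * kappa + D * 1[endog_i]
    B_i  = beta0 * A_i^gamma * exp(delta * (pI_i - pI_mean))

- `A_i` — whole-cell abundance, LogNormal(mu_A, sigma_A). Defaults
  mu_A = ln(1e5), sigma_A = 2.3 (≈1 decade sd; ~4–5 decades of dynamic
  range, typical of a cell-line proteome). The absolute scale is arbitrary
  MS intensity units; what matters is its ratio to the detection limit,
  chosen so that the bottom abundance quartile sits below the limit at low
  TurboID expression but becomes measurable at high expression.
- `B_i` — streptavidin-bead background. `gamma = 1.3 > 1` makes capture
  superlinear in abundance, so the no-TurboID background is dominated by
  the top abundance quartile and the relative gain of abundant proteins is
  compressed (their background forms an expression-independent floor).
  `beta0 = 2e-4` places the background detection threshold at the boundary
  of the top abundance quartile. `delta = 0.1` gives the mild high-pI bias
  of bead binders; pI ~ Normal(7, 1).
- `P_ig` — proximity factor: `rho = 8` for true interactors
  (`frac_interactors = 0.1`) in bait-role groups, 1 otherwise. An 8-fold
  boost is a strong but realistic proximity signal and leaves the
  4×-over-expressing control able to halve it — the regime where false
  negatives appear.
- `D = 5e7` for the `frac_endog = 1%` of proteins drawn from the top
  abundance decile that carry biotin independently of TurboID
  (carboxylase-like). The level dominates these proteins' own labeling
  signal, so they are detected even without TurboID and respond to
  normalization, not to expression — which is exactly what makes them
  canonical false positives under a mismatched, normalized control.
- `kappa = 1` — only relative expression matters; unit rescalings of all
  intensities are equivalent.

Each protein owns `1 + Poisson(3)` peptides; 20% of peptides appear at a
second charge state (two precursors, one unique peptide — this exercises
the charge-collapsed unique-peptide filter). Precursor response fractions
are drawn once per protein from a symmetric Dirichlet(1) and shared across
samples, the standard fixed-response-factor assumption that makes sum,
Top1 and MaxLFQ-style aggregation comparable. Observed cell intensity is
`S_is * fraction * exp(eps)`, `eps ~ Normal(0, 0.25²)` on the natural-log
scale (~25–30% CV, typical label-free precision). Detection is censored at
`LOD = 1000` through a logistic dropout in ln-intensity with width 0.25
(set the width to 0 for a hard threshold). All draws derive from a single
seed; identical configuration gives byte-identical output.

### What the simulator reproduces, and what it does not

Reproduced (and asserted by the test suite): identification counts rising
with TurboID expression; per-protein intensity near-linear in expression;
no-TurboID background dominated by the top abundance quartile; larger
relative intensity gains for low- than high-abundance proteins as
expression rises; endogenous-biotin proteins surfacing as apparent
interactors under a normalized, over-expressing control; and the
false-positive/false-negative asymmetry of under-/over-expressing
controls. Not modeled: peptide-specific ionization interference, shared
peptides between protein groups, replicate-level expression variability
within a group, batch effects, and label-free ratio compression. Passing
tests therefore demonstrate that the *analysis* behaves correctly under a
faithful abstraction of the measurement process, not that any specific
real dataset will show these exact magnitudes.

## Pipeline

Order is filter → normalize → aggregate → impute → log2 → test, enforced
by provenance flags on the matrix (running a stage out of order raises).

- **Unique-peptide filter** (default k = 2): peptides are distinct modified
  sequences with charge collapsed; counting is across all samples.
- **Total-intensity normalization**: every sample scaled so its summed
  precursor intensity is 1e7; idempotent; applied at precursor level before
  aggregation. Composition caveat: when the bait carries many strongly
  enriched interactors, its total intensity is inflated and normalization
  shifts all null proteins negative (~−0.5 log2 under the reference
  conditions). Enrichment calls are robust to this; de-enrichment calls on
  normalized data are not, and the per-control error accounting therefore
  counts only the enriched arm as discoveries.
- **Aggregation**: `sum` (default); `top1` picks each protein's globally
  most intense precursor once (ties by lexicographic id) for cross-sample
  consistency; `maxlfq` estimates pairwise sample log-ratios as medians
  over shared precursors, solves per-sample log-abundances by least squares
  on the ratio graph per connected component (mean-zero gauge), and
  rescales to the sum aggregate's total. Singleton components fall back to
  the sample's summed intensity. Delayed normalization is out of scope.
- **Imputation**: missing cells get the per-sample q-quantile (default
  q = 0.01) of present values, linear interpolation between order
  statistics at h = (n−1)q + 1 (the common default across statistical
  environments; stated explicitly because conventions differ). A global
  variant (`scope="global"`) is available; per-sample is the default since
  imputation happens at the analyzed-matrix level immediately before log2.
- **Moderated test**: prior (d0, s0²) by moment matching on
  log s²_g — e_g = log s²_g − digamma(d_g/2) + log(d_g/2); mean(e) and the
  excess of var(e) over trigamma(d_g/2) identify s0² and d0, with the
  trigamma inverse found by monotone bracketing root-finding. When the
  observed dispersion does not exceed its sampling expectation, d0 = ∞ and
  s0² is the mean residual variance (complete shrinkage). Residual
  variances are floored at 1e-12 before estimation so constant-imputed
  proteins cannot produce infinite statistics while keeping their ranks.
  p-values are two-sided from t with d0 + d_g df (normal when d0 = ∞).
  Plain moderation only — no trend or robust variants; with small,
  homogeneous designs the difference is minor, and the plain form is the
  one whose classical limits (d0 = 0 pooled t; d0 = ∞ common variance) are
  exactly testable. Contrast is always bait − control, two groups.
- **Calls**: enriched ⇔ log2FC > log2(2) and BH-adjusted p < 0.05
  (strict inequalities); mirrored for de-enriched.
- **π-score**: −log10(p_raw) · sign(log2FC); p = 0 clamps to the smallest
  positive float with a warning; sign(0) = 0.

## Evaluation layer

- **Occurrence frequency**: per protein, the number of per-control
  comparisons calling it enriched; proteins missing from a comparison
  count 0 there; high confidence at ≥ threshold (default 3).
- **ROC**: proteins scored by π-value; negatives are all quantified
  proteins outside the positive set; AUROC via the rank (Mann–Whitney)
  formula with ties averaged, which the tests verify equals trapezoidal
  integration of the empirical curve.
- **Abundance quartiles**: rank-based, Q1_top = most abundant 25%, ties
  broken by stable id order; top-1% flag uses ceil(0.01·n).
- **Relative intensity**: per-protein group-mean (unlogged) over baseline
  group-mean; proteins absent from the baseline are excluded; per-quartile
  summaries are arithmetic means of per-protein ratios (not ratios of
  means).
- **Expression-response fits**: OLS of group-mean intensity on group
  expression, requiring ≥ 3 usable groups; R² defined as 0 for a
  zero-variance response (no expression response by construction). Group
  means rather than replicate-level values are used, with group expression
  taken as the mean of its samples' values.
- **Matching report**: per candidate control, expression mismatch
  log2(E_ctrl/E_bait), call counts, and — with ground truth — TP/FP/FN over
  the enriched arm only (interactome accounting: de-enrichment is reported
  but is not a discovery). The recommended control minimizes |mismatch|.

## Numerical choices and degenerate inputs

Zero/blank intensities in input reports are treated as not-detected (the
common convention of DIA exports). Missing cells serialize as `NA`; floats
serialize with 17 significant digits so round trips are exact to well below
1e-12 relative. A precursor mapped to two protein groups, duplicate
(sample, precursor) pairs, duplicate sample ids, and zero TurboID
expression outside no-TurboID samples are construction-time errors. A
sample with no present values cannot be imputed and errors; an all-zero
residual-variance matrix is a degenerate fit and errors.

## Problem sizes

The test suite and the acceptance script run everything on simulations of
2000 proteins × 3 replicates per group (the reference conditions), with
50–100 replicate simulations for calibration quantities and 20 for the
full control-titration benchmark; the whole acceptance script completes in
about a minute on one CPU. These sizes give stable estimates of every
reported fraction while keeping iteration fast.

## Known limitations

- Ambiguity from peptides shared between close paralogs is out of scope:
  protein groups are opaque ids and each precursor belongs to exactly one.
- Total-intensity normalization's composition bias (above) means
  de-enrichment calls on normalized data from interactor-rich baits should
  not be interpreted as depletion.
- The MaxLFQ-style aggregator implements the protein-ratio solver core
  only; without delayed normalization its absolute levels are anchored to
  the sum aggregate.
- Group-level expression is treated as exact; real titrations have
  within-group expression spread that propagates into the fits.
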