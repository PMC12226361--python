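# plmatch

Expression-matched control analysis for TurboID proximity-labeling
proteomics.

## The problem

Proximity labeling with TurboID identifies a bait protein's neighbors by
biotinylating nearby proteins, enriching them on streptavidin beads, and
quantifying them by mass spectrometry. The catch is the control: background
labeling scales with how much TurboID the control cells express. A control
expressing less TurboID than the bait fusion makes everything look
bait-enriched (false positives); a control expressing more swamps true
interactors in background (false negatives); and intensity normalization
cannot fully repair the mismatch because its distortion depends on protein
abundance — it even promotes endogenously biotinylated background proteins
(ACACA-like carboxylases) into apparent interactors. The remedy is to match
the control's TurboID expression to the bait's.

`plmatch` implements the full desk side of such a study for people running
or evaluating TurboID/BioID experiments: quantification of a DIA-NN-style
precursor report into a protein matrix, moderated differential testing,
cross-control consensus scoring, ROC benchmarking, and a seeded simulator
of proximity-labeling experiments with known ground truth so every claim
above can be measured rather than asserted.

## The model

**Quantification.** Proteins with < 2 unique peptides are dropped; each
sample is scaled so its summed precursor intensity is 10,000,000; protein
intensity is the precursor sum (alternatives: Top1 = the single most
intense precursor chosen consistently across samples, or a MaxLFQ-style
estimate from median pairwise log-ratios solved by least squares); missing
values are imputed at the per-sample 1% quantile; intensities are
log2-transformed.

**Testing.** For each protein *g* with pooled two-group residual variance
*s²_g* on *d_g* degrees of freedom, an empirical-Bayes prior (*d₀*, *s₀²*)
is estimated by matching the moments of log *s²_g* under a scaled-F model,
and the moderated statistic is

    t_g = (x̄_bait − x̄_ctrl) / (s_post,g · √(1/n₁ + 1/n₂)),
    s²_post,g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),   t_g ~ t(d₀ + d_g)

with Benjamini–Hochberg adjustment, calls at fold change > 2 and adjusted
p < 0.05, and the signed score π = −log₁₀(p) · sign(log₂FC) for ranking.

**Simulation.** Expected captured signal per protein *i* in group *g*:
`S = B_i + E_g·A_i·P_ig + D·[endogenously biotinylated]`, where `A_i` is
whole-cell abundance (log-normal), `B_i = β₀·A_i^γ·exp(δ(pI_i − p̄I))` is
streptavidin-bead background, `E_g` the group's relative TurboID
expression, and `P_ig` the proximity factor (ρ for true interactors in
bait samples). Signal is split over fixed per-protein peptide fractions,
jittered with log-normal noise, and censored at a detection limit —
which reproduces the expression-dependent identification counts and
abundance-dependent relative gains seen in real titrations.

## Worked example

`examples/04_control_matching.py` simulates a bait with three controls at
0.25×, 1× and 4× the bait's TurboID expression and scores each comparison
against ground truth:

```
              expression_mismatch  n_enriched  ...  false_positives  false_negatives
control
ctrl_low                     -2.0        1765  ...             1571               11
ctrl_matched                  0.0         193  ...                1               13
ctrl_high                     2.0         103  ...                0              102

recommended control: ctrl_matched
AUROC[ctrl_low] = 0.985
AUROC[ctrl_matched] = 1.000
AUROC[ctrl_high] = 1.000
```

Reading: the under-expressing control calls 1765 proteins enriched, of
which 1571 are false — nearly the whole detectable proteome looks like an
interactor. The over-expressing control misses 102 of ~205 true
interactors. The matched control finds 192 of them with a single false
positive, and is what the report recommends (smallest |expression
mismatch|). The other scripts in `examples/` cover simulation, the
quantification stages, the moderated test, consensus across controls, the
normalization artifact, and the expression titration; each prints a short
interpretation alongside its numbers.

A thin CLI wraps the same library calls:

```bash
plmatch simulate --seed 5 --out sim/
plmatch quantify --report sim/report.tsv --design sim/design.tsv --method sum --out matrix.tsv
plmatch diffexp --matrix matrix.tsv --design sim/design.tsv --bait bait --control ctrl_matched --out diff.tsv
plmatch consensus --diff diff1.tsv --diff diff2.tsv --threshold 3 --out consensus.tsv
plmatch evaluate --design sim/design.tsv --bait bait --diff-dir diffs/ --truth sim/truth.tsv --out report.tsv
plmatch run --config pipeline.yaml --out results/
```

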