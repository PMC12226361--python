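"""Why the control's TurboID expression should match the bait's.

Compares the bait against controls at 0.25x, 1x and 4x its TurboID
expression on the non-normalized path. An under-expressing control inflates
false positives (everything looks enriched); an over-expressing control
inflates false negatives (true interactors are swamped by the control's
stronger background labeling). The matched control minimizes both.
"""
import plmatch as pm

table, design, _, truth = pm.simulate_experiment(pm.SimConfig(seed=1))
matrix = pm.quantify_pipeline(table, normalize=False)
results = pm.differential_per_control(matrix, design, "bait")
report = pm.matching_report(results, design, "bait", truth=truth)

cols = ["expression_mismatch", "n_enriched", "true_positives",
        "false_positives", "false_negatives"]
print(report.controls[cols].round(2))
print("\nrecommended control:", report.recommended_control)

for control in results:
    auc, _ = pm.roc_analysis(results[control], set(truth.interactors))
    print(f"AUROC[{control}] = {auc:.3f}")
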