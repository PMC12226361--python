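"""Evaluation layer: cross-control consensus, ROC against known
interactors, abundance-quartile relative-intensity analysis, per-protein
expression-response fits, and the expression-matching report.

These operations answer the study-design question at the heart of the
package: which control, among candidates with different TurboID expression,
gives the most faithful interactome? The matching report quantifies the
expected answer — the control whose TurboID expression matches the bait's —
by counting enriched/de-enriched calls and, when simulator ground truth is
available, false positives and false negatives.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import DesignError
from .simulate import GroundTruth
from .types import (
    QUARTILE_LABELS,
    ConsensusResult,
    DiffResult,
    ProteinMatrix,
    QuartileMap,
    StudyDesign,
)


def occurrence_frequency(results: Sequence[DiffResult], threshold: int = 3) -> ConsensusResult:
    """Count, per protein, the comparisons in which it was called enriched.

    Proteins absent from a comparison contribute 0 for that comparison.
    ``high_confidence`` flags proteins enriched in >= ``threshold``
    comparisons.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need >= 2 differential results for a consensus")
    if threshold < 1 or threshold > len(results):
        raise ValueError(
            f"threshold must be in [1, {len(results)}], got {threshold}"
        )
    universe = pd.Index(sorted(set().union(*(set(r.proteins) for r in results))), name="protein")
    freq = pd.Series(0, index=universe, dtype=int)
    for r in results:
        freq.loc[r.enriched()] += 1
    table = pd.DataFrame({
        "occurrence_frequency": freq,
        "n_comparisons": len(results),
        "high_confidence": freq >= threshold,
    })
    return ConsensusResult(table, threshold=threshold)


def auroc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by the rank (Mann-Whitney) formula with ties averaged."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(scores)  # ascending, ties averaged
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_analysis(result: DiffResult, positives) -> tuple[float, pd.DataFrame]:
    """ROC of the pi-value score against a known-interactor set.

    Proteins are scored by pi_value (descending = most bait-enriched);
    negatives are all quantified proteins not in the positive set. Returns
    the AUROC and the ROC curve points (fpr, tpr, threshold).
    """
    pos = set(positives)
    tab = result.table
    labels = tab.index.isin(pos)
    if labels.sum() == 0:
        raise ValueError("no positives among the quantified proteins")
    if labels.all():
        raise ValueError("no negatives among the quantified proteins")
    scores = tab["pi_value"].to_numpy(dtype=float)
    auc = auroc_rank(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def abundance_quartiles(wholecell: pd.Series) -> QuartileMap:
    """Assign abundance quartiles (Q1_top = most abundant 25%) and flag the
    top 1% most abundant proteins. Ties are broken by stable protein-id
    order after the abundance sort."""
    if len(wholecell) == 0:
        raise ValueError("empty abundance table")
    ab = wholecell.astype(float)
    if (ab <= 0).any():
        raise ValueError("abundances must be positive")
    # stable sort on (-abundance, id): equal abundances keep id order
    ordered = ab.sort_index().sort_values(ascending=False, kind="stable")
    n = len(ordered)
    labels = np.empty(n, dtype=object)
    bounds = [round(n * f / 4) for f in range(5)]
    for qi in range(4):
        labels[bounds[qi]:bounds[qi + 1]] = QUARTILE_LABELS[qi]
    n_top = int(np.ceil(0.01 * n))
    top1 = np.zeros(n, dtype=bool)
    top1[:n_top] = True
    table = pd.DataFrame(
        {"abundance_quartile": labels, "top1pct": top1}, index=ordered.index
    ).loc[wholecell.index]
    return QuartileMap(table)


def relative_intensity(
    matrix: ProteinMatrix,
    design: StudyDesign,
    baseline_group: str,
    quartiles: QuartileMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-protein relative intensities against a baseline group.

    Group means use unlogged intensities over present cells. The ratio for a
    protein is group mean / baseline mean, missing when the protein has no
    present baseline cell. With a :class:`QuartileMap`, per-quartile
    arithmetic means of the ratios are also returned (proteins missing in
    the baseline are excluded from the quartile means).
    """
    if matrix.log2:
        raise ValueError("relative_intensity expects unlogged intensities")
    if baseline_group not in design.groups:
        raise DesignError(f"baseline group {baseline_group!r} not in design")
    group_means = {}
    for g in design.groups:
        cols = [s for s in design.samples_in(g) if s in matrix.values.columns]
        if not cols:
            continue
        group_means[g] = matrix.values[cols].mean(axis=1)  # skipna
    means = pd.DataFrame(group_means)
    base = means[baseline_group]
    ratios = means.div(base, axis=0)
    ratios[base.isna()] = np.nan
    if quartiles is None:
        return ratios, None
    qlab = quartiles.table["abundance_quartile"].reindex(ratios.index)
    per_quartile = ratios.groupby(qlab, observed=False).mean()
    per_quartile = per_quartile.reindex(QUARTILE_LABELS)
    return ratios, per_quartile


@dataclass(frozen=True)
class ExpressionFitSummary:
    """Per-protein linear fits of intensity vs TurboID expression.

    ``fits`` has one row per protein with >= 3 usable group means (slope,
    intercept, r_squared, n_groups_used); ``fraction_above_threshold`` is
    the share of included proteins with R^2 above the threshold.
    """

    fits: pd.DataFrame
    r2_threshold: float
    fraction_above_threshold: float


def expression_response_fit(
    matrix: ProteinMatrix,
    design: StudyDesign,
    r2_threshold: float = 0.5,
    groups: Sequence[str] | None = None,
) -> ExpressionFitSummary:
    """Ordinary least-squares fit of per-protein group-mean intensity
    against group TurboID expression.

    Proteins with valid group means in fewer than three groups are
    excluded. R^2 is 1 - SS_res/SS_tot, defined as 0 when the response has
    zero variance.
    """
    if matrix.log2:
        raise ValueError("expression_response_fit expects unlogged intensities")
    use_groups = list(groups) if groups is not None else design.groups
    expr = np.array([design.group_expression(g) for g in use_groups])
    if len(use_groups) < 3:
        raise DesignError("need >= 3 groups for a per-protein line fit")
    if len(np.unique(expr)) < 3:
        raise DesignError("need >= 3 distinct expression levels")
    means = pd.DataFrame({
        g: matrix.values[[s for s in design.samples_in(g) if s in matrix.values.columns]].mean(axis=1)
        for g in use_groups
    })
    y = means.to_numpy()
    rows = []
    for i, protein in enumerate(means.index):
        ok = ~np.isnan(y[i])
        if ok.sum() < 3:
            continue
        xi, yi = expr[ok], y[i, ok]
        slope, intercept = np.polyfit(xi, yi, 1)
        resid = yi - (slope * xi + intercept)
        ss_tot = float(((yi - yi.mean()) ** 2).sum())
        ss_res = float((resid ** 2).sum())
        r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        rows.append((protein, slope, intercept, r2, int(ok.sum())))
    fits = pd.DataFrame(
        rows, columns=["protein", "slope", "intercept", "r_squared", "n_groups_used"]
    ).set_index("protein")
    frac = float((fits["r_squared"] > r2_threshold).mean()) if len(fits) else np.nan
    return ExpressionFitSummary(fits=fits, r2_threshold=r2_threshold,
                                fraction_above_threshold=frac)


@dataclass(frozen=True)
class MatchingReport:
    """Per-control comparison summary for the expression-matching workflow.

    ``controls`` has one row per candidate control group:
    expression_mismatch (log2 of control/bait TurboID expression), call
    counts, and — when ground truth is supplied — true/false positive and
    false negative counts over the enriched arm. ``recommended_control`` is
    the group minimizing |expression_mismatch|.
    """

    controls: pd.DataFrame
    bait_group: str
    recommended_control: str


def matching_report(
    diff_results: Mapping[str, DiffResult],
    design: StudyDesign,
    bait_group: str,
    truth: GroundTruth | None = None,
) -> MatchingReport:
    """Summarize differential results across candidate controls and
    recommend the expression-matched one.

    False positives / negatives follow the enriched arm only: FP = called
    enriched but not a true interactor; FN = true interactor not called
    enriched (whether missing or merely not significant); TP = called
    enriched and a true interactor.
    """
    if not diff_results:
        raise ValueError("no differential results supplied")
    e_bait = design.group_expression(bait_group)
    if e_bait == 0:
        raise ValueError("bait group has zero TurboID expression")
    interactors = set(truth.interactors) if truth is not None else None
    rows = []
    for control, result in diff_results.items():
        if result.bait_group and result.bait_group != bait_group:
            raise DesignError(
                f"result for control {control!r} was computed against bait "
                f"{result.bait_group!r}, not {bait_group!r}"
            )
        e_ctrl = design.group_expression(control)
        mismatch = np.log2(e_ctrl / e_bait) if e_ctrl > 0 else -np.inf
        calls = result.table["call"]
        row = dict(
            control=control,
            expression_mismatch=mismatch,
            n_enriched=int((calls == "enriched").sum()),
            n_de_enriched=int((calls == "de_enriched").sum()),
        )
        if interactors is not None:
            enriched = set(result.enriched())
            row["true_positives"] = len(enriched & interactors)
            row["false_positives"] = len(enriched - interactors)
            row["false_negatives"] = len(interactors - enriched)
        rows.append(row)
    controls = pd.DataFrame(rows).set_index("control")
    recommended = controls["expression_mismatch"].abs().idxmin()
    return MatchingReport(controls=controls, bait_group=bait_group,
                          recommended_control=str(recommended))
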