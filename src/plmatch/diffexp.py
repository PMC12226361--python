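"""Two-group moderated differential analysis.

Implements the empirical-Bayes moderated t-test: per-protein pooled residual
variances are shrunk toward a prior variance ``s0^2`` with prior degrees of
freedom ``d0`` estimated from the observed variance distribution by matching
the first two moments of ``log s_g^2`` under a scaled-F model (the standard
digamma/trigamma scheme). The moderated statistic

    t_g = log2FC_g / (s_post_g * sqrt(1/n1 + 1/n2)),
    s_post_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom. With
``d0 = 0`` this reduces exactly to the classical pooled two-sample t-test;
with ``d0 = inf`` every protein gets the common prior variance.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateFitError, DesignError, PipelineOrderError
from .types import DiffResult, EBayesFit, ProteinMatrix, StudyDesign

VAR_FLOOR = 1e-12  # floor for zero residual variances (constant imputation)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone root-finding.

    trigamma is strictly decreasing from +inf (x -> 0) to 0 (x -> inf), so
    the root is unique. Very small y maps to a huge x (near-infinite prior
    df); very large y to x near 0.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-8:
        return 1.0 / y
    f = lambda x: special.polygamma(1, x) - y
    # bracket: trigamma(x) ~ 1/x + 1/(2x^2) so these bounds are generous
    lo, hi = 1e-8, 1e9
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def _fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from residual variances by moment matching on
    log s^2. Returns d0 = inf and s0^2 = mean(s^2) when the observed
    dispersion of log s^2 does not exceed its sampling expectation."""
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return np.inf, float(np.mean(s2))
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * trigamma_inverse(evar)
    if not np.isfinite(d0):
        return np.inf, float(np.mean(s2))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated(
    matrix: ProteinMatrix,
    design: StudyDesign,
    bait_group: str,
    control_group: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> tuple[DiffResult, EBayesFit]:
    """Moderated two-group test of bait vs control on a log2 matrix.

    Parameters
    ----------
    matrix:
        Imputed, log2-transformed protein matrix.
    bait_group, control_group:
        Group labels from the design; the contrast is always bait - control.
    fc_threshold, alpha:
        Call thresholds passed to :func:`classify_calls`.
    prior_df:
        Override for the prior degrees of freedom d0. ``None`` (default)
        estimates d0 from the data; ``0`` disables moderation (classical
        pooled t); ``inf`` forces complete shrinkage to the prior variance.
    """
    if not matrix.log2 or not matrix.imputed:
        raise PipelineOrderError("fit_moderated requires an imputed, log2 matrix")
    bait_samples = design.samples_in(bait_group)
    ctrl_samples = design.samples_in(control_group)
    if len(bait_samples) < 2 or len(ctrl_samples) < 2:
        raise DesignError("both groups need >= 2 samples for a variance estimate")
    missing_cols = [s for s in bait_samples + ctrl_samples if s not in matrix.values.columns]
    if missing_cols:
        raise DesignError(f"matrix lacks sample column(s) {missing_cols}")

    yb = matrix.values[bait_samples].to_numpy()
    yc = matrix.values[ctrl_samples].to_numpy()
    n1, n2 = yb.shape[1], yc.shape[1]
    df_resid = float(n1 + n2 - 2)

    mb = yb.mean(axis=1)
    mc = yc.mean(axis=1)
    log2_fc = mb - mc
    ss = ((yb - mb[:, None]) ** 2).sum(axis=1) + ((yc - mc[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if np.all(s2 <= 0):
        raise DegenerateFitError("every protein has zero residual variance")
    s2 = np.maximum(s2, VAR_FLOOR)

    if prior_df is None:
        d0, s0_sq = _fit_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.mean(s2))
    elif np.isinf(prior_df):
        d0, s0_sq = np.inf, float(np.mean(s2))
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_prior(s2, df_resid)

    if np.isinf(d0):
        s_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    t_mod = log2_fc / se
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = bh_adjust(p_raw)

    index = matrix.values.index
    table = pd.DataFrame({
        "log2_fc": log2_fc,
        "t_mod": t_mod,
        "df_total": df_total,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "pi_value": pi_value(p_raw, log2_fc),
        "call": "not_significant",
    }, index=index)
    result = DiffResult(table, bait_group=bait_group, control_group=control_group)
    result = classify_calls(result, fc_threshold=fc_threshold, alpha=alpha)
    fit = EBayesFit(
        d0=d0, s0_sq=s0_sq, d_g=df_resid,
        s_g_sq=pd.Series(s2, index=index, name="s_g_sq"),
        s_post_sq=pd.Series(s_post, index=index, name="s_post_sq"),
    )
    return result, fit


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_calls(result: DiffResult, fc_threshold: float = 2.0, alpha: float = 0.05) -> DiffResult:
    """Threshold calls: enriched if log2FC > log2(fc_threshold) and
    adjusted p < alpha; de-enriched for the mirrored fold change; otherwise
    not significant."""
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    lfc = np.log2(fc_threshold)
    tab = result.table.copy()
    sig = tab["p_adj"] < alpha
    call = np.where(
        sig & (tab["log2_fc"] > lfc), "enriched",
        np.where(sig & (tab["log2_fc"] < -lfc), "de_enriched", "not_significant"),
    )
    tab["call"] = call
    return DiffResult(tab, bait_group=result.bait_group, control_group=result.control_group)


def pi_value(p_raw, log2_fc):
    """Signed significance score: -log10(p) * sign(log2FC).

    p = 0 is clamped to the smallest positive float with a warning; a zero
    fold change gives a zero score regardless of p.
    """
    p = np.asarray(p_raw, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    fc = np.atleast_1d(np.asarray(log2_fc, dtype=float))
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p-value of 0 clamped to smallest positive float", RuntimeWarning)
        p = np.maximum(p, np.finfo(float).tiny)
    out = -np.log10(p) * np.sign(fc)
    return float(out[0]) if scalar else out
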