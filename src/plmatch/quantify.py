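"""Precursor filtering and normalization, protein aggregation, imputation
and log transform.

Stage order is filter -> normalize -> aggregate -> impute -> log2, enforced
through the provenance flags on :class:`~plmatch.types.ProteinMatrix`.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import PipelineOrderError
from .types import PrecursorTable, ProteinMatrix, strip_charge

TOTAL_INTENSITY_SCALE = 1e7  # every sample's precursor total is scaled to this


def filter_min_unique_peptides(table: PrecursorTable, k: int = 2) -> PrecursorTable:
    """Drop proteins identified by fewer than ``k`` unique peptides.

    A unique peptide is a distinct (modified) sequence; charge states of the
    same sequence count once. ``k=1`` is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1 or not len(table):
        return table
    rec = table.records
    npep = rec.groupby("protein_group")["peptide_seq"].nunique()
    keep = set(npep.index[npep >= k])
    return table.with_records(rec[rec["protein_group"].isin(keep)])


def normalize_total_intensity(table: PrecursorTable, scale: float = TOTAL_INTENSITY_SCALE) -> PrecursorTable:
    """Scale each sample so its total precursor intensity equals ``scale``
    (default 1e7). Idempotent."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not len(table):
        return table.with_records(table.records, normalized=True)
    totals = table.sample_totals()
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total intensity")
    rec = table.records.copy()
    rec["intensity"] = rec["intensity"] * (scale / totals.loc[rec["sample_id"]].to_numpy())
    return table.with_records(rec, normalized=True)


def aggregate(table: PrecursorTable, method: str = "sum") -> ProteinMatrix:
    """Aggregate precursor intensities to a protein x sample matrix.

    ``sum``
        Sum of present precursor intensities; a cell is missing iff no
        precursor was detected there.
    ``top1``
        For each protein the single precursor with the largest total
        intensity across samples is chosen once (ties broken by
        lexicographic precursor id); its row becomes the protein's row.
    ``maxlfq``
        Pairwise sample log-ratios estimated as the median of per-precursor
        log-ratios over shared precursors, then per-sample log-abundances
        solved by least squares over the ratio graph (independently per
        connected component) and rescaled so each protein's total matches
        the sum aggregate.
    """
    if method not in {"sum", "top1", "maxlfq"}:
        raise ValueError(f"unknown aggregation method {method!r}")
    if not len(table):
        raise ValueError("cannot aggregate an empty precursor table")
    rec = table.records
    samples = table.samples

    sums = rec.pivot_table(
        index="protein_group", columns="sample_id", values="intensity", aggfunc="sum"
    ).reindex(columns=samples)
    sums.index.name = "protein"

    if method == "sum":
        values = sums
    elif method == "top1":
        totals = rec.groupby(["protein_group", "precursor_id"])["intensity"].sum().reset_index()
        totals = totals.sort_values(
            ["protein_group", "intensity", "precursor_id"],
            ascending=[True, False, True],
        )
        best = totals.groupby("protein_group", sort=True).head(1)
        # each precursor maps to exactly one protein, so an id set suffices
        sel = rec[rec["precursor_id"].isin(set(best["precursor_id"]))]
        values = sel.pivot_table(
            index="protein_group", columns="sample_id", values="intensity", aggfunc="sum"
        ).reindex(index=sums.index, columns=samples)
        values.index.name = "protein"
    else:
        values = _aggregate_maxlfq(rec, sums, samples)

    values = values.rename_axis(index="protein", columns=None)
    return ProteinMatrix(values, aggregation_method=method, normalized=table.normalized)


def _aggregate_maxlfq(rec: pd.DataFrame, sums: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(np.nan, index=sums.index, columns=samples)
    sample_pos = {s: i for i, s in enumerate(samples)}
    for protein, sub in rec.groupby("protein_group", sort=True):
        wide = sub.pivot_table(index="precursor_id", columns="sample_id", values="intensity")
        present_samples = list(wide.columns)
        m = len(present_samples)
        if m == 1:
            out.loc[protein, present_samples[0]] = sums.loc[protein, present_samples[0]]
            continue
        logw = np.log(wide.to_numpy())
        # median pairwise log-ratios over shared precursors
        rows, cols, ratios = [], [], []
        for a in range(m):
            for b in range(a + 1, m):
                shared = ~np.isnan(logw[:, a]) & ~np.isnan(logw[:, b])
                if shared.any():
                    rows.append(a)
                    cols.append(b)
                    ratios.append(np.median(logw[shared, b] - logw[shared, a]))
        if rows:
            adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
            n_comp, labels = connected_components(adj, directed=False)
        else:
            n_comp, labels = m, np.arange(m)
        logx = np.zeros(m)
        for comp in range(n_comp):
            members = np.nonzero(labels == comp)[0]
            if len(members) == 1:
                s = present_samples[members[0]]
                out.loc[protein, s] = sums.loc[protein, s]
                continue
            local = {g: j for j, g in enumerate(members)}
            A_rows, A_vals = [], []
            b_vec = []
            for a, b, r in zip(rows, cols, ratios):
                if labels[a] == comp:
                    A_rows.append((local[a], local[b]))
                    b_vec.append(r)
            k = len(members)
            A = np.zeros((len(b_vec) + 1, k))
            rhs = np.zeros(len(b_vec) + 1)
            for idx, ((ja, jb), r) in enumerate(zip(A_rows, b_vec)):
                A[idx, ja] = -1.0
                A[idx, jb] = 1.0
                rhs[idx] = r
            A[-1, :] = 1.0  # gauge: mean-zero within component
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            vals = np.exp(sol)
            comp_samples = [present_samples[j] for j in members]
            total = sums.loc[protein, comp_samples].sum()
            vals *= total / vals.sum()
            out.loc[protein, comp_samples] = vals
    return out


def impute_quantile(matrix: ProteinMatrix, q: float = 0.01, scope: str = "sample") -> ProteinMatrix:
    """Replace missing cells with a low quantile of the observed values.

    With ``scope="sample"`` (default) each sample's missing cells get that
    sample's ``q``-quantile of present values; ``scope="global"`` uses one
    quantile over all present cells. The quantile uses linear interpolation
    between order statistics (position h = (n-1)q + 1).
    """
    if matrix.log2:
        raise PipelineOrderError("impute before log2 transform, not after")
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    if scope not in {"sample", "global"}:
        raise ValueError(f"unknown scope {scope!r}")
    vals = matrix.values.copy()
    arr = vals.to_numpy()
    if not np.isnan(arr).any():
        return matrix.evolve(vals, imputed=True)
    if scope == "global":
        present = arr[~np.isnan(arr)]
        if present.size == 0:
            raise ValueError("matrix has no present values to impute from")
        fill = float(np.quantile(present, q))
        vals = vals.fillna(fill)
    else:
        for col in vals.columns:
            col_vals = vals[col]
            present = col_vals.dropna()
            if present.empty:
                raise ValueError(f"sample {col!r} is entirely missing; cannot impute")
            vals[col] = col_vals.fillna(float(np.quantile(present.to_numpy(), q)))
    return matrix.evolve(vals, imputed=True)


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Elementwise log2. Requires a fully imputed, strictly positive matrix."""
    if matrix.log2:
        return matrix
    if not matrix.imputed:
        raise PipelineOrderError("log2 transform requires an imputed matrix")
    arr = matrix.values.to_numpy()
    if (arr <= 0).any():
        raise ValueError("matrix contains non-positive values; impute first")
    return matrix.evolve(np.log2(matrix.values), log2=True)
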