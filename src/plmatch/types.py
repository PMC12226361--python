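"""Domain types shared by every stage of the pipeline.

The types are thin, validating wrappers around pandas objects. Each wrapper
enforces its structural invariants at construction time so that downstream
stages never have to re-check them, and carries the provenance flags
(normalized / imputed / log2 / aggregation method) that the pipeline uses to
enforce stage order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, IntegrityError

PRECURSOR_COLUMNS = ["sample_id", "protein_group", "peptide_seq", "precursor_id", "intensity"]
DESIGN_COLUMNS = ["sample_id", "group", "role", "replicate", "turboid_expression"]
ROLES = {"bait", "control", "no_turbo"}

DIFF_COLUMNS = ["log2_fc", "t_mod", "df_total", "p_raw", "p_adj", "pi_value", "call"]
CALLS = {"enriched", "de_enriched", "not_significant"}

QUARTILE_LABELS = ["Q1_top", "Q2", "Q3", "Q4_bottom"]


def strip_charge(precursor_id: str) -> str:
    """Derive a peptide sequence from a precursor id by stripping the
    trailing charge integer (``"PEPTIDEK2"`` -> ``"PEPTIDEK"``)."""
    return precursor_id.rstrip("0123456789")


@dataclass(frozen=True)
class PrecursorTable:
    """Long-format table of detected precursor intensities.

    Only detected cells are stored: a missing (sample, precursor) pair means
    the precursor was not quantified in that sample. Intensities are
    arbitrary MS intensity units, always >= 0.
    """

    records: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        rec = self.records
        missing = [c for c in PRECURSOR_COLUMNS if c not in rec.columns]
        if missing:
            raise IntegrityError(f"precursor table lacks columns: {missing}")
        rec = rec[PRECURSOR_COLUMNS].reset_index(drop=True)
        rec["intensity"] = rec["intensity"].astype(float)
        if len(rec):
            inten = rec["intensity"].to_numpy(dtype=float)
            if not np.all(np.isfinite(inten)) or (inten < 0).any():
                raise IntegrityError("precursor intensities must be finite and >= 0")
            dup = rec.duplicated(["sample_id", "precursor_id"])
            if dup.any():
                pair = rec.loc[dup.idxmax(), ["sample_id", "precursor_id"]].tolist()
                raise IntegrityError(f"duplicate (sample_id, precursor_id) pair: {pair}")
            ngroups = rec.groupby("precursor_id", sort=False)["protein_group"].nunique()
            bad = ngroups[ngroups > 1]
            if len(bad):
                raise IntegrityError(
                    f"precursor {bad.index[0]!r} maps to {bad.iloc[0]} protein groups"
                )
        object.__setattr__(self, "records", rec)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    @property
    def proteins(self) -> list[str]:
        return sorted(self.records["protein_group"].unique())

    def sample_totals(self) -> pd.Series:
        return self.records.groupby("sample_id")["intensity"].sum()

    def with_records(self, records: pd.DataFrame, **flags) -> "PrecursorTable":
        return PrecursorTable(records, **{"normalized": self.normalized, **flags})


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample metadata: group, role, replicate, relative TurboID expression.

    ``turboid_expression`` is the relative TurboID abundance of the sample's
    cell population (from whole-cell proteomics in a real experiment); zero is
    allowed only for ``no_turbo`` samples.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in tab.columns]
        if missing:
            raise DesignError(f"design lacks columns: {missing}")
        tab = tab[DESIGN_COLUMNS].reset_index(drop=True)
        if tab["sample_id"].duplicated().any():
            dup = tab.loc[tab["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise IntegrityError(f"duplicate sample_id {dup!r} in design")
        bad_role = set(tab["role"]) - ROLES
        if bad_role:
            raise DesignError(f"unknown role(s) {sorted(bad_role)}; expected one of {sorted(ROLES)}")
        expr = tab["turboid_expression"].to_numpy(dtype=float)
        if not np.all(np.isfinite(expr)) or (expr < 0).any():
            raise DesignError("turboid_expression must be finite and >= 0")
        zero_expr = (expr == 0) & (tab["role"] != "no_turbo").to_numpy()
        if zero_expr.any():
            sid = tab.loc[zero_expr, "sample_id"].iloc[0]
            raise DesignError(
                f"sample {sid!r} has turboid_expression 0 but role != 'no_turbo'"
            )
        if (tab["replicate"].to_numpy(dtype=float) < 1).any():
            raise DesignError("replicate must be a positive integer")
        object.__setattr__(self, "table", tab)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def samples_in(self, group: str) -> list[str]:
        sel = self.table.loc[self.table["group"] == group, "sample_id"]
        if sel.empty:
            raise DesignError(f"group {group!r} not in design")
        return sel.tolist()

    def role_of(self, group: str) -> str:
        roles = self.table.loc[self.table["group"] == group, "role"].unique()
        if len(roles) == 0:
            raise DesignError(f"group {group!r} not in design")
        return roles[0]

    def group_expression(self, group: str) -> float:
        """Group-level TurboID expression: mean over the group's samples."""
        sel = self.table.loc[self.table["group"] == group, "turboid_expression"]
        if sel.empty:
            raise DesignError(f"group {group!r} not in design")
        return float(sel.mean())


@dataclass(frozen=True)
class ProteinMatrix:
    """Protein x sample intensity matrix with provenance flags.

    ``values`` is indexed by protein id with one column per sample; NaN marks
    a missing cell. The flags record which pipeline stages have been applied,
    and the stage functions refuse to run out of order.
    """

    values: pd.DataFrame
    aggregation_method: str = "sum"
    normalized: bool = False
    log2: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.aggregation_method not in {"sum", "top1", "maxlfq"}:
            raise ValueError(f"unknown aggregation_method {self.aggregation_method!r}")
        vals = self.values.astype(float)
        arr = vals.to_numpy()
        if self.imputed and np.isnan(arr).any():
            raise IntegrityError("imputed matrix must have no missing cells")
        if not self.log2:
            present = arr[~np.isnan(arr)]
            if (present < 0).any():
                raise IntegrityError("non-log2 matrix must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def evolve(self, values: pd.DataFrame, **flags) -> "ProteinMatrix":
        state = dict(
            aggregation_method=self.aggregation_method,
            normalized=self.normalized,
            log2=self.log2,
            imputed=self.imputed,
        )
        state.update(flags)
        return ProteinMatrix(values, **state)


@dataclass(frozen=True)
class EBayesFit:
    """Empirical-Bayes variance model: prior (d0, s0^2) and per-protein
    residual and posterior variances.

    ``s_post_sq`` is the convex combination
    ``(d0*s0_sq + d_g*s_g_sq) / (d0 + d_g)``; with d0 = inf it equals
    ``s0_sq`` for every protein.
    """

    d0: float
    s0_sq: float
    d_g: float
    s_g_sq: pd.Series
    s_post_sq: pd.Series


@dataclass(frozen=True)
class DiffResult:
    """Per-protein two-group differential result.

    Columns: log2_fc (bait minus control, log2 scale), t_mod, df_total,
    p_raw, p_adj (Benjamini-Hochberg), pi_value
    (-log10(p_raw) * sign(log2_fc)) and the threshold call.
    """

    table: pd.DataFrame
    bait_group: str = ""
    control_group: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in DIFF_COLUMNS if c not in self.table.columns]
        if missing:
            raise IntegrityError(f"diff result lacks columns: {missing}")
        tab = self.table[DIFF_COLUMNS].copy()
        for col in DIFF_COLUMNS[:-1]:
            tab[col] = tab[col].astype(float)
        bad_calls = set(tab["call"].dropna()) - CALLS
        if bad_calls:
            raise IntegrityError(f"unknown call label(s): {sorted(bad_calls)}")
        object.__setattr__(self, "table", tab)

    @property
    def proteins(self) -> pd.Index:
        return self.table.index

    def enriched(self) -> pd.Index:
        return self.table.index[self.table["call"] == "enriched"]


@dataclass(frozen=True)
class ConsensusResult:
    """Cross-control occurrence-frequency consensus.

    ``occurrence_frequency`` counts, per protein, the comparisons in which it
    was called enriched; proteins at or above the configured threshold are
    flagged high confidence.
    """

    table: pd.DataFrame  # columns: occurrence_frequency, n_comparisons, high_confidence
    threshold: int

    def __post_init__(self) -> None:
        tab = self.table
        need = ["occurrence_frequency", "n_comparisons", "high_confidence"]
        missing = [c for c in need if c not in tab.columns]
        if missing:
            raise IntegrityError(f"consensus result lacks columns: {missing}")
        freq = tab["occurrence_frequency"].to_numpy()
        ncmp = tab["n_comparisons"].to_numpy()
        if (freq < 0).any() or (freq > ncmp).any():
            raise IntegrityError("occurrence_frequency must lie in [0, n_comparisons]")
        object.__setattr__(self, "table", tab[need].copy())

    def high_confidence_proteins(self) -> pd.Index:
        return self.table.index[self.table["high_confidence"]]


@dataclass(frozen=True)
class QuartileMap:
    """Abundance quartile assignment (Q1_top = most abundant 25%) plus a
    flag for the top 1% most abundant proteins."""

    table: pd.DataFrame  # columns: abundance_quartile, top1pct

    def __post_init__(self) -> None:
        bad = set(self.table["abundance_quartile"]) - set(QUARTILE_LABELS)
        if bad:
            raise IntegrityError(f"unknown quartile label(s): {sorted(bad)}")

    def proteins_in(self, quartile: str) -> pd.Index:
        return self.table.index[self.table["abundance_quartile"] == quartile]
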