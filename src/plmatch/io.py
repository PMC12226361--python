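"""Readers and writers for the tabular formats the pipeline touches.

Everything is plain TSV. Missing cells are serialized as ``NA``; floats are
written with enough digits (%.17g) that a write/read round trip reproduces
values to better than 1e-12 relative. ProteinMatrix provenance flags travel
in a single ``#`` comment line at the top of the file.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .types import (
    DESIGN_COLUMNS,
    DIFF_COLUMNS,
    PRECURSOR_COLUMNS,
    ConsensusResult,
    DiffResult,
    PrecursorTable,
    ProteinMatrix,
    StudyDesign,
    strip_charge,
)

NA = "NA"
FLOAT_FMT = "%.17g"

DEFAULT_REPORT_COLUMNS: Mapping[str, str] = {
    "sample_id": "Run",
    "protein_group": "Protein.Group",
    "peptide_seq": "Modified.Sequence",
    "precursor_id": "Precursor.Id",
    "intensity": "Precursor.Quantity",
}


def read_precursor_report(path, column_map: Mapping[str, str] | None = None) -> PrecursorTable:
    """Read a DIA-NN-style long-format precursor report.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    column_map:
        Maps internal field names (``sample_id``, ``protein_group``,
        ``peptide_seq``, ``precursor_id``, ``intensity``) to the file's
        column names. Unspecified fields use the DIA-NN defaults (``Run``,
        ``Protein.Group``, ``Modified.Sequence``, ``Precursor.Id``,
        ``Precursor.Quantity``). A missing peptide column is tolerated: the
        peptide sequence is then derived from the precursor id by stripping
        the trailing charge integer.

    Rows with zero, missing or non-finite intensity are treated as
    not-detected and dropped.
    """
    colmap = dict(DEFAULT_REPORT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "protein_group", "precursor_id", "intensity"]
    for key in required:
        if colmap[key] not in raw.columns:
            raise FormatError(f"report is missing column {colmap[key]!r} (for {key})")
    out = pd.DataFrame(
        {key: raw[colmap[key]] for key in required}
    )
    pep_col = colmap["peptide_seq"]
    if pep_col in raw.columns:
        out["peptide_seq"] = raw[pep_col]
    else:
        out["peptide_seq"] = out["precursor_id"].map(strip_charge)
    out["intensity"] = pd.to_numeric(out["intensity"], errors="coerce")
    present = out["intensity"].notna() & (out["intensity"] > 0)
    out = out.loc[present, PRECURSOR_COLUMNS]
    return PrecursorTable(out)


def read_design(path) -> StudyDesign:
    """Read a study-design TSV (sample_id, group, role, replicate,
    turboid_expression)."""
    raw = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"design file is missing column(s) {missing}")
    return StudyDesign(raw)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_precursor_report(table: PrecursorTable, path) -> None:
    """Write a PrecursorTable back out in the same long TSV layout the
    reader accepts (default DIA-NN column names)."""
    out = table.records.rename(columns=dict(
        sample_id="Run",
        protein_group="Protein.Group",
        peptide_seq="Modified.Sequence",
        precursor_id="Precursor.Id",
        intensity="Precursor.Quantity",
    ))
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_abundance_table(path) -> pd.Series:
    """Read a whole-cell abundance TSV (columns: protein, abundance) into a
    Series indexed by protein id."""
    raw = pd.read_csv(path, sep="\t")
    for col in ("protein", "abundance"):
        if col not in raw.columns:
            raise FormatError(f"abundance table is missing column {col!r}")
    if raw["protein"].duplicated().any():
        dup = raw.loc[raw["protein"].duplicated(), "protein"].iloc[0]
        raise IntegrityError(f"duplicate protein {dup!r} in abundance table")
    return raw.set_index("protein")["abundance"].astype(float)


def write_abundance_table(abundance: pd.Series, path) -> None:
    frame = abundance.rename("abundance").rename_axis("protein").reset_index()
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_id_list(path) -> list[str]:
    """Read a plain-text id list, one id per line; blank lines ignored.
    Identifiers are case-sensitive exact strings."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


_FLAG_RE = re.compile(r"(\w+)=(\S+)")


def write_matrix(matrix: ProteinMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# aggregation_method=%s normalized=%s log2=%s imputed=%s\n"
            % (matrix.aggregation_method, matrix.normalized, matrix.log2, matrix.imputed)
        )
        matrix.values.rename_axis("protein").to_csv(
            fh, sep="\t", na_rep=NA, float_format=FLOAT_FMT
        )


def read_matrix(path) -> ProteinMatrix:
    flags = dict(aggregation_method="sum", normalized=False, log2=False, imputed=False)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for key, val in _FLAG_RE.findall(first):
                if key == "aggregation_method":
                    flags[key] = val
                elif key in flags:
                    flags[key] = val == "True"
        else:
            fh.seek(0)
        frame = pd.read_csv(fh, sep="\t", index_col="protein", na_values=[NA])
    return ProteinMatrix(frame, **flags)


def write_diff_result(result: DiffResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("# bait=%s control=%s\n" % (result.bait_group or NA, result.control_group or NA))
        result.table.rename_axis("protein").to_csv(
            fh, sep="\t", na_rep=NA, float_format=FLOAT_FMT
        )


def read_diff_result(path) -> DiffResult:
    bait = control = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(_FLAG_RE.findall(first))
            bait = meta.get("bait", "")
            control = meta.get("control", "")
            bait = "" if bait == NA else bait
            control = "" if control == NA else control
        else:
            fh.seek(0)
        frame = pd.read_csv(fh, sep="\t", index_col="protein", na_values=[NA])
    frame["call"] = frame["call"].astype(str)
    return DiffResult(frame, bait_group=bait, control_group=control)


def write_consensus(result: ConsensusResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("# threshold=%d\n" % result.threshold)
        result.table.rename_axis("protein").to_csv(fh, sep="\t", na_rep=NA)


def read_consensus(path) -> ConsensusResult:
    threshold = 1
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            threshold = int(dict(_FLAG_RE.findall(first)).get("threshold", 1))
        else:
            fh.seek(0)
        frame = pd.read_csv(fh, sep="\t", index_col="protein")
    frame["high_confidence"] = frame["high_confidence"].astype(bool)
    return ConsensusResult(frame, threshold=threshold)


def write_results(obj, path) -> None:
    """Polymorphic writer: dispatches on the result type."""
    if isinstance(obj, ProteinMatrix):
        write_matrix(obj, path)
    elif isinstance(obj, DiffResult):
        write_diff_result(obj, path)
    elif isinstance(obj, ConsensusResult):
        write_consensus(obj, path)
    elif isinstance(obj, PrecursorTable):
        write_precursor_report(obj, path)
    elif isinstance(obj, StudyDesign):
        write_design(obj, path)
    else:
        raise TypeError(f"no writer for {type(obj).__name__}")
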