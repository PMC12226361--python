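"""End-to-end pipeline: filter -> normalize -> aggregate -> impute -> log2
-> per-control differential analysis -> consensus -> matching report.

The pipeline can run from files (precursor report + design) or from the
built-in simulator, and can run the normalized and non-normalized branches
side by side, since the choice of branch is itself one of the comparisons
the expression-matching workflow cares about.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import benchmark, diffexp, io, quantify, simulate
from .errors import ConfigurationError
from .types import DiffResult, PrecursorTable, ProteinMatrix, StudyDesign

log = logging.getLogger("plmatch")

DEFAULTS = dict(
    min_peptides=2,
    impute_q=0.01,
    fc_threshold=2.0,
    alpha=0.05,
    consensus_threshold=3,
    scale=quantify.TOTAL_INTENSITY_SCALE,
    aggregation="sum",
)


def quantify_pipeline(
    table: PrecursorTable,
    min_peptides: int = 2,
    normalize: bool = True,
    aggregation: str = "sum",
    impute_q: float = 0.01,
    scale: float = quantify.TOTAL_INTENSITY_SCALE,
    log2: bool = True,
) -> ProteinMatrix:
    """Precursor table -> analysis-ready protein matrix."""
    table = quantify.filter_min_unique_peptides(table, min_peptides)
    if normalize:
        table = quantify.normalize_total_intensity(table, scale)
    matrix = quantify.aggregate(table, aggregation)
    matrix = quantify.impute_quantile(matrix, impute_q)
    if log2:
        matrix = quantify.log2_transform(matrix)
    return matrix


def differential_per_control(
    matrix: ProteinMatrix,
    design: StudyDesign,
    bait_group: str,
    control_groups: list[str] | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> dict[str, DiffResult]:
    """Run the bait-vs-control moderated test for every candidate control
    (default: every non-bait group in the design)."""
    if control_groups is None:
        control_groups = [g for g in design.groups if g != bait_group]
    out = {}
    for control in control_groups:
        result, _ = diffexp.fit_moderated(
            matrix, design, bait_group, control,
            fc_threshold=fc_threshold, alpha=alpha,
        )
        out[control] = result
    return out


@dataclass
class PipelineOutput:
    design: StudyDesign
    matrices: dict[str, ProteinMatrix]            # branch -> matrix
    diff_results: dict[str, dict[str, DiffResult]]  # branch -> control -> result
    consensus: dict[str, Any]
    reports: dict[str, benchmark.MatchingReport]
    truth: simulate.GroundTruth | None = None


def run_pipeline(config: Mapping[str, Any], out_dir) -> PipelineOutput:
    """Execute a full run from a configuration mapping (the YAML schema of
    ``plmatch run``) and write every artifact under ``out_dir``.

    The configuration must provide either a ``simulation`` block (SimConfig
    fields) or an ``inputs`` block with ``report`` and ``design`` paths.
    Outputs already present in ``out_dir`` cause an error rather than a
    silent overwrite.
    """
    out_dir = Path(out_dir)
    params = {**DEFAULTS, **{k: v for k, v in config.items()
                             if k not in ("simulation", "inputs")}}
    branches = config.get("branches", ["normalized"])
    bad = set(branches) - {"normalized", "non_normalized"}
    if bad:
        raise ConfigurationError(f"unknown branch(es) {sorted(bad)}")

    has_sim = "simulation" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise ConfigurationError(
            "config must contain exactly one of 'simulation' or 'inputs'"
        )
    if has_inputs:
        inputs = config["inputs"]
        for key in ("report", "design"):
            if key not in inputs:
                raise ConfigurationError(f"inputs block is missing {key!r}")
        for key in ("report", "design"):
            if not Path(inputs[key]).exists():
                raise ConfigurationError(f"input file not found: {inputs[key]}")

    bait_group = config.get("bait")
    out_dir.mkdir(parents=True, exist_ok=True)
    existing = [p.name for p in out_dir.iterdir() if p.suffix == ".tsv"]
    if existing:
        raise ConfigurationError(
            f"output directory already contains results ({existing[:3]}...); refusing to overwrite"
        )

    logfile = out_dir / "run.log"
    handler = logging.FileHandler(logfile)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for key in sorted(params):
            log.info("param %s=%r", key, params[key])

        truth = None
        if has_sim:
            sim_cfg = _sim_config(config["simulation"])
            log.info("simulating experiment with seed=%d", sim_cfg.seed)
            table, design, wholecell, truth = simulate.simulate_experiment(sim_cfg)
            io.write_precursor_report(table, out_dir / "report.tsv")
            io.write_design(design, out_dir / "design.tsv")
            io.write_abundance_table(wholecell, out_dir / "wholecell.tsv")
            _write_truth(truth, out_dir / "truth.tsv")
        else:
            table = io.read_precursor_report(inputs["report"])
            design = io.read_design(inputs["design"])

        if bait_group is None:
            baits = [g for g in design.groups if design.role_of(g) == "bait"]
            if len(baits) != 1:
                raise ConfigurationError(
                    "config must name a 'bait' group when the design does not "
                    "contain exactly one bait-role group"
                )
            bait_group = baits[0]
        log.info("bait group: %s", bait_group)

        matrices, diffs, consensus, reports = {}, {}, {}, {}
        for branch in branches:
            normalize = branch == "normalized"
            matrix = quantify_pipeline(
                table,
                min_peptides=params["min_peptides"],
                normalize=normalize,
                aggregation=params["aggregation"],
                impute_q=params["impute_q"],
                scale=params["scale"],
            )
            matrices[branch] = matrix
            io.write_matrix(matrix, out_dir / f"matrix_{branch}.tsv")
            results = differential_per_control(
                matrix, design, bait_group,
                fc_threshold=params["fc_threshold"], alpha=params["alpha"],
            )
            diffs[branch] = results
            for control, result in results.items():
                io.write_diff_result(result, out_dir / f"diff_{branch}_{control}.tsv")
                log.info("branch=%s control=%s enriched=%d", branch, control,
                         len(result.enriched()))
            if len(results) >= 2:
                thr = min(params["consensus_threshold"], len(results))
                cons = benchmark.occurrence_frequency(list(results.values()), thr)
                consensus[branch] = cons
                io.write_consensus(cons, out_dir / f"consensus_{branch}.tsv")
            report = benchmark.matching_report(results, design, bait_group, truth=truth)
            reports[branch] = report
            report.controls.to_csv(out_dir / f"matching_{branch}.tsv", sep="\t")
            log.info("branch=%s recommended control: %s", branch,
                     report.recommended_control)
        return PipelineOutput(design=design, matrices=matrices, diff_results=diffs,
                              consensus=consensus, reports=reports, truth=truth)
    finally:
        log.removeHandler(handler)
        handler.close()


def _sim_config(block: Mapping[str, Any]) -> simulate.SimConfig:
    block = dict(block)
    groups = block.pop("groups", None)
    kwargs: dict[str, Any] = {}
    if groups is not None:
        kwargs["groups"] = tuple(
            simulate.GroupSpec(g["label"], g["role"], float(g["turboid_expression"]))
            for g in groups
        )
    valid = set(simulate.SimConfig.__dataclass_fields__)
    unknown = set(block) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulation parameter(s) {sorted(unknown)}")
    kwargs.update(block)
    return simulate.SimConfig(**kwargs)


def _write_truth(truth: simulate.GroundTruth, path) -> None:
    frame = truth.proteins.join(truth.proximity.add_prefix("proximity_"))
    frame.to_csv(path, sep="\t", float_format=io.FLOAT_FMT)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a YAML mapping")
    return cfg
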