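"""Seeded generative model of a TurboID proximity-labeling experiment.

The simulator emits the same artifacts a real experiment would: a
long-format precursor report, a study design, a whole-cell abundance table,
and (unlike a real experiment) the ground truth behind them. Its generative
rules encode the empirical structure of streptavidin-enrichment proteomics:

* bead background biased toward high-abundance, high-pI proteins;
* TurboID labeling proportional to TurboID expression per protein, so total
  captured signal and identified-protein counts rise with expression;
* endogenously biotinylated, expression-independent background proteins
  (ACACA-like carboxylases), sampled from the most abundant decile;
* a detection limit that makes identification counts depend on labeling
  intensity, and that compresses the relative intensity gain of
  high-abundance proteins (whose bead background forms a floor) relative to
  low-abundance ones as expression rises.

The expected captured signal for protein ``i`` in a sample of group ``g``
with TurboID expression ``E_g`` is::

    S_ig = B_i + E_g * A_i * P_ig * kappa + D * [i endogenously biotinylated]
    B_i  = beta0 * A_i**gamma * exp(delta * (pI_i - pI_mean))

where ``A_i`` is whole-cell abundance, ``P_ig`` the proximity factor (rho
for true interactors in bait groups, 1 otherwise) and ``kappa`` a global
labeling scale fixed at 1 (only relative expression matters). Each protein
has a fixed set of peptides/precursors with Dirichlet response fractions;
observed per-cell intensity is ``S_ig * fraction * exp(eps)`` with
independent log-normal noise, censored at the detection limit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import PlmatchError
from .types import PrecursorTable, StudyDesign


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: label, role (bait/control/no_turbo) and
    relative TurboID expression E."""

    label: str
    role: str
    turboid_expression: float


def _default_groups() -> tuple[GroupSpec, ...]:
    # Bait plus a control titration bracketing the bait's expression.
    return (
        GroupSpec("bait", "bait", 1.0),
        GroupSpec("ctrl_low", "control", 0.25),
        GroupSpec("ctrl_matched", "control", 1.0),
        GroupSpec("ctrl_high", "control", 4.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    Defaults are the package's reference conditions: 2000 proteins, three
    biological replicates per group, 10% true interactors boosted 8-fold in
    bait samples, 2% endogenously biotinylated background proteins, and a
    detection limit that produces realistic dropout.
    """

    n_proteins: int = 2000
    n_replicates: int = 3
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    frac_interactors: float = 0.1
    interactor_boost: float = 8.0       # rho: proximity factor for interactors in bait groups
    frac_endogenous_biotin: float = 0.01
    endog_level: float = 5e7            # D: expression-independent biotin signal
    bead_scale: float = 2e-4            # beta0
    bead_abundance_exp: float = 1.3     # gamma: superlinear abundance capture on beads
    bead_pi_coef: float = 0.1           # delta: isoelectric-point bias
    abundance_log_mean: float = 11.5129 # mu_A = ln(1e5)
    abundance_log_sd: float = 2.3
    pi_mean: float = 7.0
    pi_sd: float = 1.0
    peptides_per_protein: float = 3.0   # mean extra peptides; counts are 1 + Poisson(this)
    second_charge_prob: float = 0.2     # chance a peptide is seen at a second charge state
    noise_log_sd: float = 0.25          # sigma_eps, natural-log scale
    lod: float = 1000.0
    dropout_softness: float = 0.25      # logistic width in ln-intensity; 0 = hard threshold
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_interactors", "frac_endogenous_biotin", "second_charge_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.interactor_boost < 1:
            raise ValueError("interactor_boost must be >= 1")
        for name in ("noise_log_sd", "abundance_log_sd", "pi_sd", "dropout_softness",
                     "lod", "bead_scale", "endog_level", "kappa"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for g in self.groups:
            if not np.isfinite(g.turboid_expression) or g.turboid_expression < 0:
                raise ValueError(f"group {g.label!r} has invalid expression")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be positive")


def expression_series_config(
    expressions: Sequence[float] = (0.25, 0.5, 1.0, 2.0),
    include_no_turbo: bool = False,
    **overrides,
) -> SimConfig:
    """Config for a control-only expression titration (the sorted
    TurboID-eGFP series): one control group per expression level, no bait."""
    groups = [
        GroupSpec(f"eGFP{i + 1}", "control", float(e)) for i, e in enumerate(expressions)
    ]
    if include_no_turbo:
        groups.insert(0, GroupSpec("parental", "no_turbo", 0.0))
    return SimConfig(groups=tuple(groups), frac_interactors=0.0, **overrides)


@dataclass(frozen=True)
class GroundTruth:
    """Per-protein truth: abundance, pI, interactor / endogenous-biotin
    flags, bead background, and the proximity factor in each group."""

    proteins: pd.DataFrame   # abundance, pI, is_interactor, is_endogenous_biotin, bead_background
    proximity: pd.DataFrame  # protein x group proximity factors

    @property
    def interactors(self) -> pd.Index:
        return self.proteins.index[self.proteins["is_interactor"]]


class SimulatedExperiment(NamedTuple):
    precursors: PrecursorTable
    design: StudyDesign
    wholecell: pd.Series
    truth: GroundTruth


def truth_labels(truth: GroundTruth) -> pd.Series:
    """Boolean positive/negative label per simulated protein: positives are
    the true interactors, every other protein is a negative."""
    return truth.proteins["is_interactor"].astype(bool)


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Run the generative model. Identical config (including seed) gives
    bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    prot_ids = np.array([f"PROT{i:05d}" for i in range(n)])

    abundance = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, n)
    pi = rng.normal(config.pi_mean, config.pi_sd, n)
    is_interactor = rng.random(n) < config.frac_interactors

    # Endogenously biotinylated proteins: carboxylases are abundant, so
    # sample from the top abundance decile (spilling over only if needed).
    n_endog = int(round(config.frac_endogenous_biotin * n))
    is_endog = np.zeros(n, dtype=bool)
    if n_endog > 0:
        order = np.argsort(-abundance, kind="stable")
        pool = order[: max(n_endog, n // 10)]
        chosen = rng.choice(pool, size=n_endog, replace=False)
        is_endog[chosen] = True

    bead = (
        config.bead_scale
        * abundance ** config.bead_abundance_exp
        * np.exp(config.bead_pi_coef * (pi - config.pi_mean))
    )

    # Peptide/precursor layout, fixed once per protein.
    n_pep = 1 + rng.poisson(config.peptides_per_protein, n)
    pep_protein, pep_seq, prec_ids, prec_pep_seq = [], [], [], []
    for i in range(n):
        for j in range(n_pep[i]):
            seq = f"PEP{i:05d}X{j}"
            charges = [2]
            if rng.random() < config.second_charge_prob:
                charges.append(3)
            for z in charges:
                pep_protein.append(i)
                prec_pep_seq.append(seq)
                prec_ids.append(f"{seq}{z}")
    prec_protein = np.asarray(pep_protein)
    n_prec = len(prec_protein)

    # Dirichlet(1) response fractions over each protein's precursors.
    # Precursors are emitted in protein order, so segment sums suffice.
    gamma_draws = rng.standard_gamma(1.0, n_prec)
    counts = np.bincount(prec_protein, minlength=n)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    seg_sums = np.add.reduceat(gamma_draws, offsets)
    fractions = gamma_draws / np.repeat(seg_sums, counts)

    # Sample grid.
    sample_ids, sample_group, sample_expr, rows = [], [], [], []
    for spec in config.groups:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{spec.label}_r{r}")
            sample_group.append(spec.label)
            sample_expr.append(spec.turboid_expression)
            rows.append(dict(
                sample_id=f"{spec.label}_r{r}", group=spec.label, role=spec.role,
                replicate=r, turboid_expression=spec.turboid_expression,
            ))
    design = StudyDesign(pd.DataFrame(rows))
    n_samples = len(sample_ids)

    # Expected captured signal per protein x group, then per sample.
    prox = np.ones((n, len(config.groups)))
    for gi, spec in enumerate(config.groups):
        if spec.role == "bait":
            prox[is_interactor, gi] = config.interactor_boost
    signal_by_group = (
        bead[:, None]
        + np.array([g.turboid_expression for g in config.groups])[None, :]
        * abundance[:, None] * prox * config.kappa
        + config.endog_level * is_endog[:, None].astype(float)
    )
    group_of_sample = np.repeat(np.arange(len(config.groups)), config.n_replicates)
    signal = signal_by_group[:, group_of_sample]          # n_proteins x n_samples

    expected = signal[prec_protein, :] * fractions[:, None]  # n_prec x n_samples
    if config.noise_log_sd > 0:
        noise = np.exp(rng.normal(0.0, config.noise_log_sd, expected.shape))
        intensity = expected * noise
    else:
        intensity = expected

    # Detection-limit censoring: hard threshold, or logistic dropout in
    # ln-intensity around the LOD when softness > 0.
    if config.lod > 0:
        with np.errstate(divide="ignore"):
            if config.dropout_softness > 0:
                z = (np.log(np.maximum(intensity, 1e-300)) - np.log(config.lod))
                p_detect = 1.0 / (1.0 + np.exp(-z / config.dropout_softness))
                detected = rng.random(intensity.shape) < p_detect
            else:
                detected = intensity >= config.lod
        detected &= intensity > 0
    else:
        detected = intensity > 0

    prec_idx, samp_idx = np.nonzero(detected)
    prec_ids_arr = np.asarray(prec_ids)
    prec_pep_arr = np.asarray(prec_pep_seq)
    samp_arr = np.asarray(sample_ids)
    records = pd.DataFrame({
        "sample_id": samp_arr[samp_idx],
        "protein_group": prot_ids[prec_protein[prec_idx]],
        "peptide_seq": prec_pep_arr[prec_idx],
        "precursor_id": prec_ids_arr[prec_idx],
        "intensity": intensity[prec_idx, samp_idx],
    })
    table = PrecursorTable(records)

    wholecell = pd.Series(abundance, index=prot_ids, name="abundance").rename_axis("protein")
    truth = GroundTruth(
        proteins=pd.DataFrame({
            "abundance": abundance,
            "pI": pi,
            "is_interactor": is_interactor,
            "is_endogenous_biotin": is_endog,
            "bead_background": bead,
        }, index=pd.Index(prot_ids, name="protein")),
        proximity=pd.DataFrame(
            prox, index=pd.Index(prot_ids, name="protein"),
            columns=[g.label for g in config.groups],
        ),
    )
    return SimulatedExperiment(table, design, wholecell, truth)
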