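import numpy as np
import pandas as pd
import pytest

from plmatch import (
    GroupSpec,
    PrecursorTable,
    ProteinMatrix,
    SimConfig,
    StudyDesign,
    simulate_experiment,
)


def make_precursor_table(rows):
    """rows: (sample, protein, peptide, precursor, intensity) tuples."""
    return PrecursorTable(pd.DataFrame(
        rows,
        columns=["sample_id", "protein_group", "peptide_seq", "precursor_id", "intensity"],
    ))


@pytest.fixture
def toy_table():
    # two proteins, two samples; P2 has a single peptide seen at two charges
    return make_precursor_table([
        ("s1", "P1", "AAK", "AAK2", 100.0),
        ("s1", "P1", "CCR", "CCR2", 200.0),
        ("s2", "P1", "AAK", "AAK2", 50.0),
        ("s2", "P1", "CCR", "CCR2", 400.0),
        ("s1", "P2", "DDE", "DDE2", 10.0),
        ("s1", "P2", "DDE", "DDE3", 30.0),
        ("s2", "P2", "DDE", "DDE2", 20.0),
    ])


@pytest.fixture
def two_group_design():
    rows = []
    for g, role in (("bait_g", "bait"), ("ctrl_g", "control")):
        for r in (1, 2, 3):
            rows.append(dict(sample_id=f"{g}_r{r}", group=g, role=role,
                             replicate=r, turboid_expression=1.0))
    return StudyDesign(pd.DataFrame(rows))


def random_matrix(rng, n_proteins=20, samples=("a", "b", "c", "d"), missing_frac=0.0,
                  **flags):
    vals = rng.lognormal(8, 1, size=(n_proteins, len(samples)))
    if missing_frac:
        mask = rng.random(vals.shape) < missing_frac
        # keep at least one present value per column
        mask[rng.integers(0, n_proteins, len(samples)), np.arange(len(samples))] = False
        vals[mask] = np.nan
    frame = pd.DataFrame(vals, index=[f"P{i:03d}" for i in range(n_proteins)],
                         columns=list(samples))
    frame.index.name = "protein"
    return ProteinMatrix(frame, **flags)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated experiment shared across tests."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """Matched-expression null: no interactor boost, two identical groups."""
    cfg = SimConfig(
        groups=(GroupSpec("g1", "bait", 1.0), GroupSpec("g2", "control", 1.0)),
        interactor_boost=1.0,
        seed=7,
    )
    return simulate_experiment(cfg)


def identified_proteins(table, sample_ids, min_peptides=2):
    """Proteins with >= min_peptides unique peptides detected in >= 1 of the
    given samples."""
    rec = table.records
    sub = rec[rec["sample_id"].isin(set(sample_ids))]
    npep = sub.groupby("protein_group")["peptide_seq"].nunique()
    return set(npep.index[npep >= min_peptides])
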