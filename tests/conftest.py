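import numpy as np
import pytest
from hypothesis import settings

from orgprobe import cascade, featurize, molecule_io as mio, synthlib

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_library():
    """Small synthetic library for unit tests (fast to generate)."""
    spec = synthlib.default_spec(n=240, seed=11)
    records, truth = synthlib.generate_library(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def small_tables(small_library):
    _, records, _ = small_library
    tables, rejects = mio.build_task_tables(records)
    assert not rejects
    return tables


@pytest.fixture(scope="session")
def default_library():
    """The full default study library: 1200 probes, 5% label noise, seed 7."""
    spec = synthlib.default_spec(n=1200, label_noise=0.05, seed=7)
    records, truth = synthlib.generate_library(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def design_sets(default_library):
    spec, _, _ = default_library
    return synthlib.generate_design_sets(spec)


@pytest.fixture(scope="session")
def trained_cascade(default_library):
    _, records, _ = default_library
    return cascade.train_cascade(records, seed=7)


@pytest.fixture(scope="session")
def maccs_bmvsp(default_library):
    """MACCS features aligned with the default library's B-MvsP table."""
    _, records, _ = default_library
    tables, _ = mio.build_task_tables(records)
    table = tables["B-MvsP"]
    return table, featurize.featurize_records(table.records, "MACCS")


def make_records(rows):
    """Helper: build standardized records from (smiles, role, organelle[, coloc])."""
    out = []
    for row in rows:
        smiles, role, organelle = row[:3]
        coloc = row[3] if len(row) > 3 else []
        rec = mio.MoleculeRecord(
            smiles=smiles, role_label=role, organelle_label=organelle,
            coloc_records=list(coloc),
        )
        out.append(mio.standardize_and_key(rec))
    return out
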