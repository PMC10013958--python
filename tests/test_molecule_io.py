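import numpy as np
import pytest
from hypothesis import given, strategies as st

from orgprobe import molecule_io as mio

from conftest import make_records


# ---------------------------------------------------------------------------
# parsing

def write_csv(tmp_path, rows, header="smiles,role,organelle,coloc_dye,coloc_r,set,id"):
    path = tmp_path / "mols.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


@pytest.mark.parametrize(
    "rows, n_records, n_rejects",
    [
        (["c1ccccc1,probe,mitochondria,,,,m1",
          "CCO,np_compound,mitochondria,,,,m2",
          "CC(=O)O,probe,lysosome,,,,m3"], 3, 0),
        (["c1ccccc1,probe,mitochondria,,,,m1",
          "not_a_smiles,probe,mitochondria,,,,bad",
          "CCO,np_compound,mitochondria,,,,m2"], 2, 1),
        ([], 0, 0),
    ],
)
def test_parse_csv_counts(tmp_path, rows, n_records, n_rejects):
    """Every input row becomes either a record or an explicit reject."""
    records, rejects = mio.parse_molecules(write_csv(tmp_path, rows))
    assert len(records) == n_records
    assert len(rejects) == n_rejects
    assert len(records) + len(rejects) == len(rows)


def test_parse_missing_file_and_column(tmp_path):
    with pytest.raises(mio.CurationError):
        mio.parse_molecules(tmp_path / "nope.csv")
    bad = tmp_path / "bad.csv"
    bad.write_text("structure,role\nCCO,probe\n")
    with pytest.raises(mio.CurationError, match="smiles"):
        mio.parse_molecules(bad)


def test_parse_smi(tmp_path):
    path = tmp_path / "mols.smi"
    path.write_text("c1ccccc1 benzene\nCCO ethanol\nxxxx bad\n")
    records, rejects = mio.parse_molecules(path)
    assert [r.source_id for r in records] == ["benzene", "ethanol"]
    assert len(rejects) == 1


def test_parse_coloc_records(tmp_path):
    rows = ['c1ccccc1,probe,mitochondria,MTR;MTG,0.85;0.9,,m1']
    records, _ = mio.parse_molecules(write_csv(tmp_path, rows))
    assert records[0].coloc_records == [("MTR", 0.85), ("MTG", 0.9)]


# ---------------------------------------------------------------------------
# standardization

def test_standardize_canonicalizes_and_keys():
    a = mio.standardize_and_key(mio.MoleculeRecord("c1ccccc1"))
    b = mio.standardize_and_key(mio.MoleculeRecord("C1=CC=CC=C1"))
    assert a.inchikey == b.inchikey
    assert a.smiles == b.smiles
    assert len(a.inchikey) == 27


def test_standardize_keeps_salt_fragments():
    """Counterions stay: the key covers the full two-fragment structure."""
    salt = mio.standardize_and_key(mio.MoleculeRecord("[Na+].[Cl-]"))
    assert "." in salt.smiles
    cation_only = mio.standardize_and_key(mio.MoleculeRecord("[Na+]"))
    assert salt.inchikey != cation_only.inchikey


def test_standardize_idempotent():
    once = mio.standardize_and_key(mio.MoleculeRecord("OC(=O)c1ccccc1"))
    twice = mio.standardize_and_key(once)
    assert once == twice


def test_standardize_rejects_garbage():
    with pytest.raises(mio.CurationError):
        mio.standardize_and_key(mio.MoleculeRecord("][junk"))


# ---------------------------------------------------------------------------
# deduplication

def test_deduplicate_rules():
    recs = make_records([
        ("c1ccccc1", "probe", "mitochondria"),
        ("C1=CC=CC=C1", "probe", "mitochondria"),   # same structure, same label
        ("c1ccccc1", "probe", "lysosome"),          # same structure, other label
        ("CCO", "probe", "mitochondria"),
    ])
    out = mio.deduplicate(recs)
    assert len(out) == 3  # within-label duplicate dropped, cross-label kept
    assert out[0].smiles == recs[0].smiles  # first occurrence wins
    assert mio.deduplicate([]) == []


def test_deduplicate_idempotent_and_merges_coloc():
    recs = make_records([
        ("c1ccccc1", "probe", "mitochondria", [("MTR", 0.9)]),
        ("c1ccccc1", "probe", "mitochondria", [("MTG", 0.7)]),
    ])
    out = mio.deduplicate(recs)
    assert len(out) == 1
    assert sorted(out[0].coloc_records) == [("MTG", 0.7), ("MTR", 0.9)]
    assert mio.deduplicate(out) == out


def test_deduplicate_requires_keys():
    with pytest.raises(mio.CurationError):
        mio.deduplicate([mio.MoleculeRecord("CCO")])


# ---------------------------------------------------------------------------
# colocalization labelling

@pytest.mark.parametrize(
    "coloc, expected",
    [
        ([("MTR", 0.85)], "good"),
        ([("MTR", 0.8)], "good"),                   # boundary: not < 0.8
        ([("MTR", 0.7), ("MTR", 0.9)], "good"),     # arithmetic mean = 0.8
        ([("MTR", 0.79)], "weak"),
        ([("lyso_dye", 0.95)], "not_applicable"),   # wrong dye filtered out
        ([], "not_applicable"),
        ([("MTR", 0.95), ("lyso_dye", 0.0)], "good"),  # mean after filtering
    ],
)
def test_label_colocalization(coloc, expected):
    rec = mio.MoleculeRecord("CCO", coloc_records=coloc)
    assert mio.label_colocalization(rec) == expected


def test_label_colocalization_validates():
    rec = mio.MoleculeRecord("CCO", coloc_records=[("MTR", 0.9)])
    with pytest.raises(mio.CurationError):
        mio.label_colocalization(rec, threshold=1.5)
    bad = mio.MoleculeRecord("CCO")
    bad.coloc_records = [("MTR", 1.7)]  # bypass constructor check
    with pytest.raises(mio.CurationError):
        mio.label_colocalization(bad)


@given(
    rs=st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=6),
    bump=st.floats(min_value=0, max_value=0.5, allow_nan=False),
    idx=st.integers(min_value=0, max_value=5),
)
def test_label_colocalization_monotone(rs, bump, idx):
    """Raising any single coefficient never flips good -> weak."""
    idx = idx % len(rs)
    rec = mio.MoleculeRecord("CCO", coloc_records=[("MTR", r) for r in rs])
    before = mio.label_colocalization(rec)
    raised = list(rs)
    raised[idx] = min(1.0, raised[idx] + bump)
    rec2 = mio.MoleculeRecord("CCO", coloc_records=[("MTR", r) for r in raised])
    after = mio.label_colocalization(rec2)
    if before == "good":
        assert after == "good"


# ---------------------------------------------------------------------------
# task tables

def test_build_task_tables_membership():
    recs = make_records([
        ("Cc1ccccc1", "probe", "mitochondria"),
        ("CCO", "np_compound", "mitochondria"),
        ("CCN", "probe", "lysosome"),
    ])
    tables, rejects = mio.build_task_tables(recs)
    assert not rejects
    assert len(tables["B-PvsC"]) == 2
    assert sorted(tables["B-PvsC"].labels) == ["np_compound", "probe"]
    assert len(tables["B-MvsP"]) == 2
    assert sorted(tables["B-MvsP"].labels) == ["mitochondria", "other"]
    assert len(tables["M-PvsP"]) == 2
    assert len(tables["B-McoL"]) == 0  # no colocalization records


def test_build_task_tables_empty():
    tables, rejects = mio.build_task_tables([])
    assert all(len(t) == 0 for t in tables.values())
    assert not rejects


def test_build_task_tables_rejects_orphan_organelle():
    rec = mio.standardize_and_key(
        mio.MoleculeRecord("CCO", organelle_label="mitochondria")
    )
    tables, rejects = mio.build_task_tables([rec])
    assert len(rejects) == 1
    assert "role" in rejects[0].reason


def test_task_table_row_conservation(small_library):
    """Table sizes are reconstructible from the label counts."""
    _, records, _ = small_library
    tables, _ = mio.build_task_tables(records)
    probes = [r for r in records if r.role_label == "probe" and r.organelle_label]
    nps = [r for r in records if r.role_label == "np_compound"]
    n_mito = sum(r.organelle_label == "mitochondria" for r in probes)
    assert len(tables["M-PvsP"]) == len(probes)
    assert len(tables["B-MvsP"]) == len(probes)
    assert len(tables["B-PvsC"]) == n_mito + sum(
        r.organelle_label == "mitochondria" for r in nps
    )
    applicable = sum(
        mio.label_colocalization(r) != "not_applicable"
        for r in probes if r.organelle_label == "mitochondria"
    )
    assert len(tables["B-McoL"]) == applicable


def test_task_table_domain_enforced():
    rec = make_records([("CCO", "probe", "mitochondria")])[0]
    with pytest.raises(mio.CurationError):
        mio.TaskTable("B-MvsP", [(rec, "golgi")])
    with pytest.raises(mio.CurationError):
        mio.TaskTable("B-MvsP", [(rec, "mitochondria"), (rec, "mitochondria")])


def test_curated_roundtrip(tmp_path, small_library):
    _, records, _ = small_library
    path = tmp_path / "curated.csv"
    mio.write_curated(records[:25], path)
    back, rejects = mio.read_curated(path)
    assert not rejects
    assert len(back) == 25
    for orig, rec in zip(records[:25], back):
        assert rec.inchikey == orig.inchikey
        assert rec.coloc_records == [
            (d, pytest.approx(r)) for d, r in orig.coloc_records
        ]
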