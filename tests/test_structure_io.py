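import numpy as np
import pytest

from hemebarrel import (
    AtomRecord,
    ResidueRecord,
    StructureModel,
    SyntheticSpec,
    load_structure,
    make_barrel,
    write_structure,
)
from hemebarrel.structure_io import FormatError, MissingChainError

ALTLOC_PDB = """\
ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60 10.00           N
ATOM      2  N  BALA A   1       1.000   0.000   0.000  0.40 10.00           N
ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
END
"""


def toy_model(n=3, chain="A"):
    residues = [
        ResidueRecord(
            chain, i + 1, "", "GLY",
            [AtomRecord("CA", "C", np.array([i * 3.8, 0.5 * i, 0.0]))],
        )
        for i in range(n)
    ]
    return StructureModel("toy", [chain], residues, [])


def test_roundtrip_preserves_identity_and_coordinates(tmp_path):
    m = toy_model()
    path = tmp_path / "toy.pdb"
    write_structure(m, path)
    m2 = load_structure(path)
    assert [r.key for r in m2.residues] == [r.key for r in m.residues]
    for a, b in zip(m.residues, m2.residues):
        assert np.linalg.norm(a.ca - b.ca) < 1e-3


def test_roundtrip_synthetic_barrel_with_ligand(tmp_path):
    model, gt = make_barrel(SyntheticSpec(heme_mode="cleft_alpha2", seed=5))
    path = tmp_path / "barrel.pdb"
    write_structure(model, path)
    m2 = load_structure(path)
    assert m2.chains == model.chains
    assert len(m2.residues) == len(model.residues)
    assert len(m2.ligands) == 1
    lig = m2.ligands[0]
    assert lig.het_code == "HEM"
    assert lig.fe_pos is not None
    assert len(lig.macrocycle_atoms) >= 12
    for a, b in zip(model.residues, m2.residues):
        assert np.linalg.norm(a.ca - b.ca) < 1e-3
    # re-parse of the re-written file is stable (idempotent round trip)
    path2 = tmp_path / "barrel2.pdb"
    write_structure(m2, path2)
    m3 = load_structure(path2)
    assert [r.key for r in m3.residues] == [r.key for r in m2.residues]


def test_altloc_collapsed_to_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    m = load_structure(p)
    n_atoms = [a for a in m.residues[0].atoms if a.name == "N"]
    assert len(n_atoms) == 1
    assert n_atoms[0].occupancy == pytest.approx(0.6)
    assert np.allclose(n_atoms[0].pos, [0.0, 0.0, 0.0])


def test_ligands_never_contain_polymer_residues():
    model, _ = make_barrel(SyntheticSpec(heme_mode="cavity_beta2", seed=2))
    polymer_keys = {r.key for r in model.residues}
    for lig in model.ligands:
        assert lig.residue.key not in polymer_keys
        assert not lig.residue.is_polymer


def test_chain_filtering_preserves_order(tmp_path):
    model, _ = make_barrel(SyntheticSpec(seed=3))
    path = tmp_path / "two.pdb"
    write_structure(model, path)
    only_b = load_structure(path, chains=["B"])
    assert only_b.chains == ["B"]
    seqs = [r.auth_seq for r in only_b.residues]
    assert seqs == sorted(seqs)
    with pytest.raises(MissingChainError):
        load_structure(path, chains=["Z"])


def test_empty_model_write_is_an_error(tmp_path):
    with pytest.raises(ValueError):
        write_structure(StructureModel("empty", [], [], []), tmp_path / "e.pdb")


def test_unparseable_file_raises_format_error(tmp_path):
    p = tmp_path / "junk.pdb"
    p.write_bytes(b"\x00\x01 not a structure")
    with pytest.raises((FormatError, MissingChainError)):
        load_structure(p, chains=["A"])
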