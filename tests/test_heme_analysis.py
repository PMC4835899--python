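import numpy as np
import pytest

from hemebarrel import (
    SyntheticSpec,
    analyze_heme_site,
    count_hemes,
    find_axial_residues,
    make_barrel,
    make_pseudo_heme,
    ruffling_score,
)
from hemebarrel.structure_io import AtomRecord, ResidueRecord, StructureModel
from hemebarrel.synthetic_data import _ligand_from_atoms, make_ring
from conftest import run_pipeline, transform_model, random_rotation

N_RING_ATOMS = 24
N_MESO = 4


def planar_ligand(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0), meso=0.0):
    return _ligand_from_atoms(make_ring(np.array(center), np.array(normal), meso))


def test_planar_ring_has_zero_ruffling():
    rms, ruffled = ruffling_score(planar_ligand())
    assert rms < 1e-9
    assert ruffled is False


@pytest.mark.parametrize("amp", [0.4, 0.7])
def test_meso_displacement_matches_closed_form(amp):
    rms, ruffled = ruffling_score(planar_ligand(meso=amp))
    expected = np.sqrt(N_MESO * amp**2 / N_RING_ATOMS)
    assert rms == pytest.approx(expected, abs=1e-9)
    assert ruffled == bool(expected > 0.25)


def test_ruffling_rigid_invariant(rng):
    lig = planar_ligand(meso=0.3)
    ref, _ = ruffling_score(lig)
    rot = random_rotation(rng)
    for a in lig.residue.atoms:
        a.pos = rot @ a.pos + np.array([5.0, -3.0, 11.0])
    lig.macrocycle_atoms = [a for a in lig.residue.atoms if a.name != "FE"]
    moved, _ = ruffling_score(lig)
    assert moved == pytest.approx(ref, abs=1e-9)


def test_too_few_ring_atoms_is_an_error():
    lig = planar_ligand()
    lig.macrocycle_atoms = lig.macrocycle_atoms[:8]
    with pytest.raises(ValueError):
        ruffling_score(lig)


def _axial_fixture():
    """Fe at origin, ring in xy; His below (proximal), Asn above (distal),
    Ser on the proximal side (must NOT be chosen as distal)."""
    def res(name, chain, seq, atoms):
        return ResidueRecord(chain, seq, "", name,
                             [AtomRecord(n, n[0], np.array(p, float)) for n, p in atoms])

    his = res("HIS", "A", 10, [("CA", (0, 0, -5.0)), ("NE2", (0, 0, -2.2))])
    asn = res("ASN", "A", 20, [("CA", (0, 2, 5.0)), ("OD1", (0.5, 0.5, 3.0))])
    ser = res("SER", "A", 30, [("CA", (3, 0, -5.0)), ("OG", (2.0, 0.0, -2.8))])
    model = StructureModel("axial", ["A"], [his, asn, ser], [planar_ligand()])
    return model


def test_proximal_and_distal_identification():
    model = _axial_fixture()
    prox, dist = find_axial_residues(model, model.ligands[0])
    assert prox is not None and prox.residue.name == "HIS"
    assert prox.atom_name == "NE2"
    assert prox.distance == pytest.approx(2.2, abs=1e-6)
    assert dist is not None and dist.residue.name == "ASN"
    assert dist.atom_name == "OD1"


def test_distal_must_be_on_opposite_face():
    model = _axial_fixture()
    # remove the Asn: the Ser is within range but on the proximal face
    model.residues = [r for r in model.residues if r.name != "ASN"]
    prox, dist = find_axial_residues(model, model.ligands[0])
    assert prox is not None
    assert dist is None


def test_no_proximal_candidate_within_cutoff_is_flagged():
    model, gt = make_barrel(SyntheticSpec(packing="Type-1", seed=6))
    _, _, _, barrel = run_pipeline(model, gt)
    far = np.array([60.0, 60.0, 0.0])
    model.ligands.append(planar_ligand(center=far))
    site = analyze_heme_site(barrel, model.ligands[0], model)
    assert site.proximal_missing
    assert site.site_mode is None
    assert "undetermined" in site.diagnostics


@pytest.mark.parametrize("mode,expected", [
    ("cleft_alpha2", "SITE_CLEFT_ISDG_OXDA"),
    ("cleft_alpha1", "SITE_CLD_DYP"),
    ("cavity_beta2", "SITE_CAVITY"),
])
def test_site_modes_match_ground_truth(mode, expected):
    for seed in (1, 5, 9):
        model, gt = make_barrel(
            SyntheticSpec(packing="Type-1", heme_mode=mode, noise_sigma=0.3, seed=seed)
        )
        _, _, _, barrel = run_pipeline(model, gt)
        site = analyze_heme_site(barrel, model.ligands[0], model)
        assert site.site_mode == expected == gt.site_mode
        assert site.proximal is not None
        assert (site.proximal.residue.chain_id,
                site.proximal.residue.auth_seq) == tuple(gt.proximal)


def test_homodimer_proximal_symmetry():
    model, gt = make_barrel(SyntheticSpec(packing="Type-1", seed=12))
    make_pseudo_heme("cleft_alpha2", model, gt, both_domains=True)
    _, _, _, barrel = run_pipeline(model, gt)
    sites = [analyze_heme_site(barrel, lig, model) for lig in model.ligands]
    assert len(sites) == 2
    nums = {s.proximal.residue.auth_seq for s in sites}
    assert len(nums) == 1            # same author number in both protomers
    assert {s.proximal.residue.chain_id for s in sites} == {"A", "B"}


def test_heme_counting():
    model, gt = make_barrel(SyntheticSpec(seed=2))
    assert count_hemes(model, model.chains) == 0
    make_pseudo_heme("cleft_alpha2", model, gt, both_domains=True)
    assert count_hemes(model, model.chains) == 2
    # a far-away group does not count toward this barrel
    model.ligands.append(planar_ligand(center=(80.0, 0.0, 0.0)))
    assert count_hemes(model, model.chains) == 2


def test_geometry_rigid_invariant(rng):
    model, gt = make_barrel(SyntheticSpec(heme_mode="cavity_beta2", seed=4))
    _, _, _, barrel = run_pipeline(model, gt)
    ref = analyze_heme_site(barrel, model.ligands[0], model)
    transform_model(model, random_rotation(rng), rng.normal(0, 25, 3))
    _, _, _, barrel2 = run_pipeline(model, gt)
    moved = analyze_heme_site(barrel2, model.ligands[0], model)
    assert moved.site_mode == ref.site_mode
    assert moved.fe_radial == pytest.approx(ref.fe_radial, abs=1e-6)
    assert moved.proximal.distance == pytest.approx(ref.proximal.distance, abs=1e-6)
    assert moved.ruffling_rms == pytest.approx(ref.ruffling_rms, abs=1e-9)
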