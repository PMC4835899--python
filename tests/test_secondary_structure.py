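import numpy as np
import pytest

from hemebarrel import (
    accept_annotation,
    assign_ss,
    detect_hbonds,
    make_helix,
    make_ladder,
)
from hemebarrel.structure_io import StructureModel
from conftest import random_rotation, transform_model


def inter_strand(bonds, n):
    return [h for h in bonds if (h.donor_res < n) != (h.acceptor_res < n)]


@pytest.mark.parametrize("n,minimum", [(6, 4), (4, 2)])
def test_antiparallel_ladder_bond_count(n, minimum):
    model, _ = make_ladder(n, "antiparallel")
    bonds = detect_hbonds(model)
    assert len(inter_strand(bonds, n)) >= minimum


def test_distant_strands_do_not_bond():
    model, _ = make_ladder(6, "antiparallel")
    far = StructureModel(model.id, model.chains, model.residues, [])
    for res in far.chain_residues("B"):
        for a in res.atoms:
            a.pos = a.pos + np.array([30.0, 0.0, 0.0])
    assert not inter_strand(detect_hbonds(far), 6)


def test_helix_has_i_to_i_minus_4_bonds():
    model, _ = make_helix(12)
    bonds = {(h.donor_res, h.acceptor_res) for h in detect_hbonds(model)}
    for i in range(4, 12):
        assert (i, i - 4) in bonds


def test_assign_ss_single_helix():
    model, _ = make_helix(12)
    elements = assign_ss(model, detect_hbonds(model))
    assert [e.kind for e in elements] == ["helix"]
    h = elements[0]
    assert h.start_idx >= 0 and h.end_idx <= 11 and len(h) >= 8


def test_assign_ss_ladder_finds_two_paired_strands():
    model, _ = make_ladder(6, "antiparallel")
    elements = assign_ss(model, detect_hbonds(model))
    strands = [e for e in elements if e.kind == "strand"]
    assert len(strands) == 2
    assert {s.chain_id for s in strands} == {"A", "B"}


def test_lone_strand_is_coil():
    """An isolated extended chain has no ladder partner, hence no elements."""
    model, _ = make_ladder(6, "antiparallel")
    lone = StructureModel("lone", ["A"], model.chain_residues("A"), [])
    assert assign_ss(lone, detect_hbonds(lone)) == []


def test_hbond_set_is_rigid_invariant(rng):
    model, _ = make_ladder(6, "antiparallel")
    ref = sorted((h.donor_res, h.acceptor_res, round(h.energy, 6))
                 for h in detect_hbonds(model))
    for _ in range(3):
        rot = random_rotation(rng)
        t = rng.normal(0, 20, 3)
        moved, _ = make_ladder(6, "antiparallel")
        transform_model(moved, rot, t)
        got = sorted((h.donor_res, h.acceptor_res, round(h.energy, 6))
                     for h in detect_hbonds(moved))
        assert got == ref


class TestAcceptAnnotation:
    def _chain(self, n):
        model, _ = make_helix(max(n, 4))
        res = model.residues[:n]
        return StructureModel("ann", ["A"], res, [])

    def test_direct_transcription(self):
        model = self._chain(18)
        els = accept_annotation(model, {"A": "---EEEE---HHHHH---"})
        assert [(e.kind, len(e)) for e in els] == [("strand", 4), ("helix", 5)]

    def test_short_runs_dropped(self):
        model = self._chain(10)
        els = accept_annotation(model, {"A": "--EE--HHH-"})
        assert els == []

    def test_length_mismatch_is_error(self):
        model = self._chain(10)
        with pytest.raises(ValueError):
            accept_annotation(model, {"A": "EEEE"})

    def test_bad_alphabet_is_error(self):
        model = self._chain(4)
        with pytest.raises(ValueError):
            accept_annotation(model, {"A": "EEXE"})

    def test_consistent_with_geometric_assignment(self):
        """On a full-backbone ladder, annotated elements contain the
        geometrically assigned ones, with matching kinds."""
        model, gt = make_ladder(8, "antiparallel")
        annotated = accept_annotation(model, gt.ss)
        assigned = assign_ss(model, detect_hbonds(model))
        assert assigned, "geometric assignment found nothing"
        for el in assigned:
            hosts = [
                a for a in annotated
                if a.kind == el.kind and a.chain_id == el.chain_id
                and a.start_idx <= el.start_idx and a.end_idx >= el.end_idx
            ]
            assert hosts, f"{el} not contained in any annotated element"
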