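import numpy as np
import pytest

from hemebarrel import (
    SyntheticSpec,
    accept_annotation,
    build_barrel_sheet,
    make_barrel,
    map_domains,
    pair_strands,
    termini_side,
)
from hemebarrel.ferredoxin_map import DomainMappingError
from hemebarrel.secondary_structure import SSElement
from hemebarrel.structure_io import StructureModel
from conftest import run_pipeline


def test_homodimer_labels_match_ground_truth(type1_barrel):
    model, gt = type1_barrel
    _, _, _, barrel = run_pipeline(model, gt)
    assert barrel.arrangement == "homodimer"
    for dom_id, dom in zip("AB", barrel.domains):
        for label, (start, end) in gt.element_spans[dom_id].items():
            el = dom.elements[label]
            assert (el.start_idx, el.end_idx) == (start, end), (dom_id, label)


def test_fused_barrel_levels(fused_barrel):
    model, gt = fused_barrel
    _, _, _, barrel = run_pipeline(model, gt)
    assert barrel.arrangement == "fused"
    assert set(barrel.barrel_labels) == {
        *(f"beta{i}" for i in range(1, 9)), *(f"alpha{i}" for i in range(1, 5))
    }
    # the second half's alpha1 is barrel alpha3, its alpha2 barrel alpha4
    assert barrel.barrel_labels["alpha3"] is barrel.domain_b.elements["alpha1"]
    assert barrel.barrel_labels["alpha4"] is barrel.domain_b.elements["alpha2"]
    assert barrel.barrel_labels["beta5"] is barrel.domain_b.elements["beta1"]


def test_decoy_decorations_do_not_shift_labels(type1_barrel):
    model, gt = type1_barrel
    elements = accept_annotation(model, gt.ss)
    ref = map_domains(
        elements, build_barrel_sheet(pair_strands(elements, None, model), model), model
    )
    # decoys: a helix and a strand carved out of loop residues
    labeled = {
        i for dom in gt.element_spans.values() for s, e in dom.values()
        for i in range(s, e + 1)
    }
    first_b = next(i for i, r in enumerate(model.residues) if r.chain_id == "B")
    loop_runs = []
    run = []
    for i in range(first_b):
        if i not in labeled:
            run.append(i)
        elif run:
            loop_runs.append(run)
            run = []
    decoys = [
        SSElement("helix", "A", loop_runs[0][0], loop_runs[0][0] + 3),
        SSElement("strand", "A", loop_runs[1][0], loop_runs[1][0] + 2),
    ]
    noisy = sorted(elements + decoys, key=lambda e: (e.chain_id, e.start_idx))
    sheet = build_barrel_sheet(pair_strands(noisy, None, model), model)
    barrel = map_domains(noisy, sheet, model)
    for dom_id, dom_ref, dom_new in zip("AB", ref.domains, barrel.domains):
        assert {
            l: (e.start_idx, e.end_idx) for l, e in dom_ref.elements.items()
        } == {l: (e.start_idx, e.end_idx) for l, e in dom_new.elements.items()}


def test_single_domain_is_a_mapping_error(type1_barrel):
    model, gt = type1_barrel
    a_res = model.chain_residues("A")
    half = StructureModel("half", ["A"], a_res, [])
    elements = accept_annotation(half, {"A": gt.ss["A"]})
    sheet = build_barrel_sheet(pair_strands(elements, None, half), half)
    with pytest.raises(DomainMappingError):
        map_domains(elements, sheet, half)


def test_degraded_helix_is_tolerated_and_flagged(type1_barrel):
    model, gt = type1_barrel
    ss_a = list(gt.ss["A"])
    s, e = gt.element_spans["A"]["alpha2"]
    for i in range(s, e + 1):
        ss_a[i] = "-"
    elements = accept_annotation(model, {"A": "".join(ss_a), "B": gt.ss["B"]})
    sheet = build_barrel_sheet(pair_strands(elements, None, model), model)
    barrel = map_domains(elements, sheet, model)
    assert "alpha2" in barrel.domain_a.missing_labels
    assert "alpha2" not in barrel.domain_a.elements
    assert set(barrel.domain_b.elements) == {
        "beta1", "alpha1", "beta2", "beta3", "alpha2", "beta4"
    }


@pytest.mark.parametrize("packing,same_end", [("Type-1", True), ("Type-2", False)])
def test_termini_sides(packing, same_end):
    model, gt = make_barrel(SyntheticSpec(packing=packing, seed=4))
    _, _, sheet, barrel = run_pipeline(model, gt)
    ta = termini_side(barrel.domain_a, sheet)
    tb = termini_side(barrel.domain_b, sheet)
    assert ta[0] * ta[1] > 0        # each domain's termini on one end
    assert tb[0] * tb[1] > 0
    assert (ta[0] * tb[0] > 0) == same_end
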