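import numpy as np
import pytest

from hemebarrel import (
    SyntheticSpec,
    accept_annotation,
    build_barrel_sheet,
    classify_packing,
    make_barrel,
    map_domains,
    pair_strands,
)


def run_pipeline(model, gt, config=None):
    """Annotation-driven pipeline up to the labeled barrel."""
    kw = {} if config is None else {"config": config}
    elements = accept_annotation(model, gt.ss, **kw)
    pairs = pair_strands(elements, None, model, **kw)
    sheet = build_barrel_sheet(pairs, model, **kw)
    barrel = map_domains(elements, sheet, model, **kw)
    return elements, pairs, sheet, barrel


def classify_synthetic(spec: SyntheticSpec):
    model, gt = make_barrel(spec)
    _, _, _, barrel = run_pipeline(model, gt)
    return classify_packing(barrel, model), model, gt, barrel


@pytest.fixture(scope="session")
def type1_barrel():
    return make_barrel(SyntheticSpec(packing="Type-1", seed=1))


@pytest.fixture(scope="session")
def type2_barrel():
    return make_barrel(SyntheticSpec(packing="Type-2", seed=1))


@pytest.fixture(scope="session")
def fused_barrel():
    return make_barrel(SyntheticSpec(packing="Type-1", arrangement="fused", seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def transform_model(model, rot, t):
    """Rigidly transform a StructureModel in place (helper for invariance tests)."""
    for res in model.residues:
        for a in res.atoms:
            a.pos = rot @ a.pos + t
    for lig in model.ligands:
        for a in lig.residue.atoms:
            a.pos = rot @ a.pos + t
        if lig.fe_pos is not None:
            lig.fe_pos = rot @ lig.fe_pos + t
    return model
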