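import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hemebarrel import (
    accept_annotation,
    align_domains,
    enumerate_mappings,
    kabsch_fit,
    make_domain_pair,
    map_isolated_domain,
)
from hemebarrel.superpose import HALF_SWAP, MAPPING_KINDS
from conftest import transform_model


def brute_force_rmsd(a, b):
    """Independent oracle: numeric minimization over rotation vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(0), b.mean(0)
    a0, b0 = a - ca, b - cb

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return float(((a0 @ r.T - b0) ** 2).sum())

    best = np.inf
    rng = np.random.default_rng(0)
    starts = [np.zeros(3)] + [rng.normal(0, 2, 3) for _ in range(7)]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best / len(a)))


def labeled_domain(model):
    elements = accept_annotation(model, model.ss_annotation)
    return map_isolated_domain(elements, model)


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        a = rng.normal(0, 5, (10, 3))
        rot, t, rmsd = kabsch_fit(a, a)
        assert rmsd < 1e-9
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation(self, rng):
        a = rng.normal(0, 5, (12, 3))
        r0 = Rotation.random(rng=rng).as_matrix()
        t0 = rng.normal(0, 10, 3)
        rot, t, rmsd = kabsch_fit(a, a @ r0.T + t0)
        assert rmsd < 1e-9
        assert np.allclose(rot, r0, atol=1e-6)
        assert np.allclose(t, t0, atol=1e-6)

    def test_proper_rotation_enforced(self, rng):
        a = rng.normal(0, 5, (10, 3))
        b = a.copy()
        b[:, 0] *= -1            # reflected set: best proper fit is imperfect
        rot, _, _ = kabsch_fit(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_on_noisy_instances(self, rng):
        for _ in range(5):
            a = rng.normal(0, 5, (10, 3))
            b = a @ Rotation.random(rng=rng).as_matrix().T + rng.normal(0, 0.5, (10, 3))
            _, _, rmsd = kabsch_fit(a, b)
            oracle = brute_force_rmsd(a, b)
            assert abs(rmsd - oracle) < 1e-4
            # isotropic noise sigma on all 3n coordinates minus the 6 fitted
            # rigid degrees of freedom: E[rmsd] ~ sigma*sqrt((3n-6)/n)
            expected = 0.5 * np.sqrt((3 * 10 - 6) / 10)
            assert 0.7 * expected < rmsd < 1.3 * expected

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        rotvec=st.tuples(*([st.floats(-3.0, 3.0)] * 3)),
        shift=st.tuples(*([st.floats(-50.0, 50.0)] * 3)),
        seed=st.integers(0, 2**16),
    )
    def test_exact_rigid_transforms_always_recovered(self, rotvec, shift, seed):
        """Property: for any rigid transform of any non-degenerate point
        cloud, the fit reproduces it with zero residual."""
        pts = np.random.default_rng(seed).normal(0, 4, (8, 3))
        r0 = Rotation.from_rotvec(np.array(rotvec)).as_matrix()
        rot, t, rmsd = kabsch_fit(pts, pts @ r0.T + np.array(shift))
        assert rmsd < 1e-8
        assert np.allclose(rot, r0, atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((4, 3)), np.zeros((5, 3)))


class TestEnumerateMappings:
    def test_four_bijections(self):
        ma, mb = make_domain_pair("direct")
        maps = enumerate_mappings(labeled_domain(ma), labeled_domain(mb))
        assert [k for k, _ in maps] == list(MAPPING_KINDS)
        for _, m in maps:
            assert sorted(m.keys()) == sorted(m.values())
            assert len(set(m.values())) == len(m)

    def test_half_swap_is_an_involution(self):
        composed = {k: HALF_SWAP[v] for k, v in HALF_SWAP.items()}
        assert composed == {k: k for k in HALF_SWAP}

    def test_missing_element_dropped_from_maps(self):
        ma, mb = make_domain_pair("direct")
        da = labeled_domain(ma)
        db = labeled_domain(mb)
        db.elements.pop("alpha2")
        for kind, m in enumerate_mappings(da, db):
            assert "alpha2" not in m.values()


class TestAlignDomains:
    def test_self_alignment_is_exact_direct(self):
        ma, _ = make_domain_pair("direct")
        da = labeled_domain(ma)
        best, _ = align_domains(da, da, ma, ma)
        assert best.mapping_kind == "direct"
        assert best.rmsd < 1e-6
        total = sum(len(e) for e in da.elements.values())
        assert best.n_pairs == total

    def test_sequence_permutant_wins_as_permuted(self):
        ma, mb = make_domain_pair("permuted")
        best, _ = align_domains(labeled_domain(ma), labeled_domain(mb), ma, mb)
        assert best.mapping_kind == "permuted"
        assert best.rmsd < 1e-3

    @pytest.mark.parametrize("kind", MAPPING_KINDS)
    @pytest.mark.parametrize("seed", range(5))
    def test_mapping_kind_recovery_under_noise(self, kind, seed):
        ma, mb = make_domain_pair(kind, seed=seed, noise_sigma=0.5)
        best, _ = align_domains(labeled_domain(ma), labeled_domain(mb), ma, mb)
        assert best.mapping_kind == kind

    def test_symmetry_of_arguments(self):
        ma, mb = make_domain_pair("rotated", seed=3, noise_sigma=0.3)
        da, db = labeled_domain(ma), labeled_domain(mb)
        fwd, _ = align_domains(da, db, ma, mb)
        rev, _ = align_domains(db, da, mb, ma)
        assert fwd.rmsd == pytest.approx(rev.rmsd, abs=1e-6)
        assert np.allclose(fwd.rotation @ rev.rotation, np.eye(3), atol=1e-6)

    def test_rmsd_rigid_invariant(self, rng):
        from scipy.spatial.transform import Rotation

        ma, mb = make_domain_pair("permuted", seed=6, noise_sigma=0.4)
        da, db = labeled_domain(ma), labeled_domain(mb)
        ref, _ = align_domains(da, db, ma, mb)
        transform_model(mb, Rotation.random(rng=rng).as_matrix(), rng.normal(0, 30, 3))
        moved, _ = align_domains(da, db, ma, mb)
        assert moved.rmsd == pytest.approx(ref.rmsd, abs=1e-6)
        assert moved.n_pairs == ref.n_pairs

    def test_rotation_is_orthonormal(self):
        ma, mb = make_domain_pair("rotated", seed=1, noise_sigma=0.2)
        best, cands = align_domains(labeled_domain(ma), labeled_domain(mb), ma, mb)
        for c in cands:
            assert np.allclose(c.rotation @ c.rotation.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(c.rotation) == pytest.approx(1.0, abs=1e-9)
            assert c.n_pairs == len(c.residue_pairs)
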