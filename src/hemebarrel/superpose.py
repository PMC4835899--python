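"""Rigid superposition of ferredoxin-like domains under symmetry hypotheses.

The ferredoxin-like fold has an internal pseudo-two-fold that exchanges its
two beta-alpha-beta units (beta1<->beta3, alpha1<->alpha2, beta2<->beta4).
Two domains can therefore be equivalenced either label-to-label (identity
map) or across the symmetry (half-swap map).  Each label map is fitted by
least squares (Kabsch) with iterative re-pairing, and the winning
hypothesis is named by combining the label map with the fitted rotation
angle between the frames as given:

    identity map,  small rotation  -> direct
    half-swap map, ~180 deg        -> rotated
    half-swap map, small rotation  -> permuted (circular permutation)
    identity map,  ~180 deg        -> rotated+permuted

RMSD and pair count are invariant to rigid pre-transforms of either input;
the rotated/permuted distinction is frame-relative by necessity (for an
exactly symmetric domain a circular permutant is rigid-indistinguishable
from a rotated copy), mirroring how these relations are defined between
domains sitting in their barrels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .ferredoxin_map import FerredoxinDomain, DOMAIN_LABEL_ORDER
from .structure_io import StructureModel

HALF_SWAP = {
    "beta1": "beta3", "alpha1": "alpha2", "beta2": "beta4",
    "beta3": "beta1", "alpha2": "alpha1", "beta4": "beta2",
}
IDENTITY = {l: l for l in DOMAIN_LABEL_ORDER}

MAPPING_KINDS = ("direct", "rotated", "permuted", "rotated+permuted")
_MAP_OF_KIND = {
    "direct": IDENTITY,
    "rotated+permuted": IDENTITY,
    "rotated": HALF_SWAP,
    "permuted": HALF_SWAP,
}


class AlignmentError(ValueError):
    """Raised when no mapping yields enough residue pairs to fit."""


@dataclass
class DomainCorrespondence:
    mapping_kind: str
    element_map: Dict[str, str]
    residue_pairs: List[Tuple[int, int]]
    rotation: np.ndarray            # 3x3 proper rotation
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    n_scored: int = 0               # pairs within the scoring distance
    is_winner: bool = False

    @property
    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch_fit(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimizing |R a + t - b|.

    Reflections are excluded by the usual determinant correction.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not Nx3: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cb - rot @ ca
    diff = (a @ rot.T + t) - b
    rmsd = float(np.sqrt((diff ** 2).sum() / len(a)))
    return rot, t, rmsd


def enumerate_mappings(
    dom_a: FerredoxinDomain, dom_b: FerredoxinDomain
) -> List[Tuple[str, Dict[str, str]]]:
    """The four candidate element maps, restricted to labels both domains have."""
    out = []
    for kind in MAPPING_KINDS:
        base = _MAP_OF_KIND[kind]
        m = {
            la: lb for la, lb in base.items()
            if la in dom_a.elements and lb in dom_b.elements
        }
        out.append((kind, m))
    return out


def _initial_pairs(
    dom_a: FerredoxinDomain,
    dom_b: FerredoxinDomain,
    element_map: Dict[str, str],
) -> List[Tuple[int, int]]:
    """Center-anchored residue pairs per mapped element (truncate to shorter)."""
    pairs: List[Tuple[int, int]] = []
    for la in DOMAIN_LABEL_ORDER:
        if la not in element_map:
            continue
        ea = dom_a.elements[la]
        eb = dom_b.elements[element_map[la]]
        ia = list(ea.indices)
        ib = list(eb.indices)
        n = min(len(ia), len(ib))
        offa = (len(ia) - n) // 2
        offb = (len(ib) - n) // 2
        pairs.extend(zip(ia[offa:offa + n], ib[offb:offb + n]))
    return pairs


def _lis_filter(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Longest subsequence increasing in both indices (order preservation)."""
    if not pairs:
        return pairs
    pairs = sorted(pairs)
    n = len(pairs)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if pairs[j][1] < pairs[i][1] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    k = int(np.argmax(best_len))
    out = []
    while k != -1:
        out.append(pairs[k])
        k = prev[k]
    return out[::-1]


def _repair(
    ca_a: Dict[int, np.ndarray],
    ca_b: Dict[int, np.ndarray],
    dom_a: FerredoxinDomain,
    dom_b: FerredoxinDomain,
    element_map: Dict[str, str],
    rot: np.ndarray,
    t: np.ndarray,
    cutoff: float,
) -> List[Tuple[int, int]]:
    """Mutually-nearest Ca pairs within cutoff, per mapped element, ordered."""
    pairs: List[Tuple[int, int]] = []
    for la in DOMAIN_LABEL_ORDER:
        if la not in element_map:
            continue
        ia = [i for i in dom_a.elements[la].indices if i in ca_a]
        ib = [j for j in dom_b.elements[element_map[la]].indices if j in ca_b]
        if not ia or not ib:
            continue
        pa = np.array([ca_a[i] for i in ia]) @ rot.T + t
        pb = np.array([ca_b[j] for j in ib])
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        el_pairs = []
        for r in range(len(ia)):
            c = int(np.argmin(d[r]))
            if d[r, c] <= cutoff and int(np.argmin(d[:, c])) == r:
                el_pairs.append((ia[r], ib[c]))
        pairs.extend(_lis_filter(el_pairs))
    return pairs


def align_domains(
    dom_a: FerredoxinDomain,
    dom_b: FerredoxinDomain,
    model_a: StructureModel,
    model_b: StructureModel,
    mappings: Optional[Sequence[str]] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Tuple[DomainCorrespondence, List[DomainCorrespondence]]:
    """Fit all candidate correspondences; return (best, all candidates).

    Best = most residue pairs within ``config.score_distance`` after the
    fit, ties broken by lower RMSD.  Candidates sharing a label map share
    a fit; the winner's kind is resolved by the fitted rotation angle.
    """
    wanted = list(mappings) if mappings is not None else list(MAPPING_KINDS)
    candidates = [c for c in enumerate_mappings(dom_a, dom_b) if c[0] in wanted]
    if not candidates:
        raise AlignmentError("no candidate mappings requested")

    ca_a = {
        i: model_a.residues[i].ca
        for el in dom_a.elements.values() for i in el.indices
        if model_a.residues[i].ca is not None
    }
    ca_b = {
        j: model_b.residues[j].ca
        for el in dom_b.elements.values() for j in el.indices
        if model_b.residues[j].ca is not None
    }

    # one geometric fit per distinct label map
    fits: Dict[Tuple[Tuple[str, str], ...], dict] = {}
    for kind, emap in candidates:
        key = tuple(sorted(emap.items()))
        if key in fits:
            continue
        pairs = [
            (i, j) for i, j in _initial_pairs(dom_a, dom_b, emap)
            if i in ca_a and j in ca_b
        ]
        if len(pairs) < 3:
            continue
        a = np.array([ca_a[i] for i, _ in pairs])
        b = np.array([ca_b[j] for _, j in pairs])
        rot, t, rmsd = kabsch_fit(a, b)
        for _ in range(config.max_refine_iter):
            new_pairs = _repair(ca_a, ca_b, dom_a, dom_b, emap, rot, t,
                                config.pair_distance)
            if len(new_pairs) < 3:
                break
            a = np.array([ca_a[i] for i, _ in new_pairs])
            b = np.array([ca_b[j] for _, j in new_pairs])
            rot, t, rmsd = kabsch_fit(a, b)
            if new_pairs == pairs:
                break
            pairs = new_pairs
        dists = np.linalg.norm((a @ rot.T + t) - b, axis=1)
        fits[key] = dict(
            pairs=pairs, rot=rot, t=t, rmsd=rmsd,
            n_scored=int((dists <= config.score_distance).sum()),
        )

    if not fits:
        raise AlignmentError(
            "fewer than 3 initial residue pairs for every candidate mapping"
        )

    results: List[DomainCorrespondence] = []
    for kind, emap in candidates:
        key = tuple(sorted(emap.items()))
        if key not in fits:
            continue
        f = fits[key]
        results.append(DomainCorrespondence(
            mapping_kind=kind,
            element_map=dict(emap),
            residue_pairs=list(f["pairs"]),
            rotation=f["rot"],
            translation=f["t"],
            rmsd=f["rmsd"],
            n_pairs=len(f["pairs"]),
            n_scored=f["n_scored"],
        ))

    def _kind_consistent(c: DomainCorrespondence) -> bool:
        big = c.rotation_angle_deg >= 90.0
        identity_map = all(a == b for a, b in c.element_map.items())
        if identity_map:
            return big == (c.mapping_kind == "rotated+permuted")
        return big == (c.mapping_kind == "rotated")

    consistent = [c for c in results if _kind_consistent(c)]
    pool = consistent if consistent else results
    best = max(pool, key=lambda c: (c.n_scored, -c.rmsd))
    best.is_winner = True
    return best, results
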