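"""Backbone hydrogen bonds and helix/strand assignment.

A deliberately minimal two-state assigner: amide hydrogens are placed
geometrically when absent, donor->acceptor electrostatic energies are
computed with the classic dipole-dipole form E = 0.084 * 332 *
(1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN) kcal/mol, and residues are marked
helix (i -> i-4 turn ladders) or strand (inter-strand bridge ladders).
No 3-10/pi helices, bridges, bends or accessibility -- the downstream
topology analysis only needs the helix/strand distinction.

Ca-only models (e.g. idealized synthetic barrels) bypass geometry through
:func:`accept_annotation`, which transcribes an external H/E/- string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .structure_io import StructureModel

_Q = 0.084 * 332.0  # kcal*Angstrom/mol, partial-charge dipole constant
_MIN_DIST = 0.5     # guard against singular 1/r for clashing coordinates


@dataclass(frozen=True)
class HBond:
    donor_res: int      # internal residue index of the NH donor
    acceptor_res: int   # internal residue index of the C=O acceptor
    energy: float       # kcal/mol


@dataclass
class SSElement:
    kind: str           # "helix" | "strand"
    chain_id: str
    start_idx: int      # internal residue index, inclusive
    end_idx: int        # internal residue index, inclusive
    label: str = ""     # assigned later (beta1..beta4, alpha1, alpha2)

    def __len__(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def indices(self) -> range:
        return range(self.start_idx, self.end_idx + 1)


def _backbone(model: StructureModel):
    """Per-residue backbone coordinate dict (None where incomplete)."""
    out = []
    for res in model.residues:
        rec = {}
        for name in ("N", "CA", "C", "O"):
            a = res.atom(name)
            rec[name] = None if a is None else a.pos
        h = res.atom("H")
        rec["H"] = None if h is None else h.pos
        out.append(rec if all(rec[n] is not None for n in ("N", "CA", "C", "O")) else None)
    return out


def _place_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Place H 1.0 A from N along the bisector opposite N's heavy neighbors."""
    u = n - c_prev
    v = n - ca
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = u + v
    nrm = np.linalg.norm(d)
    if nrm < 1e-6:  # degenerate (collinear) geometry
        d = u
        nrm = 1.0
    return n + d / nrm


def detect_hbonds(
    model: StructureModel, config: PipelineConfig = DEFAULT_CONFIG
) -> List[HBond]:
    """Backbone N-H...O=C hydrogen bonds below the energy cutoff.

    Residues with missing backbone atoms are skipped.  Prolines and chain
    N-termini have no placeable amide hydrogen and never donate.  At most
    the two best (lowest-energy) bonds per donor are kept.
    """
    bb = _backbone(model)
    n_res = len(model.residues)
    chain_of = [r.chain_id for r in model.residues]

    donors: List[Tuple[int, np.ndarray, np.ndarray]] = []  # (idx, N, H)
    for i in range(n_res):
        if bb[i] is None or model.residues[i].name == "PRO":
            continue
        h = bb[i]["H"]
        if h is None:
            if i == 0 or bb[i - 1] is None or chain_of[i - 1] != chain_of[i]:
                continue
            h = _place_amide_h(bb[i]["N"], bb[i]["CA"], bb[i - 1]["C"])
        donors.append((i, bb[i]["N"], h))

    acceptors = [
        (j, bb[j]["C"], bb[j]["O"]) for j in range(n_res) if bb[j] is not None
    ]
    if not donors or not acceptors:
        return []

    acc_o = np.array([o for _, _, o in acceptors])
    per_donor: List[HBond] = []
    for i, npos, hpos in donors:
        # coarse distance prefilter on N...O
        d_no = np.linalg.norm(acc_o - npos, axis=1)
        for k in np.nonzero(d_no < 5.2)[0]:
            j, cpos, opos = acceptors[k]
            # an amide cannot bond its own or an adjacent residue's carbonyl
            if abs(i - j) < 2 and chain_of[i] == chain_of[j]:
                continue
            d_on = max(np.linalg.norm(opos - npos), _MIN_DIST)
            d_ch = max(np.linalg.norm(cpos - hpos), _MIN_DIST)
            d_oh = max(np.linalg.norm(opos - hpos), _MIN_DIST)
            d_cn = max(np.linalg.norm(cpos - npos), _MIN_DIST)
            e = _Q * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
            if e < config.hbond_energy_cutoff:
                per_donor.append(HBond(i, j, e))

    # keep the two best bonds per donor
    by_donor: Dict[int, List[HBond]] = {}
    for hb in per_donor:
        by_donor.setdefault(hb.donor_res, []).append(hb)
    kept: List[HBond] = []
    for i in sorted(by_donor):
        kept.extend(sorted(by_donor[i], key=lambda h: h.energy)[:2])
    return kept


def _segments(flags: Sequence[bool], chain_of: Sequence[str]):
    """Maximal runs of True within a single chain -> (start, end) inclusive."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        boundary = i > 0 and chain_of[i] != chain_of[i - 1]
        if f and start is not None and boundary:
            runs.append((start, i - 1))
            start = i
        elif f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def assign_ss(
    model: StructureModel,
    hbonds: List[HBond],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[SSElement]:
    """Two-state secondary structure from hydrogen-bond patterns.

    Helix: two consecutive i+4 -> i turns mark residues i+1..i+4.
    Strand: ladders of two or more consecutive (anti)parallel bridges.
    Runs shorter than the configured minima are dropped; overlaps resolve
    strand-over-helix.
    """
    n = len(model.residues)
    chain_of = [r.chain_id for r in model.residues]
    has = {(hb.donor_res, hb.acceptor_res) for hb in hbonds}

    def hb(d: int, a: int) -> bool:
        return (d, a) in has

    # --- helices ---------------------------------------------------------
    turn4 = [
        i + 4 < n and chain_of[i] == chain_of[i + 4] and hb(i + 4, i)
        for i in range(n)
    ]
    helix = [False] * n
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                helix[k] = True

    # --- strands ---------------------------------------------------------
    def parallel_bridge(i: int, j: int) -> bool:
        return (hb(i, j - 1) and hb(j + 1, i)) or (hb(j, i - 1) and hb(i + 1, j))

    def antiparallel_bridge(i: int, j: int) -> bool:
        return (hb(i, j) and hb(j, i)) or (hb(i + 1, j - 1) and hb(j + 1, i - 1))

    bridge_partners: Dict[int, List[int]] = {}
    pairs_considered = {
        (min(d, a), max(d, a))
        for d, a in has
        if abs(d - a) >= 2 or chain_of[d] != chain_of[a]
    }
    # bridges may sit one residue away from the actual bond; widen the net
    cand = set()
    for i, j in pairs_considered:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                a, b = i + di, j + dj
                if 0 <= a < n and 0 <= b < n and a < b:
                    cand.add((a, b))
    bridges = set()
    for i, j in cand:
        if 1 <= i < n - 1 and 1 <= j < n - 1 and (abs(i - j) >= 3 or chain_of[i] != chain_of[j]):
            if parallel_bridge(i, j) or antiparallel_bridge(i, j):
                bridges.add((i, j))

    strand = [False] * n
    for i, j in bridges:
        # ladder: an adjacent bridge in either direction
        neighbours = [
            (i + 1, j + 1), (i + 1, j - 1), (i - 1, j + 1), (i - 1, j - 1),
            (i + 2, j + 2), (i + 2, j - 2), (i - 2, j + 2), (i - 2, j - 2),
        ]
        if any((a, b) in bridges or (b, a) in bridges for a, b in neighbours):
            strand[i] = strand[j] = True
    # fill single gaps inside a strand run (alternating bridge registers)
    for i in range(1, n - 1):
        if not strand[i] and strand[i - 1] and strand[i + 1] and chain_of[i - 1] == chain_of[i + 1]:
            strand[i] = True

    # strand beats helix on overlap
    helix = [h and not s for h, s in zip(helix, strand)]

    elements: List[SSElement] = []
    for s, e in _segments(strand, chain_of):
        if e - s + 1 >= config.min_strand_len:
            elements.append(SSElement("strand", chain_of[s], s, e))
    for s, e in _segments(helix, chain_of):
        if e - s + 1 >= config.min_helix_len:
            elements.append(SSElement("helix", chain_of[s], s, e))
    elements.sort(key=lambda el: (model.chains.index(el.chain_id), el.start_idx))
    return elements


def accept_annotation(
    model: StructureModel,
    annotation: Dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[SSElement]:
    """Build SS elements directly from per-chain H/E/- strings.

    The injection point for Ca-only models and third-party DSSP output:
    downstream stages are agnostic to where the assignment came from.
    """
    elements: List[SSElement] = []
    for chain_id in model.chains:
        resids = model.chain_residues(chain_id)
        ann = annotation.get(chain_id)
        if ann is None:
            raise ValueError(f"no annotation for chain {chain_id}")
        if len(ann) != len(resids):
            raise ValueError(
                f"annotation length {len(ann)} != {len(resids)} residues in chain {chain_id}"
            )
        bad = set(ann) - set("HE-")
        if bad:
            raise ValueError(f"annotation alphabet must be H/E/-, got {sorted(bad)}")
        first, _ = model.chain_index_range(chain_id)
        i = 0
        while i < len(ann):
            ch = ann[i]
            j = i
            while j < len(ann) and ann[j] == ch:
                j += 1
            length = j - i
            if ch == "E" and length >= config.min_strand_len:
                elements.append(SSElement("strand", chain_id, first + i, first + j - 1))
            elif ch == "H" and length >= config.min_helix_len:
                elements.append(SSElement("helix", chain_id, first + i, first + j - 1))
            i = j
    elements.sort(key=lambda el: (model.chains.index(el.chain_id), el.start_idx))
    return elements
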