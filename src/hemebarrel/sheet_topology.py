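"""Strand pairing graph and barrel sheet geometry.

Strand pairs are scored either by inter-strand backbone hydrogen bonds
(full-backbone models) or by Ca-Ca contacts (annotation-driven Ca-only
models).  The closed eight-stranded barrel is the single 8-cycle of the
pairing graph; its axis is taken from the singular directions of the
centered strand midpoints, picking the direction that best aligns with
the strands themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import networkx as nx

from .config import PipelineConfig, DEFAULT_CONFIG
from .secondary_structure import HBond, SSElement
from .structure_io import StructureModel


@dataclass
class StrandPair:
    strand_a: SSElement
    strand_b: SSElement
    n_hbonds: int                  # H-bond count, or contact count in Ca mode
    orientation: str               # "parallel" | "antiparallel"


@dataclass
class BarrelSheet:
    strands: List[SSElement]       # cyclic order (len 8 when closed)
    orientations: List[str]        # per adjacent pair in the cycle
    axis: np.ndarray               # unit vector
    center: np.ndarray
    closed: bool
    diagnostics: str = ""


def strand_direction(model: StructureModel, strand: SSElement) -> np.ndarray:
    """Unit N->C direction fitted by least squares through the Ca trace."""
    coords = model.ca_coords(list(strand.indices))
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, coords[-1] - coords[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def strand_midpoint(model: StructureModel, strand: SSElement) -> np.ndarray:
    return model.ca_coords(list(strand.indices)).mean(axis=0)


def pair_strands(
    elements: Sequence[SSElement],
    hbonds: Optional[Sequence[HBond]],
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[StrandPair]:
    """All strand pairs supported by enough H-bonds (or Ca contacts).

    Passing ``hbonds=None`` (or an empty list) switches to contact mode:
    Ca-Ca distances below ``config.contact_cutoff`` count, with the
    ``min_pair_contacts`` threshold.
    """
    strands = [e for e in elements if e.kind == "strand"]
    if len(strands) < 2:
        return []

    contact_mode = not hbonds
    pairs: List[StrandPair] = []
    res_of = {}
    if not contact_mode:
        for si, s in enumerate(strands):
            for i in s.indices:
                res_of[i] = si

    for ai in range(len(strands)):
        for bi in range(ai + 1, len(strands)):
            sa, sb = strands[ai], strands[bi]
            if contact_mode:
                ca = model.ca_coords(list(sa.indices))
                cb = model.ca_coords(list(sb.indices))
                d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
                count = int((d < config.contact_cutoff).sum())
                threshold = config.min_pair_contacts
            else:
                ia, ib = set(sa.indices), set(sb.indices)
                count = sum(
                    1
                    for hb in hbonds
                    if (hb.donor_res in ia and hb.acceptor_res in ib)
                    or (hb.donor_res in ib and hb.acceptor_res in ia)
                )
                threshold = config.min_pair_hbonds
            if count >= threshold:
                da = strand_direction(model, sa)
                db = strand_direction(model, sb)
                orientation = "parallel" if float(np.dot(da, db)) > 0 else "antiparallel"
                pairs.append(StrandPair(sa, sb, count, orientation))
    return pairs


def _pick_axis(midpoints: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Singular direction of the midpoint cloud most aligned with strands."""
    centered = midpoints - midpoints.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    align = [float(np.abs(directions @ v).sum()) for v in vt]
    return vt[int(np.argmax(align))]


def build_barrel_sheet(
    pairs: Sequence[StrandPair],
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> BarrelSheet:
    """Extract the barrel cycle and axis from the pairing graph.

    A missing cycle is a diagnosis (``closed=False``), not an exception:
    open sheets are a legitimate outcome for broken or partial inputs.
    """
    g = nx.Graph()
    strands: List[SSElement] = []
    seen = set()
    for p in pairs:
        for s in (p.strand_a, p.strand_b):
            key = id(s)
            if key not in seen:
                seen.add(key)
                strands.append(s)
        g.add_edge(id(p.strand_a), id(p.strand_b), pair=p)
    by_id = {id(s): s for s in strands}

    cycles = nx.cycle_basis(g) if g.number_of_nodes() else []
    cycle = max(cycles, key=len) if cycles else []
    closed = len(cycle) == 8
    diagnostics = "" if closed else (
        f"no 8-cycle in pairing graph (longest cycle {len(cycle)}, "
        f"{g.number_of_nodes()} strands, {g.number_of_edges()} pairs)"
    )

    cyc_strands = [by_id[n] for n in cycle] if cycle else strands
    if not cyc_strands:
        return BarrelSheet([], [], np.array([0.0, 0.0, 1.0]), np.zeros(3), False,
                           diagnostics or "no strand pairs")

    mids = np.array([strand_midpoint(model, s) for s in cyc_strands])
    dirs = np.array([strand_direction(model, s) for s in cyc_strands])
    axis = _pick_axis(mids, dirs) if len(cyc_strands) >= 3 else dirs[0]
    center = mids.mean(axis=0)

    # axis sign: the first chain's N-terminus projects negative
    first_chain = model.chains[0]
    first_idx, _ = model.chain_index_range(first_chain)
    nterm = model.residues[first_idx].ca
    if nterm is not None and float(np.dot(nterm - center, axis)) > 0:
        axis = -axis
    axis = axis / np.linalg.norm(axis)

    orientations = []
    if cycle:
        for k in range(len(cyc_strands)):
            a = cyc_strands[k]
            b = cyc_strands[(k + 1) % len(cyc_strands)]
            da = strand_direction(model, a)
            db = strand_direction(model, b)
            orientations.append("parallel" if float(np.dot(da, db)) > 0 else "antiparallel")

    return BarrelSheet(cyc_strands, orientations, axis, center, closed, diagnostics)
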