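"""Identify the two ferredoxin-like domains of a barrel and label elements.

Each ferredoxin-like domain is a beta-alpha-beta-beta-alpha-beta unit
(labels beta1, alpha1, beta2, beta3, alpha2, beta4 in sequence order)
whose four strands are all members of the closed 8-cycle.  A chain may
carry one domain (homo-/heterodimeric barrels) or two fused domains in
tandem; fused barrels additionally receive barrel-level labels beta1-beta8
and alpha1-alpha4 numbered continuously along the chain.

Candidate assignments skip non-core decorations: the search maximizes
core-cycle membership of the chosen strands first and total element
length second.  A domain with a degraded helix (one missing alpha) is
tolerated and flagged.
"""

from __future__ import annotations

import difflib
import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .secondary_structure import SSElement
from .sheet_topology import BarrelSheet
from .structure_io import StructureModel

BETA_LABELS = ("beta1", "beta2", "beta3", "beta4")
DOMAIN_LABEL_ORDER = ("beta1", "alpha1", "beta2", "beta3", "alpha2", "beta4")


class DomainMappingError(ValueError):
    """Raised when fewer than two ferredoxin-like domains can be mapped."""


@dataclass
class FerredoxinDomain:
    chain_id: str
    elements: Dict[str, SSElement]          # label -> element
    seq_span: Tuple[int, int]               # internal indices, inclusive
    n_term_pos: np.ndarray
    c_term_pos: np.ndarray
    is_fused_half: bool = False
    half_index: int = 0                     # 1 or 2 when fused
    missing_labels: Tuple[str, ...] = ()    # degraded-helix tolerance

    def strand(self, label: str) -> SSElement:
        return self.elements[label]

    @property
    def strands(self) -> List[SSElement]:
        return [self.elements[l] for l in BETA_LABELS if l in self.elements]


@dataclass
class BarrelModel:
    domain_a: FerredoxinDomain
    domain_b: FerredoxinDomain
    sheet: BarrelSheet
    arrangement: str                        # homodimer | heterodimer | fused
    barrel_labels: Dict[str, SSElement] = field(default_factory=dict)

    @property
    def domains(self) -> Tuple[FerredoxinDomain, FerredoxinDomain]:
        return (self.domain_a, self.domain_b)

    def domain_of_element(self, element: SSElement) -> Optional[FerredoxinDomain]:
        for dom in self.domains:
            if any(el is element for el in dom.elements.values()):
                return dom
        return None

    def domain_label_of(self, element: SSElement) -> Optional[Tuple[str, str]]:
        """(domain id 'A'/'B', domain-level label) of an element."""
        for name, dom in zip("AB", self.domains):
            for label, el in dom.elements.items():
                if el is element:
                    return name, label
        return None

    def barrel_label_of(self, element: SSElement) -> Optional[str]:
        for label, el in self.barrel_labels.items():
            if el is element:
                return label
        return None


def _candidate_assignments(chain_elements: List[SSElement], core_ids: set):
    """Enumerate E-H-E-E-H-E (and degraded-helix) matches over the chain.

    Yields (score, labels) where labels maps domain labels to elements and
    score = (#core strands, total length).  Helices are optional one at a
    time; strands must appear in sequence order.
    """
    strands = [(i, e) for i, e in enumerate(chain_elements) if e.kind == "strand"]
    helices = [(i, e) for i, e in enumerate(chain_elements) if e.kind == "helix"]
    for combo in itertools.combinations(strands, 4):
        pos = [i for i, _ in combo]
        els = [e for _, e in combo]
        # helix candidates between beta1-beta2 and between beta3-beta4
        h1 = [e for i, e in helices if pos[0] < i < pos[1]]
        h2 = [e for i, e in helices if pos[2] < i < pos[3]]
        for a1 in (h1 or [None]):
            for a2 in (h2 or [None]):
                labels: Dict[str, SSElement] = {
                    "beta1": els[0], "beta2": els[1],
                    "beta3": els[2], "beta4": els[3],
                }
                missing = []
                if a1 is not None:
                    labels["alpha1"] = a1
                else:
                    missing.append("alpha1")
                if a2 is not None:
                    labels["alpha2"] = a2
                else:
                    missing.append("alpha2")
                if len(missing) > 1:
                    continue  # at most one degraded helix tolerated
                n_core = sum(1 for e in els if id(e) in core_ids)
                total_len = sum(len(e) for e in labels.values())
                yield (n_core, len(labels), total_len), labels, tuple(missing)


def _best_assignment(chain_elements: List[SSElement], core_ids: set):
    best = None
    for score, labels, missing in _candidate_assignments(chain_elements, core_ids):
        if best is None or score > best[0]:
            best = (score, labels, missing)
    return best


def _make_domain(
    model: StructureModel,
    chain_id: str,
    labels: Dict[str, SSElement],
    missing: Tuple[str, ...],
    fused_half: int = 0,
) -> FerredoxinDomain:
    start = min(e.start_idx for e in labels.values())
    end = max(e.end_idx for e in labels.values())
    return FerredoxinDomain(
        chain_id=chain_id,
        elements=labels,
        seq_span=(start, end),
        n_term_pos=model.residues[start].ca,
        c_term_pos=model.residues[end].ca,
        is_fused_half=fused_half > 0,
        half_index=fused_half,
        missing_labels=missing,
    )


def _chain_identity(model: StructureModel, ca: str, cb: str) -> float:
    sa = [r.name for r in model.chain_residues(ca)]
    sb = [r.name for r in model.chain_residues(cb)]
    return difflib.SequenceMatcher(a=sa, b=sb).ratio()


def _fused_split(chain_elements: List[SSElement], core_ids: set):
    """Best (prefix-domain, suffix-domain) split of one chain's elements."""
    best = None
    for cut in range(4, len(chain_elements) - 3):
        first = _best_assignment(chain_elements[:cut], core_ids)
        second = _best_assignment(chain_elements[cut:], core_ids)
        if first is None or second is None:
            continue
        score = (first[0][0] + second[0][0], first[0][2] + second[0][2])
        if best is None or score > best[0]:
            best = (score, first, second)
    return best


def map_domains(
    elements: Sequence[SSElement],
    sheet: BarrelSheet,
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> BarrelModel:
    """Label the two ferredoxin-like domains and decide the arrangement."""
    core_ids = {id(s) for s in sheet.strands}
    domains: List[FerredoxinDomain] = []
    per_chain: Dict[str, List[SSElement]] = {}
    for e in elements:
        per_chain.setdefault(e.chain_id, []).append(e)

    candidates: List[Tuple[str, object, object]] = []
    for chain_id in model.chains:
        ch_els = sorted(per_chain.get(chain_id, []), key=lambda e: e.start_idx)
        if sum(1 for e in ch_els if e.kind == "strand") >= 8:
            split = _fused_split(ch_els, core_ids)
            if split is not None:
                _, first, second = split
                d1 = _make_domain(model, chain_id, first[1], first[2], fused_half=1)
                d2 = _make_domain(model, chain_id, second[1], second[2], fused_half=2)
                domains.extend([d1, d2])
                continue
        single = _best_assignment(ch_els, core_ids)
        if single is not None and single[0][0] >= 3:
            domains.append(_make_domain(model, chain_id, single[1], single[2]))

    if len(domains) < 2:
        found = [
            f"{e.chain_id}:{e.kind}[{e.start_idx}-{e.end_idx}]" for e in elements
        ]
        raise DomainMappingError(
            f"found {len(domains)} ferredoxin-like domain(s); candidate elements: {found}"
        )
    domains = domains[:2]
    dom_a, dom_b = domains

    if dom_a.is_fused_half and dom_b.is_fused_half and dom_a.chain_id == dom_b.chain_id:
        arrangement = "fused"
    else:
        ident = _chain_identity(model, dom_a.chain_id, dom_b.chain_id)
        arrangement = "homodimer" if ident > config.homodimer_identity else "heterodimer"

    barrel_labels: Dict[str, SSElement] = {}
    if arrangement == "fused":
        # continuous numbering along the chain: domain 2's alpha1 is barrel
        # alpha3, its beta1 is barrel beta5, and so on
        for half, dom in ((1, dom_a), (2, dom_b)):
            off_b = 0 if half == 1 else 4
            off_a = 0 if half == 1 else 2
            for label, el in dom.elements.items():
                if label.startswith("beta"):
                    barrel_labels[f"beta{int(label[4]) + off_b}"] = el
                else:
                    barrel_labels[f"alpha{int(label[5]) + off_a}"] = el

    return BarrelModel(dom_a, dom_b, sheet, arrangement, barrel_labels)


def map_isolated_domain(
    elements: Sequence[SSElement],
    model: StructureModel,
    chain_id: Optional[str] = None,
) -> FerredoxinDomain:
    """Label a single ferredoxin-like domain outside any barrel context.

    Used when comparing isolated domains (no closed sheet to define core
    strands); the assignment simply maximizes total element length over
    the beta-alpha-beta-beta-alpha-beta pattern.
    """
    chain = chain_id or model.chains[0]
    ch_els = sorted(
        [e for e in elements if e.chain_id == chain], key=lambda e: e.start_idx
    )
    best = _best_assignment(ch_els, core_ids=set())
    if best is None:
        raise DomainMappingError(f"no ferredoxin-like pattern in chain {chain}")
    return _make_domain(model, chain, best[1], best[2])


def termini_side(domain: FerredoxinDomain, sheet: BarrelSheet) -> Tuple[float, float]:
    """Signed axial coordinates of the domain's N and C termini."""
    t_n = float(np.dot(domain.n_term_pos - sheet.center, sheet.axis))
    t_c = float(np.dot(domain.c_term_pos - sheet.center, sheet.axis))
    return t_n, t_c
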