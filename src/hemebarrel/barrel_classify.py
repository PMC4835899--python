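"""Type-1 / Type-2 barrel packing classification.

The two packing modes differ in which strands cross the domain boundary
in the closed 8-cycle: Type-1 pairs beta2 of one ferredoxin-like domain
with beta4 of the other (both inter-domain seams beta2--beta4), Type-2
pairs beta2 with beta2 and beta4 with beta4.  Termini orientation is the
geometric corollary (Type-1: all four domain termini on one barrel end;
Type-2: the two domains' termini on opposite ends) and is reported as
corroboration, never as a veto.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .ferredoxin_map import BarrelModel, termini_side
from .sheet_topology import strand_direction

_ARROW_UP = "↑"
_ARROW_DOWN = "↓"
_GREEK_BETA = "β"


@dataclass
class PackingCall:
    packing: str                                  # Type-1 | Type-2 | unclassified
    inter_domain_pairs: List[Tuple[str, str]]     # e.g. [("A:beta2", "B:beta4"), ...]
    strand_order_string: str
    termini_consistent: Optional[bool]
    diagnostics: str = ""


def _cycle_labels(barrel: BarrelModel):
    """(domain id, label) for each strand around the sheet cycle."""
    out = []
    for s in barrel.sheet.strands:
        tagged = barrel.domain_label_of(s)
        out.append(tagged)
    return out


def classify_packing(barrel: BarrelModel, model=None) -> PackingCall:
    """Read the two inter-domain seams off the 8-cycle and match patterns."""
    sheet = barrel.sheet
    if not sheet.closed or len(sheet.strands) != 8:
        return PackingCall(
            "unclassified", [], "", None,
            diagnostics=sheet.diagnostics or "sheet not a closed 8-cycle",
        )

    tags = _cycle_labels(barrel)
    if any(t is None for t in tags):
        missing = [i for i, t in enumerate(tags) if t is None]
        return PackingCall(
            "unclassified", [], "", None,
            diagnostics=f"cycle strands at positions {missing} carry no domain label",
        )

    n = len(tags)
    seams = [
        k for k in range(n) if tags[k][0] != tags[(k + 1) % n][0]
    ]
    if len(seams) != 2:
        return PackingCall(
            "unclassified", [], "", None,
            diagnostics=f"{len(seams)} inter-domain seams in cycle (expected 2); "
                        "domain strands not contiguous",
        )

    pairs = []
    for k in seams:
        a, b = tags[k], tags[(k + 1) % n]
        if a[0] == "B":  # normalize to (A-side, B-side)
            a, b = b, a
        pairs.append((f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}"))
    seam_set = {(p[0].split(":")[1], p[1].split(":")[1]) for p in pairs}

    if seam_set == {("beta2", "beta4"), ("beta4", "beta2")}:
        packing = "Type-1"
    elif seam_set == {("beta2", "beta2"), ("beta4", "beta4")}:
        packing = "Type-2"
    else:
        return PackingCall(
            "unclassified", pairs, "", None,
            diagnostics=f"inter-domain seams {sorted(seam_set)} match neither packing pattern",
        )

    order_string = _strand_order_string(barrel, tags, model)
    termini_ok = _termini_consistent(barrel, packing)
    return PackingCall(packing, pairs, order_string, termini_ok)


def _strand_order_string(barrel: BarrelModel, tags, model) -> str:
    """Arrow-notation cyclic order starting at domain A beta2, toward A beta3."""
    n = len(tags)
    start = next(i for i, t in enumerate(tags) if t == ("A", "beta2"))
    nxt = tags[(start + 1) % n]
    step = 1 if nxt == ("A", "beta3") else -1

    order = [tags[(start + step * k) % n] for k in range(n)]
    strands = [barrel.sheet.strands[(start + step * k) % n] for k in range(n)]

    if model is not None:
        axis = barrel.sheet.axis
        dots = [float(np.dot(strand_direction(model, s), axis)) for s in strands]
        # report in the frame where the first strand points up
        flip = dots[0] < 0
        arrows = [
            (_ARROW_UP if (d > 0) != flip else _ARROW_DOWN) for d in dots
        ]
    else:
        arrows = [(_ARROW_UP if k % 2 == 0 else _ARROW_DOWN) for k in range(n)]

    return " ".join(
        f"{_GREEK_BETA}{label[4]}{arrow}" for (_, label), arrow in zip(order, arrows)
    )


def _termini_consistent(barrel: BarrelModel, packing: str) -> bool:
    ta_n, ta_c = termini_side(barrel.domain_a, barrel.sheet)
    tb_n, tb_c = termini_side(barrel.domain_b, barrel.sheet)
    same_a = ta_n * ta_c > 0
    same_b = tb_n * tb_c > 0
    if not (same_a and same_b):
        return False
    same_end = ta_n * tb_n > 0
    return bool(same_end) if packing == "Type-1" else bool(not same_end)
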