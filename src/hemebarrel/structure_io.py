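"""Reading and writing protein structures.

Wraps :mod:`gemmi` to turn PDB/mmCIF files into a small uniform coordinate
model: polymer residues in chain order, plus heme-like HETATM groups pulled
out into :class:`LigandGroup` records with the iron position and the
porphyrin/isobacteriochlorin macrocycle atoms identified by atom-name
convention.

Residues carry their author numbering (``auth_seq`` + insertion code) as the
public identity -- that is how the literature refers to them (His76, His299) --
while the pipeline internally uses 0-based contiguous indices into
:attr:`StructureModel.residues`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import gemmi

from .config import DEFAULT_HEME_CODES

_WATER_NAMES = {"HOH", "WAT", "DOD"}

# Macrocycle heavy atoms of a heme/siroheme group: the four pyrrole nitrogens,
# the alpha/beta pyrrole carbons and the meso carbons.  Propionates and other
# substituents are deliberately excluded from planarity analysis.
_RING_ATOM_NAMES = frozenset(
    ["NA", "NB", "NC", "ND"]
    + [f"C{ring}{pos}" for ring in "1234" for pos in ("A", "B", "C", "D")]
    + [f"C{pos}{ring}" for ring in "ABCD" for pos in ("1", "2", "3", "4")]
    + ["CHA", "CHB", "CHC", "CHD"]
)


class FormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class MissingChainError(KeyError):
    """Raised when a requested chain is absent from the model."""


@dataclass
class AtomRecord:
    name: str
    element: str
    pos: np.ndarray           # shape (3,), Angstrom
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0


@dataclass
class ResidueRecord:
    chain_id: str
    auth_seq: int
    icode: str
    name: str
    atoms: List[AtomRecord]
    is_polymer: bool = True

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.auth_seq, self.icode)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[np.ndarray]:
        a = self.atom("CA")
        return a.pos if a is not None else None

    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.auth_seq}{self.icode}".rstrip()


@dataclass
class LigandGroup:
    het_code: str
    residue: ResidueRecord
    fe_pos: Optional[np.ndarray] = None
    macrocycle_atoms: List[AtomRecord] = field(default_factory=list)


@dataclass
class StructureModel:
    id: str
    chains: List[str]
    residues: List[ResidueRecord]
    ligands: List[LigandGroup]
    model_number: int = 1

    def chain_residues(self, chain_id: str) -> List[ResidueRecord]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chain_index_range(self, chain_id: str) -> Tuple[int, int]:
        """(first, last+1) internal indices of a chain's polymer residues."""
        idx = [i for i, r in enumerate(self.residues) if r.chain_id == chain_id]
        if not idx:
            raise MissingChainError(chain_id)
        return idx[0], idx[-1] + 1

    def ca_coords(self, indices: Sequence[int]) -> np.ndarray:
        out = []
        for i in indices:
            ca = self.residues[i].ca
            if ca is None:
                raise ValueError(f"residue {self.residues[i].key} has no CA atom")
            out.append(ca)
        return np.asarray(out, dtype=float)


def _collapse_altlocs(atoms: List[AtomRecord]) -> List[AtomRecord]:
    """Keep, per atom name, the single highest-occupancy conformer."""
    best: Dict[str, AtomRecord] = {}
    order: List[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def _ligand_from_residue(res: ResidueRecord) -> LigandGroup:
    fe = None
    for a in res.atoms:
        if a.element.upper() == "FE" or a.name.strip().upper() == "FE":
            fe = a.pos
            break
    ring = [a for a in res.atoms if a.name in _RING_ATOM_NAMES]
    return LigandGroup(het_code=res.name, residue=res, fe_pos=fe, macrocycle_atoms=ring)


def load_structure(
    path: str,
    chains: Optional[Sequence[str]] = None,
    model: Optional[int] = None,
    heme_codes: Sequence[str] = DEFAULT_HEME_CODES,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only one coordinate model is retained (the first, or ``model``), waters
    are dropped, alternate locations are collapsed to the highest-occupancy
    conformer, and residues whose het code is in ``heme_codes`` become
    :class:`LigandGroup` entries instead of polymer residues.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no coordinate model")
    st.setup_entities()

    gm = None
    if model is not None:
        for m in st:
            if m.num == model:
                gm = m
                break
        if gm is None:
            raise FormatError(f"{path}: no model number {model}")
    else:
        gm = st[0]

    available = [ch.name for ch in gm]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise MissingChainError(f"chain(s) {missing} not in {available}")

    heme_set = {c.upper() for c in heme_codes}
    residues: List[ResidueRecord] = []
    ligands: List[LigandGroup] = []
    chain_order: List[str] = []
    for ch in gm:
        if chains is not None and ch.name not in chains:
            continue
        for res in ch:
            if res.name in _WATER_NAMES:
                continue
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name.upper(),
                    pos=np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                    occupancy=a.occ,
                    bfactor=a.b_iso,
                )
                for a in res
            ]
            atoms = _collapse_altlocs(atoms)
            if not atoms:
                continue
            rec = ResidueRecord(
                chain_id=ch.name,
                auth_seq=res.seqid.num,
                icode=res.seqid.icode.strip(),
                name=res.name,
                atoms=atoms,
                is_polymer=res.name.upper() not in heme_set
                and res.het_flag != "H",
            )
            if res.name.upper() in heme_set:
                rec.is_polymer = False
                ligands.append(_ligand_from_residue(rec))
            elif res.het_flag == "H" and res.name.upper() not in heme_set:
                # non-heme heterogen: keep neither as polymer nor as ligand
                continue
            else:
                residues.append(rec)
                if ch.name not in chain_order:
                    chain_order.append(ch.name)

    seen = set()
    for r in residues:
        if r.key in seen:
            raise FormatError(f"duplicate residue key {r.key}")
        seen.add(r.key)

    return StructureModel(
        id=st.name or str(path),
        chains=chain_order,
        residues=residues,
        ligands=ligands,
        model_number=gm.num,
    )


def write_structure(model: StructureModel, path: str) -> None:
    """Write the model as a PDB file (round-trips through load_structure)."""
    if not model.residues and not model.ligands:
        raise ValueError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model(model.model_number)
    chain_map: Dict[str, gemmi.Chain] = {}

    def _chain(cid: str) -> gemmi.Chain:
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        return chain_map[cid]

    def _add(res: ResidueRecord, het: bool) -> None:
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.auth_seq, res.icode or " ")
        gr.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element if a.element else a.name[0])
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            ga.b_iso = a.bfactor
            gr.add_atom(ga)
        _chain(res.chain_id).add_residue(gr)

    for res in model.residues:
        _add(res, het=False)
    for lig in model.ligands:
        _add(lig.residue, het=True)
    for cid in list(chain_map):
        gm.add_chain(chain_map[cid])
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
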