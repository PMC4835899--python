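"""Heme/siroheme site location, axial residues, binding mode and ruffling.

The proximal residue is the polymer side chain coordinating the iron
axially (His NE2/ND1, Tyr OH, Cys SG or Met SD within 3.5 A of Fe); the
distal residue is the nearest functional side chain on the opposite face
of the porphyrin plane within 6 A of Fe.  The binding mode is one of
three spatial classes: the cleft of a ferredoxin-like domain next to
alpha2 (IsdG/OxdA-like), next to alpha1 (Cld/DyP/EfeB/HemQ-like), or the
barrel cavity itself (siroheme decarboxylase-like).  Ruffling is the RMS
out-of-plane deviation of the macrocycle heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .ferredoxin_map import BarrelModel
from .sheet_topology import strand_midpoint
from .structure_io import LigandGroup, ResidueRecord, StructureModel

SITE_CLEFT_ISDG_OXDA = "SITE_CLEFT_ISDG_OXDA"
SITE_CLD_DYP = "SITE_CLD_DYP"
SITE_CAVITY = "SITE_CAVITY"

# candidate coordinating atoms per residue type
_PROXIMAL_ATOMS = {
    "HIS": ("NE2", "ND1"),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "MET": ("SD",),
}
_DISTAL_ATOMS = {
    "HIS": ("NE2", "ND1"),
    "ARG": ("NH1", "NH2", "NE"),
    "ASN": ("ND2", "OD1"),
    "SER": ("OG",),
}


@dataclass
class AxialContact:
    residue: ResidueRecord
    residue_index: int
    atom_name: str
    distance: float


@dataclass
class HemeSite:
    ligand: LigandGroup
    proximal: Optional[AxialContact] = None
    distal: Optional[AxialContact] = None
    proximal_missing: bool = False
    host_label_domain: Optional[Tuple[str, str]] = None   # (domain id, label)
    host_label_barrel: Optional[str] = None
    site_mode: Optional[str] = None
    fe_radial: Optional[float] = None
    ruffling_rms: Optional[float] = None
    ruffled: Optional[bool] = None
    diagnostics: str = ""


def _fit_plane(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points -> (centroid, unit normal)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[-1]


def _candidates(
    model: StructureModel, atom_table: Dict[str, Tuple[str, ...]]
) -> List[Tuple[int, ResidueRecord, str, np.ndarray]]:
    out = []
    for i, res in enumerate(model.residues):
        names = atom_table.get(res.name.upper())
        if not names:
            continue
        for an in names:
            a = res.atom(an)
            if a is not None:
                out.append((i, res, an, a.pos))
    return out


def find_axial_residues(
    model: StructureModel,
    ligand: LigandGroup,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Tuple[Optional[AxialContact], Optional[AxialContact]]:
    """(proximal, distal) axial contacts of the ligand's iron.

    A missing proximal within the cutoff is not an error -- disordered
    proximal helices occur -- the site is simply flagged upstream.
    """
    if ligand.fe_pos is None:
        raise ValueError(f"ligand {ligand.het_code} has no Fe position")
    fe = ligand.fe_pos

    best_prox: Optional[AxialContact] = None
    for i, res, an, pos in _candidates(model, _PROXIMAL_ATOMS):
        d = float(np.linalg.norm(pos - fe))
        if d <= config.proximal_cutoff and (best_prox is None or d < best_prox.distance):
            best_prox = AxialContact(res, i, an, d)

    best_dist: Optional[AxialContact] = None
    if len(ligand.macrocycle_atoms) >= 4:
        ring = np.array([a.pos for a in ligand.macrocycle_atoms])
        c, normal = _fit_plane(ring)
        prox_side = 0.0
        if best_prox is not None:
            prox_atom = best_prox.residue.atom(best_prox.atom_name)
            prox_side = float(np.dot(prox_atom.pos - c, normal))
        for i, res, an, pos in _candidates(model, _DISTAL_ATOMS):
            if best_prox is not None and i == best_prox.residue_index:
                continue
            d = float(np.linalg.norm(pos - fe))
            side = float(np.dot(pos - c, normal))
            opposite = prox_side == 0.0 or side * prox_side < 0
            if d <= config.distal_cutoff and opposite and (
                best_dist is None or d < best_dist.distance
            ):
                best_dist = AxialContact(res, i, an, d)

    return best_prox, best_dist


def _host_element(barrel: BarrelModel, residue_index: int):
    for name, dom in zip("AB", barrel.domains):
        for label, el in dom.elements.items():
            if el.start_idx <= residue_index <= el.end_idx:
                return (name, label), el
    return None, None


def fe_radial_distance(barrel: BarrelModel, fe: np.ndarray) -> float:
    v = fe - barrel.sheet.center
    return float(np.linalg.norm(v - np.dot(v, barrel.sheet.axis) * barrel.sheet.axis))


def classify_site(
    barrel: BarrelModel,
    site: HemeSite,
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> HemeSite:
    """Fill in host labels, radial position and the binding-site mode."""
    fe = site.ligand.fe_pos
    if fe is None:
        site.diagnostics = "no Fe position; mode undetermined"
        return site
    site.fe_radial = fe_radial_distance(barrel, fe)

    core = barrel.sheet.strands
    mean_radius = float(np.mean([
        fe_radial_distance(barrel, strand_midpoint(model, s)) for s in core
    ])) if core else float("nan")
    in_cavity = (
        np.isfinite(mean_radius) and site.fe_radial < config.cavity_margin * mean_radius
    )

    host = None
    if site.proximal is not None:
        host, el = _host_element(barrel, site.proximal.residue_index)
        site.host_label_domain = host
        if el is not None and barrel.arrangement == "fused":
            site.host_label_barrel = barrel.barrel_label_of(el)

    if in_cavity:
        site.site_mode = SITE_CAVITY
        if host is not None and host[1] not in ("beta2",):
            site.diagnostics = (
                f"Fe in barrel cavity (radial {site.fe_radial:.1f} A vs mean strand "
                f"radius {mean_radius:.1f} A) but proximal host is {host[1]}"
            )
    elif host is not None:
        label = host[1]
        if label == "alpha2":
            site.site_mode = SITE_CLEFT_ISDG_OXDA
        elif label == "alpha1":
            site.site_mode = SITE_CLD_DYP
        elif label == "beta2":
            # strand-hosted proximal with Fe outside the cavity margin:
            # report the cavity mode with both signals in the diagnostics
            site.site_mode = SITE_CAVITY
            site.diagnostics = (
                f"proximal on beta2 but Fe radial {site.fe_radial:.1f} A exceeds "
                f"cavity margin ({config.cavity_margin:.2f} x {mean_radius:.1f} A)"
            )
        else:
            site.site_mode = None
            site.diagnostics = f"proximal host {label} matches no known binding mode"
    else:
        site.site_mode = None
        site.diagnostics = "proximal absent and Fe outside barrel cavity; mode undetermined"
    return site


def ruffling_score(
    ligand: LigandGroup, config: PipelineConfig = DEFAULT_CONFIG
) -> Tuple[float, bool]:
    """RMS out-of-plane deviation of the macrocycle and the ruffled flag."""
    if len(ligand.macrocycle_atoms) < 12:
        raise ValueError(
            f"only {len(ligand.macrocycle_atoms)} macrocycle atoms; need >= 12"
        )
    pts = np.array([a.pos for a in ligand.macrocycle_atoms])
    c, normal = _fit_plane(pts)
    dev = (pts - c) @ normal
    rms = float(np.sqrt(np.mean(dev ** 2)))
    return rms, rms > config.ruffling_threshold


def analyze_heme_site(
    barrel: BarrelModel,
    ligand: LigandGroup,
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> HemeSite:
    """Full per-ligand analysis: axial residues, mode, ruffling."""
    site = HemeSite(ligand=ligand)
    if ligand.fe_pos is None:
        site.proximal_missing = True
        site.diagnostics = "ligand group has no Fe atom"
        return site
    prox, dist = find_axial_residues(model, ligand, config)
    site.proximal = prox
    site.distal = dist
    site.proximal_missing = prox is None
    site = classify_site(barrel, site, model, config)
    try:
        site.ruffling_rms, site.ruffled = ruffling_score(ligand, config)
    except ValueError:
        site.ruffling_rms, site.ruffled = None, None
    return site


def count_hemes(
    model: StructureModel,
    barrel_chains: Sequence[str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> int:
    """Heme-like groups whose Fe (or ring centroid) lies near the barrel."""
    chain_set = set(barrel_chains)
    coords = [
        a.pos for r in model.residues if r.chain_id in chain_set for a in r.atoms
    ]
    if not coords:
        return 0
    pts = np.array(coords)
    n = 0
    for lig in model.ligands:
        if lig.fe_pos is not None:
            ref = lig.fe_pos
        elif lig.macrocycle_atoms:
            ref = np.mean([a.pos for a in lig.macrocycle_atoms], axis=0)
        else:
            ref = lig.residue.atoms[0].pos
        if float(np.linalg.norm(pts - ref, axis=1).min()) <= config.heme_near_chain:
            n += 1
    return n
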