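"""Machine-readable pipeline reports.

`run_classify` executes the full per-structure pipeline (parse -> secondary
structure -> pairing graph -> barrel sheet -> domain labels -> packing type
-> heme sites -> internal domain correspondence) and returns a serializable
:class:`BarrelReport`.  `run_compare` superposes two (possibly isolated)
domains under all candidate correspondences.  Every classification carries
its evidence (pair lists, distances, diagnostics), and every report embeds
the effective configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .barrel_classify import PackingCall, classify_packing
from .config import PipelineConfig, DEFAULT_CONFIG
from .ferredoxin_map import (
    BarrelModel,
    FerredoxinDomain,
    map_domains,
    map_isolated_domain,
    termini_side,
)
from .heme_analysis import HemeSite, analyze_heme_site, count_hemes
from .secondary_structure import accept_annotation, assign_ss, detect_hbonds
from .sheet_topology import build_barrel_sheet, pair_strands
from .structure_io import StructureModel, load_structure
from .superpose import DomainCorrespondence, align_domains

SCHEMA_VERSION = "1.0"


class StageError(RuntimeError):
    """Pipeline failure wrapped with the name of the failing stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class BarrelReport:
    structure_id: str
    chains: List[str]
    arrangement: Optional[str] = None
    packing: Optional[PackingCall] = None
    termini: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    heme_sites: List[HemeSite] = field(default_factory=list)
    heme_count: int = 0
    correspondences: List[DomainCorrespondence] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    config: Dict = field(default_factory=dict)
    barrel: Optional[BarrelModel] = None      # not serialized; for callers

    def to_dict(self) -> dict:
        def _axial(site: HemeSite, which: str) -> Optional[dict]:
            c = getattr(site, which)
            if c is None:
                return None
            return {
                "chain": c.residue.chain_id,
                "auth_seq": c.residue.auth_seq,
                "name": c.residue.name,
                "atom": c.atom_name,
                "distance": round(c.distance, 3),
            }

        return {
            "schema_version": SCHEMA_VERSION,
            "structure_id": self.structure_id,
            "chains": self.chains,
            "arrangement": self.arrangement,
            "packing": None if self.packing is None else {
                "packing": self.packing.packing,
                "inter_domain_pairs": [list(p) for p in self.packing.inter_domain_pairs],
                "strand_order": self.packing.strand_order_string,
                "termini_consistent": self.packing.termini_consistent,
                "diagnostics": self.packing.diagnostics,
            },
            "termini_axial": {k: [round(v[0], 2), round(v[1], 2)]
                              for k, v in self.termini.items()},
            "heme_count": self.heme_count,
            "heme_sites": [
                {
                    "het_code": s.ligand.het_code,
                    "proximal": _axial(s, "proximal"),
                    "proximal_missing": s.proximal_missing,
                    "distal": _axial(s, "distal"),
                    "host_label_domain": list(s.host_label_domain)
                    if s.host_label_domain else None,
                    "host_label_barrel": s.host_label_barrel,
                    "site_mode": s.site_mode,
                    "fe_radial": None if s.fe_radial is None else round(s.fe_radial, 2),
                    "ruffling_rms": None if s.ruffling_rms is None
                    else round(s.ruffling_rms, 4),
                    "ruffled": s.ruffled,
                    "diagnostics": s.diagnostics,
                }
                for s in self.heme_sites
            ],
            "correspondences": [_corr_dict(c) for c in self.correspondences],
            "warnings": self.warnings,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _corr_dict(c: DomainCorrespondence) -> dict:
    return {
        "mapping_kind": c.mapping_kind,
        "element_map": c.element_map,
        "rmsd": round(c.rmsd, 4),
        "n_pairs": c.n_pairs,
        "n_scored": c.n_scored,
        "rotation_angle_deg": round(c.rotation_angle_deg, 1),
        "winner": c.is_winner,
    }


def _load_annotation(path_or_dict) -> Dict[str, str]:
    if isinstance(path_or_dict, dict):
        ann = path_or_dict
    else:
        with open(path_or_dict) as fh:
            ann = json.load(fh)
    if "ss" in ann and isinstance(ann["ss"], dict):
        ann = ann["ss"]   # ground-truth sidecar format
    return {str(k): str(v) for k, v in ann.items()}


def run_classify(
    path: str,
    chains: Optional[Sequence[str]] = None,
    ligand_codes: Optional[Sequence[str]] = None,
    annotation=None,
    config: PipelineConfig = DEFAULT_CONFIG,
    model: Optional[StructureModel] = None,
) -> BarrelReport:
    """Full pipeline on one structure file (or a pre-built model)."""
    warnings: List[str] = []
    try:
        if model is None:
            kw = {} if ligand_codes is None else {"heme_codes": tuple(ligand_codes)}
            model = load_structure(path, chains=chains, **kw)
    except Exception as exc:
        raise StageError("structure_io", exc) from exc

    report = BarrelReport(
        structure_id=model.id,
        chains=list(model.chains),
        config=config.to_dict(),
    )

    try:
        if annotation is not None:
            elements = accept_annotation(model, _load_annotation(annotation), config)
            hbonds = None
        else:
            hbonds = detect_hbonds(model, config)
            elements = assign_ss(model, hbonds, config)
    except Exception as exc:
        raise StageError("secondary_structure", exc) from exc

    try:
        pairs = pair_strands(elements, hbonds, model, config)
        sheet = build_barrel_sheet(pairs, model, config)
    except Exception as exc:
        raise StageError("sheet_topology", exc) from exc
    if not sheet.closed:
        warnings.append(f"sheet not closed: {sheet.diagnostics}")

    try:
        barrel = map_domains(elements, sheet, model, config)
    except Exception as exc:
        raise StageError("ferredoxin_map", exc) from exc
    report.barrel = barrel
    report.arrangement = barrel.arrangement
    for name, dom in zip("AB", barrel.domains):
        if dom.missing_labels:
            warnings.append(
                f"domain {name}: missing element(s) {list(dom.missing_labels)}"
            )
        report.termini[name] = termini_side(dom, sheet)

    report.packing = classify_packing(barrel, model)
    if report.packing.packing == "unclassified":
        warnings.append(f"packing unclassified: {report.packing.diagnostics}")

    try:
        report.heme_count = count_hemes(model, model.chains, config)
        for lig in model.ligands:
            report.heme_sites.append(analyze_heme_site(barrel, lig, model, config))
    except Exception as exc:
        raise StageError("heme_analysis", exc) from exc

    try:
        _, all_cands = align_domains(
            barrel.domain_a, barrel.domain_b, model, model, config=config
        )
        report.correspondences = all_cands
    except Exception as exc:
        warnings.append(f"domain correspondence failed: {exc}")

    report.warnings = warnings
    return report


def _domain_for_compare(
    path: str,
    chain: Optional[str],
    annotation,
    domain_select: str,
    config: PipelineConfig,
    model: Optional[StructureModel] = None,
) -> Tuple[FerredoxinDomain, StructureModel]:
    if model is None:
        model = load_structure(path, chains=[chain] if chain else None)
    if annotation is not None:
        elements = accept_annotation(model, _load_annotation(annotation), config)
        hbonds = None
    else:
        hbonds = detect_hbonds(model, config)
        elements = assign_ss(model, hbonds, config)

    n_strands = sum(1 for e in elements if e.kind == "strand")
    if n_strands >= 8:
        pairs = pair_strands(elements, hbonds, model, config)
        sheet = build_barrel_sheet(pairs, model, config)
        barrel = map_domains(elements, sheet, model, config)
        dom = barrel.domain_a if domain_select in ("A", "1", "auto") else barrel.domain_b
    else:
        dom = map_isolated_domain(elements, model, chain)
    return dom, model


def run_compare(
    path_a: str,
    path_b: str,
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
    annotation_a=None,
    annotation_b=None,
    domain_a: str = "auto",
    domain_b: str = "auto",
    config: PipelineConfig = DEFAULT_CONFIG,
    model_a: Optional[StructureModel] = None,
    model_b: Optional[StructureModel] = None,
) -> dict:
    """Superpose two domains under all candidate correspondences."""
    da, ma = _domain_for_compare(path_a, chain_a, annotation_a, domain_a, config,
                                 model_a)
    db, mb = _domain_for_compare(path_b, chain_b, annotation_b, domain_b, config,
                                 model_b)
    best, candidates = align_domains(da, db, ma, mb, config=config)
    return {
        "schema_version": SCHEMA_VERSION,
        "a": {"structure_id": ma.id, "chain": da.chain_id,
              "span": list(da.seq_span)},
        "b": {"structure_id": mb.id, "chain": db.chain_id,
              "span": list(db.seq_span)},
        "winner": _corr_dict(best),
        "candidates": [_corr_dict(c) for c in candidates],
        "config": config.to_dict(),
    }


def summarize(report: BarrelReport) -> str:
    """Human-readable one-screen summary."""
    lines = [f"structure : {report.structure_id}  chains {','.join(report.chains)}"]
    lines.append(f"arrangement: {report.arrangement}")
    if report.packing is not None:
        lines.append(f"packing    : {report.packing.packing}")
        if report.packing.strand_order_string:
            lines.append(f"order      : {report.packing.strand_order_string}")
        lines.append(f"termini ok : {report.packing.termini_consistent}")
    lines.append(f"hemes      : {report.heme_count}")
    for s in report.heme_sites:
        prox = (
            f"{s.proximal.residue.label()}:{s.proximal.atom_name}"
            f" @{s.proximal.distance:.2f}A" if s.proximal else "absent"
        )
        ruff = "n/a" if s.ruffling_rms is None else f"{s.ruffling_rms:.3f}A"
        lines.append(
            f"  {s.ligand.het_code}: mode={s.site_mode} proximal={prox} "
            f"host={s.host_label_domain} ruffling={ruff}"
        )
    for c in report.correspondences:
        flag = "*" if c.is_winner else " "
        lines.append(
            f"  map {flag}{c.mapping_kind:<16} rmsd={c.rmsd:5.2f}A "
            f"pairs={c.n_pairs:3d} angle={c.rotation_angle_deg:5.1f}"
        )
    for w in report.warnings:
        lines.append(f"warning    : {w}")
    return "\n".join(lines)
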