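"""Pipeline configuration.

All geometric thresholds used across the pipeline live here so that a
report can embed the exact configuration it was produced with.  Values
are defaults of the implementation; none of them is prescribed by the
underlying structural families themselves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

# Het codes treated as heme-like ligand groups (heme b/c variants and
# siroheme).  Siroheme het codes vary between entries, hence configurable.
DEFAULT_HEME_CODES = ("HEM", "HEC", "HEB", "SRM", "SHH")


@dataclass
class PipelineConfig:
    # --- ligand extraction -------------------------------------------------
    heme_codes: tuple = DEFAULT_HEME_CODES

    # --- hydrogen bonds / secondary structure ------------------------------
    hbond_energy_cutoff: float = -0.5   # kcal/mol, Kabsch-Sander style energy
    min_strand_len: int = 3             # residues
    min_helix_len: int = 4              # residues

    # --- strand pairing ----------------------------------------------------
    min_pair_hbonds: int = 2            # backbone H-bonds per strand pair
    contact_cutoff: float = 5.5         # Angstrom, CA-CA, annotation mode
    min_pair_contacts: int = 3          # contacts per strand pair, annotation mode

    # --- domain mapping ----------------------------------------------------
    homodimer_identity: float = 0.95    # residue-name identity above which two
                                        # chains count as the same gene product

    # --- superposition -----------------------------------------------------
    pair_distance: float = 4.5          # Angstrom, re-pairing radius
    score_distance: float = 4.0         # Angstrom, pair counts toward score
    max_refine_iter: int = 10

    # --- heme geometry -----------------------------------------------------
    proximal_cutoff: float = 3.5        # Angstrom, axial Fe-ligand distance
    distal_cutoff: float = 6.0          # Angstrom, distal shell around Fe
    ruffling_threshold: float = 0.25    # Angstrom, RMS out-of-plane deviation
    cavity_margin: float = 0.75         # Fe counts as in-cavity below this
                                        # fraction of the mean strand radius
    heme_near_chain: float = 15.0       # Angstrom, ligand-to-barrel assignment

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["heme_codes"] = list(self.heme_codes)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "heme_codes" in raw:
            raw["heme_codes"] = tuple(raw["heme_codes"])
        return cls(**raw)


DEFAULT_CONFIG = PipelineConfig()
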