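"""Structure quality control: backbone dihedrals, Ramachandran-region
summary and an RMSD acceptability gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from ._data import read_tsv_rows
from .structure import Structure, backbone_dihedrals, superpose_rmsd

__all__ = [
    "RamachandranSummary",
    "phi_psi",
    "ramachandran_summary",
    "rmsd_gate",
]

REGIONS = ("favored", "allowed", "generous", "disallowed")
_TIER_NAME = {"core": "favored", "allowed": "allowed", "generous": "generous"}


@lru_cache(maxsize=None)
def _region_boxes() -> dict[str, list[tuple[str, float, float, float, float]]]:
    out: dict[str, list] = {"general": [], "glycine": []}
    for mp, tier, phi_min, phi_max, psi_min, psi_max in read_tsv_rows("rama_regions.tsv")[1:]:
        out[mp].append(
            (_TIER_NAME[tier], float(phi_min), float(phi_max), float(psi_min), float(psi_max))
        )
    return out


def classify_region(phi: float, psi: float, aa: str = "A") -> str:
    """Four-tier Ramachandran region of a (phi, psi) pair; glycine uses its
    own (symmetric) region map."""
    boxes = _region_boxes()["glycine" if aa == "G" else "general"]
    best = "disallowed"
    order = {r: i for i, r in enumerate(REGIONS)}
    for tier, phi_min, phi_max, psi_min, psi_max in boxes:
        if phi_min <= phi <= phi_max and psi_min <= psi <= psi_max:
            if order[tier] < order[best]:
                best = tier
    return best


def phi_psi(s: Structure) -> dict[tuple[str, int], tuple[float | None, float | None]]:
    """Backbone (phi, psi) per residue; chain termini have None entries."""
    out = {}
    for cid, residues in s.chains.items():
        for res, (phi, psi) in zip(residues, backbone_dihedrals(residues)):
            out[(cid, res.resnum)] = (phi, psi)
    return out


@dataclass
class RamachandranSummary:
    dihedrals: dict[tuple[str, int], tuple[float | None, float | None]]
    regions: dict[tuple[str, int], str]  # includes "undefined"
    fractions: dict[str, float]  # over defined residues
    n_defined: int

    @property
    def allowed_or_better(self) -> float:
        return self.fractions["favored"] + self.fractions["allowed"]


def ramachandran_summary(s: Structure) -> RamachandranSummary:
    """Region classification for every residue with defined phi and psi,
    with region fractions over the defined residues.  The headline QC
    number is ``allowed_or_better`` (favored + allowed)."""
    dihedrals = phi_psi(s)
    regions: dict[tuple[str, int], str] = {}
    counts = {r: 0 for r in REGIONS}
    n_defined = 0
    for cid, residues in s.chains.items():
        for res in residues:
            phi, psi = dihedrals[(cid, res.resnum)]
            if phi is None or psi is None:
                regions[(cid, res.resnum)] = "undefined"
                continue
            region = classify_region(phi, psi, res.aa)
            regions[(cid, res.resnum)] = region
            counts[region] += 1
            n_defined += 1
    if n_defined == 0:
        fractions = {r: 0.0 for r in REGIONS}
    else:
        fractions = {r: counts[r] / n_defined for r in REGIONS}
    return RamachandranSummary(dihedrals, regions, fractions, n_defined)


def rmsd_gate(
    model: Structure,
    reference: Structure,
    cutoff: float = 2.8,
    atom_selection: str = "backbone",
) -> tuple[bool, float]:
    """Kabsch-superposed RMSD against a reference, gated at ``cutoff`` (A).

    Returns (passed, rmsd); passes iff rmsd <= cutoff.
    """
    value = superpose_rmsd(model, reference, atom_selection)
    return value <= cutoff, value
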