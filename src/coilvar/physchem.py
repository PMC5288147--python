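"""Three-axis physico-chemical classification of amino acids.

Each residue has a fixed profile on three categorical axes: structural class
(aliphatic / aromatic / polar / special), hydropathy (hydrophobic /
hydrophilic) and charge (positive / negative / neutral).  The canonical
table is chemically standard; a small override layer reproduces the literal
labels of the published variant table where it deviates (tyrosine, proline,
cysteine) so that published strings can be regenerated verbatim without
polluting the canonical chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from ._data import read_tsv_rows

__all__ = ["PhysChemProfile", "PropertyChange", "profile", "diff_profiles", "literal_label"]

AXES = ("structural_class", "hydropathy", "charge")


@dataclass(frozen=True)
class PhysChemProfile:
    residue: str
    structural_class: str
    hydropathy: str
    charge: str


@dataclass(frozen=True)
class PropertyChange:
    wt_profile: PhysChemProfile
    mut_profile: PhysChemProfile
    changed_axes: frozenset[str]

    def __post_init__(self):
        same = all(
            getattr(self.wt_profile, ax) == getattr(self.mut_profile, ax) for ax in AXES
        )
        if same != (not self.changed_axes):
            raise ValueError("changed_axes inconsistent with profiles")


@lru_cache(maxsize=None)
def _profiles() -> dict[str, PhysChemProfile]:
    rows = read_tsv_rows("physchem_profiles.tsv")
    assert rows[0] == ["residue", "structural_class", "hydropathy", "charge"]
    return {r[0]: PhysChemProfile(*r) for r in rows[1:]}


@lru_cache(maxsize=None)
def _literal_overrides() -> dict[str, str]:
    rows = read_tsv_rows("physchem_overrides.tsv")
    return {r[0]: r[1] for r in rows[1:]}


def profile(aa: str) -> PhysChemProfile:
    """Canonical profile of a standard one-letter residue code."""
    try:
        return _profiles()[aa]
    except KeyError:
        raise ValueError(f"unknown residue code {aa!r}") from None


def diff_profiles(wt: str, mut: str) -> PropertyChange:
    """Profile difference; ``changed_axes`` lists exactly the differing axes."""
    pw, pm = profile(wt), profile(mut)
    changed = frozenset(ax for ax in AXES if getattr(pw, ax) != getattr(pm, ax))
    return PropertyChange(pw, pm, changed)


_CHARGE_LABEL = {"positive": "Charged(+)", "negative": "Charged(-)", "neutral": "Neutral"}


def literal_label(aa: str) -> str:
    """Published-table style label, e.g. ``Polar, Hydrophilic, Charged(-)``.

    Residues in the override table return the published literal instead of
    the canonical rendering.
    """
    over = _literal_overrides()
    if aa in over:
        return over[aa]
    p = profile(aa)
    return f"{p.structural_class.capitalize()}, {p.hydropathy.capitalize()}, {_CHARGE_LABEL[p.charge]}"
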