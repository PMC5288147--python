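"""Side-chain topology, ideal internal coordinates and chi angles (internal).

Side chains are described as a construction tree: every heavy atom is placed
by a NeRF step from three previously placed atoms.  Bond lengths, bond angles
and all non-rotatable torsions are measured once from the ideal residue
templates bundled with biotite (chemical component dictionary), which also
fixes the correct L-chirality of the CB branch.  Rotatable torsions are the
free chi angles supplied by the caller (typically from the rotamer library).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .geometry import angle, dihedral, place_atom

__all__ = [
    "CHI_ATOMS",
    "N_CHI",
    "SIDECHAIN_ATOMS",
    "aa1to3",
    "aa3to1",
    "build_side_chain",
    "measure_chis",
    "residue_bonds",
]

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}

STANDARD_AAS = frozenset(AA3)


def aa1to3(aa: str) -> str:
    try:
        return AA3[aa]
    except KeyError:
        raise ValueError(f"not a standard one-letter amino acid code: {aa!r}") from None


def aa3to1(aa: str) -> str:
    try:
        return AA1[aa.upper()]
    except KeyError:
        raise ValueError(f"not a standard three-letter amino acid code: {aa!r}") from None


# Number of rotatable chi dihedrals per residue.  Proline's ring is built
# with fixed template torsions and contributes no free chi.
N_CHI = {
    "A": 0, "G": 0, "P": 0,
    "S": 1, "C": 1, "T": 1, "V": 1,
    "D": 2, "N": 2, "H": 2, "I": 2, "L": 2, "F": 2, "W": 2, "Y": 2,
    "E": 3, "Q": 3, "M": 3,
    "K": 4, "R": 4,
}

# Atom quadruples defining each chi dihedral (standard convention).
CHI_ATOMS = {
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
    "A": [], "G": [], "P": [],
}

# Construction tree: (atom, (ref_a, ref_b, ref_c), torsion_spec).
# torsion_spec: ("fix",)               -> template torsion
#               ("chi", k)             -> chi_k (1-based)
#               ("branch", k, primary) -> chi_k + template offset vs. primary
_CB = ("CB", ("C", "N", "CA"), ("fix",))

_TREES = {
    "A": [_CB],
    "G": [],
    "S": [_CB, ("OG", ("N", "CA", "CB"), ("chi", 1))],
    "C": [_CB, ("SG", ("N", "CA", "CB"), ("chi", 1))],
    "T": [_CB, ("OG1", ("N", "CA", "CB"), ("chi", 1)),
          ("CG2", ("N", "CA", "CB"), ("branch", 1, "OG1"))],
    "V": [_CB, ("CG1", ("N", "CA", "CB"), ("chi", 1)),
          ("CG2", ("N", "CA", "CB"), ("branch", 1, "CG1"))],
    "L": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("CD1", ("CA", "CB", "CG"), ("chi", 2)),
          ("CD2", ("CA", "CB", "CG"), ("branch", 2, "CD1"))],
    "I": [_CB, ("CG1", ("N", "CA", "CB"), ("chi", 1)),
          ("CG2", ("N", "CA", "CB"), ("branch", 1, "CG1")),
          ("CD1", ("CA", "CB", "CG1"), ("chi", 2))],
    "M": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("SD", ("CA", "CB", "CG"), ("chi", 2)),
          ("CE", ("CB", "CG", "SD"), ("chi", 3))],
    "P": [_CB, ("CG", ("N", "CA", "CB"), ("fix",)),
          ("CD", ("CA", "CB", "CG"), ("fix",))],
    "D": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("OD1", ("CA", "CB", "CG"), ("chi", 2)),
          ("OD2", ("CA", "CB", "CG"), ("branch", 2, "OD1"))],
    "N": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("OD1", ("CA", "CB", "CG"), ("chi", 2)),
          ("ND2", ("CA", "CB", "CG"), ("branch", 2, "OD1"))],
    "E": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("CD", ("CA", "CB", "CG"), ("chi", 2)),
          ("OE1", ("CB", "CG", "CD"), ("chi", 3)),
          ("OE2", ("CB", "CG", "CD"), ("branch", 3, "OE1"))],
    "Q": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("CD", ("CA", "CB", "CG"), ("chi", 2)),
          ("OE1", ("CB", "CG", "CD"), ("chi", 3)),
          ("NE2", ("CB", "CG", "CD"), ("branch", 3, "OE1"))],
    "K": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("CD", ("CA", "CB", "CG"), ("chi", 2)),
          ("CE", ("CB", "CG", "CD"), ("chi", 3)),
          ("NZ", ("CG", "CD", "CE"), ("chi", 4))],
    "R": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("CD", ("CA", "CB", "CG"), ("chi", 2)),
          ("NE", ("CB", "CG", "CD"), ("chi", 3)),
          ("CZ", ("CG", "CD", "NE"), ("chi", 4)),
          ("NH1", ("CD", "NE", "CZ"), ("fix",)),
          ("NH2", ("CD", "NE", "CZ"), ("fix",))],
    "H": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("ND1", ("CA", "CB", "CG"), ("chi", 2)),
          ("CD2", ("CA", "CB", "CG"), ("branch", 2, "ND1")),
          ("CE1", ("CB", "CG", "ND1"), ("fix",)),
          ("NE2", ("CB", "CG", "CD2"), ("fix",))],
    "F": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("CD1", ("CA", "CB", "CG"), ("chi", 2)),
          ("CD2", ("CA", "CB", "CG"), ("branch", 2, "CD1")),
          ("CE1", ("CB", "CG", "CD1"), ("fix",)),
          ("CE2", ("CB", "CG", "CD2"), ("fix",)),
          ("CZ", ("CG", "CD1", "CE1"), ("fix",))],
    "W": [_CB, ("CG", ("N", "CA", "CB"), ("chi", 1)),
          ("CD1", ("CA", "CB", "CG"), ("chi", 2)),
          ("CD2", ("CA", "CB", "CG"), ("branch", 2, "CD1")),
          ("NE1", ("CB", "CG", "CD1"), ("fix",)),
          ("CE2", ("CB", "CG", "CD2"), ("fix",)),
          ("CE3", ("CB", "CG", "CD2"), ("fix",)),
          ("CZ2", ("CG", "CD2", "CE2"), ("fix",)),
          ("CZ3", ("CG", "CD2", "CE3"), ("fix",)),
          ("CH2", ("CD2", "CE3", "CZ3"), ("fix",))],
}
_TREES["Y"] = _TREES["F"] + [("OH", ("CD1", "CE1", "CZ"), ("fix",))]

SIDECHAIN_ATOMS = {aa: tuple(e[0] for e in tree) for aa, tree in _TREES.items()}

# Ring-closure / cyclic bonds not implied by the construction tree.
_EXTRA_BONDS = {
    "P": [("CD", "N")],
    "F": [("CZ", "CE2")],
    "Y": [("CZ", "CE2")],
    "H": [("CE1", "NE2")],
    "W": [("NE1", "CE2"), ("CH2", "CZ2")],
}


@lru_cache(maxsize=None)
def _template_coords(aa: str) -> dict[str, np.ndarray]:
    from biotite.structure.info import residue as ccd_residue

    arr = ccd_residue(aa1to3(aa))
    return {
        name: arr.coord[arr.atom_name == name][0].astype(float)
        for name in set(arr.atom_name)
    }


@lru_cache(maxsize=None)
def _internal_coords(aa: str):
    """Per construction-tree entry: (atom, refs, spec, bond, angle, torsion)."""
    tmpl = _template_coords(aa)
    out = []
    for name, (a, b, c), spec in _TREES[aa]:
        pa, pb, pc, pd = tmpl[a], tmpl[b], tmpl[c], tmpl[name]
        bond = float(np.linalg.norm(pd - pc))
        ang = angle(pb, pc, pd)
        tor = dihedral(pa, pb, pc, pd)
        if spec[0] == "branch":
            _, k, primary = spec
            tor -= dihedral(pa, pb, pc, tmpl[primary])
        out.append((name, (a, b, c), spec, bond, ang, tor))
    return tuple(out)


def build_side_chain(
    backbone: dict[str, np.ndarray], aa: str, chis: tuple[float, ...] = ()
) -> dict[str, np.ndarray]:
    """Construct ideal side-chain coordinates (including CB) for ``aa``.

    ``backbone`` must provide N, CA and C coordinates.  ``chis`` supplies the
    rotatable dihedrals in degrees; missing values default to the template's.
    """
    if aa not in _TREES:
        raise ValueError(f"not a standard amino acid: {aa!r}")
    for req in ("N", "CA", "C"):
        if req not in backbone:
            raise ValueError(f"backbone atom {req} required to build side chain")
    coords: dict[str, np.ndarray] = {
        "N": np.asarray(backbone["N"], float),
        "CA": np.asarray(backbone["CA"], float),
        "C": np.asarray(backbone["C"], float),
    }
    placed: dict[str, np.ndarray] = {}
    for name, (a, b, c), spec, bond, ang, tor in _internal_coords(aa):
        if spec[0] == "chi":
            k = spec[1]
            torsion = chis[k - 1] if k <= len(chis) else tor
        elif spec[0] == "branch":
            k = spec[1]
            base = chis[k - 1] if k <= len(chis) else 0.0
            torsion = base + tor
        else:
            torsion = tor
        pos = place_atom(coords[a], coords[b], coords[c], bond, ang, torsion)
        coords[name] = pos
        placed[name] = pos
    return placed


def measure_chis(coords: dict[str, np.ndarray], aa: str) -> list[float]:
    """Measure the chi dihedrals of a residue from its atom coordinates."""
    out = []
    for quad in CHI_ATOMS[aa]:
        try:
            pts = [coords[n] for n in quad]
        except KeyError as exc:
            raise ValueError(f"missing atom {exc} for chi measurement of {aa}") from None
        out.append(dihedral(*pts))
    return out


@lru_cache(maxsize=None)
def residue_bonds(aa: str) -> frozenset[tuple[str, str]]:
    """Heavy-atom bonds within one residue (unordered name pairs)."""
    bonds = {("N", "CA"), ("CA", "C"), ("C", "O")}
    for name, (_, _, c), _spec in _TREES[aa]:
        bonds.add((c, name))
    bonds.update(_EXTRA_BONDS.get(aa, ()))
    return frozenset(tuple(sorted(b)) for b in bonds)
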