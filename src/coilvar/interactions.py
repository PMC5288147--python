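"""Geometric detection of inter-residue interactions from 3D coordinates.

Detectors cover hydrogen bonds (heavy-atom donor-acceptor distance plus an
acceptor-donor-antecedent angle fallback for hydrogen-free models),
hydrophobic contacts (apolar carbon pairs), salt bridges (opposite-charge
group atoms) and aromatic ring-centroid interactions.  All thresholds live
in :class:`InteractionCriteria`; detectors are pure functions of the
coordinates and are invariant under rigid-body motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from ._data import read_tsv_rows
from .geometry import angle
from .structure import Residue, Structure

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_salt_bridges",
    "detect_aromatic",
    "detect_all",
    "partner_map",
]

MAINCHAIN = {"N", "CA", "C", "O"}

_AROMATIC_RINGS = {
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "W": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class InteractionCriteria:
    hbond_max_da: float = 3.5
    hbond_min_angle: float = 120.0
    hydrophobic_max_cc: float = 4.5
    saltbridge_max: float = 4.0
    aromatic_max_centroid: float = 6.0
    aromatic_polar_max: float = 4.5
    enable_aromatic_polar: bool = False
    include_mainchain_mainchain: bool = False
    include_his_saltbridge: bool = False
    min_sequence_separation: int = 2  # same-chain |i-j| below this is skipped

    def __post_init__(self):
        for name in ("hbond_max_da", "hydrophobic_max_cc", "saltbridge_max", "aromatic_max_centroid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InteractionRecord:
    kind: str
    residue_i: tuple[str, int, str]  # chain, resnum, aa
    residue_j: tuple[str, int, str]
    atoms: tuple[str, str]
    distance: float
    angle: float | None
    chain_relation: str  # inter | intra

    def key(self):
        return (self.kind, self.residue_i[:2], self.residue_j[:2], self.atoms)


@lru_cache(maxsize=None)
def _hbond_tables():
    donors: dict[tuple[str, str], str] = {}
    acceptors: set[tuple[str, str]] = set()
    for aa, atom, role, ant in read_tsv_rows("hbond_atoms.tsv")[1:]:
        if role in ("donor", "both"):
            donors[(aa, atom)] = ant
        if role in ("acceptor", "both"):
            acceptors.add((aa, atom))
    return donors, acceptors


@lru_cache(maxsize=None)
def _apolar_table() -> dict[str, frozenset[str]]:
    out = {}
    for row in read_tsv_rows("apolar_atoms.tsv")[1:]:
        aa = row[0]
        atoms = row[1].split("|") if len(row) > 1 and row[1] else []
        out[aa] = frozenset(atoms)
    return out


@lru_cache(maxsize=None)
def _charged_table() -> dict[tuple[str, str], str]:
    return {(aa, atom): sign for aa, atom, sign in read_tsv_rows("charged_atoms.tsv")[1:]}


def _entries(s: Structure):
    entries = [(res, atom) for res, atom in s.atoms()]
    coords = np.array([a.coords for _, a in entries])
    return entries, coords


def _pair_ok(res_i: Residue, res_j: Residue, c: InteractionCriteria) -> bool:
    if res_i.chain_id == res_j.chain_id:
        return abs(res_i.resnum - res_j.resnum) >= c.min_sequence_separation
    return True


def _ordered(res_i, name_i, res_j, name_j):
    ki = (res_i.chain_id, res_i.resnum)
    kj = (res_j.chain_id, res_j.resnum)
    if kj < ki:
        return res_j, name_j, res_i, name_i
    return res_i, name_i, res_j, name_j


def _relation(res_i: Residue, res_j: Residue) -> str:
    return "intra" if res_i.chain_id == res_j.chain_id else "inter"


def detect_hbonds(s: Structure, c: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """Hydrogen bonds as donor-acceptor heavy-atom pairs within
    ``hbond_max_da`` whose acceptor-donor-antecedent angle (hydrogen-free
    criterion) is at least ``hbond_min_angle``.
    """
    c = c or InteractionCriteria()
    donors, acceptors = _hbond_tables()
    entries, coords = _entries(s)
    tree = cKDTree(coords)
    records = []
    for i, j in sorted(tree.query_pairs(c.hbond_max_da)):
        res_i, atom_i = entries[i]
        res_j, atom_j = entries[j]
        if res_i is res_j or not _pair_ok(res_i, res_j, c):
            continue
        for (dres, datom), (ares, aatom) in (
            ((res_i, atom_i), (res_j, atom_j)),
            ((res_j, atom_j), (res_i, atom_i)),
        ):
            if datom.name == "N":
                antecedent = "CA"
            elif (dres.aa, datom.name) in donors:
                antecedent = donors[(dres.aa, datom.name)]
            else:
                continue
            if aatom.name != "O" and (ares.aa, aatom.name) not in acceptors:
                continue
            both_mainchain = datom.name in MAINCHAIN and aatom.name in MAINCHAIN
            if both_mainchain and not c.include_mainchain_mainchain:
                continue
            if antecedent not in dres.atoms:
                continue
            theta = angle(aatom.coords, datom.coords, dres.coord(antecedent))
            if theta < c.hbond_min_angle:
                continue
            d = float(np.linalg.norm(datom.coords - aatom.coords))
            ri, ni, rj, nj = _ordered(dres, datom.name, ares, aatom.name)
            records.append(
                InteractionRecord(
                    "hbond",
                    (ri.chain_id, ri.resnum, ri.aa),
                    (rj.chain_id, rj.resnum, rj.aa),
                    (ni, nj),
                    round(d, 6),
                    round(theta, 6),
                    _relation(dres, ares),
                )
            )
    return sorted(set(records), key=lambda r: r.key())


def detect_hydrophobic(s: Structure, c: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """Hydrophobic contacts: one record per residue pair with at least one
    apolar side-chain atom pair within ``hydrophobic_max_cc`` (closest pair
    reported).
    """
    c = c or InteractionCriteria()
    apolar = _apolar_table()
    entries, coords = _entries(s)
    tree = cKDTree(coords)
    best: dict[tuple, tuple[float, str, str, Residue, Residue]] = {}
    for i, j in tree.query_pairs(c.hydrophobic_max_cc):
        res_i, atom_i = entries[i]
        res_j, atom_j = entries[j]
        if res_i is res_j or not _pair_ok(res_i, res_j, c):
            continue
        if atom_i.name not in apolar[res_i.aa] or atom_j.name not in apolar[res_j.aa]:
            continue
        d = float(np.linalg.norm(atom_i.coords - atom_j.coords))
        ri, ni, rj, nj = _ordered(res_i, atom_i.name, res_j, atom_j.name)
        key = ((ri.chain_id, ri.resnum), (rj.chain_id, rj.resnum))
        if key not in best or d < best[key][0]:
            best[key] = (d, ni, nj, ri, rj)
    records = [
        InteractionRecord(
            "hydrophobic",
            (ri.chain_id, ri.resnum, ri.aa),
            (rj.chain_id, rj.resnum, rj.aa),
            (ni, nj),
            round(d, 6),
            None,
            _relation(ri, rj),
        )
        for d, ni, nj, ri, rj in best.values()
    ]
    return sorted(records, key=lambda r: r.key())


def detect_salt_bridges(s: Structure, c: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """Salt bridges: opposite-charge group atoms within ``saltbridge_max``
    (one record per residue pair, closest atom pair reported).
    """
    c = c or InteractionCriteria()
    charged = _charged_table()
    entries, coords = _entries(s)
    tree = cKDTree(coords)

    def sign_of(res, name):
        sg = charged.get((res.aa, name))
        if sg == "+h":
            return "+" if c.include_his_saltbridge else None
        return sg

    best: dict[tuple, tuple[float, str, str, Residue, Residue]] = {}
    for i, j in tree.query_pairs(c.saltbridge_max):
        res_i, atom_i = entries[i]
        res_j, atom_j = entries[j]
        if res_i is res_j or not _pair_ok(res_i, res_j, c):
            continue
        si = sign_of(res_i, atom_i.name)
        sj = sign_of(res_j, atom_j.name)
        if si is None or sj is None or si == sj:
            continue
        d = float(np.linalg.norm(atom_i.coords - atom_j.coords))
        ri, ni, rj, nj = _ordered(res_i, atom_i.name, res_j, atom_j.name)
        key = ((ri.chain_id, ri.resnum), (rj.chain_id, rj.resnum))
        if key not in best or d < best[key][0]:
            best[key] = (d, ni, nj, ri, rj)
    records = [
        InteractionRecord(
            "salt_bridge",
            (ri.chain_id, ri.resnum, ri.aa),
            (rj.chain_id, rj.resnum, rj.aa),
            (ni, nj),
            round(d, 6),
            None,
            _relation(ri, rj),
        )
        for d, ni, nj, ri, rj in best.values()
    ]
    return sorted(records, key=lambda r: r.key())


def detect_aromatic(s: Structure, c: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """Aromatic-aromatic ring-centroid pairs within ``aromatic_max_centroid``
    and, when enabled, aromatic-centroid to polar-atom contacts.
    """
    c = c or InteractionCriteria()
    rings = []
    for res in s.residues():
        names = _AROMATIC_RINGS.get(res.aa)
        if names and all(n in res.atoms for n in names):
            rings.append((res, np.mean([res.coord(n) for n in names], axis=0)))
    records = []
    for x in range(len(rings)):
        for y in range(x + 1, len(rings)):
            res_i, ci = rings[x]
            res_j, cj = rings[y]
            if not _pair_ok(res_i, res_j, c):
                continue
            d = float(np.linalg.norm(ci - cj))
            if d > c.aromatic_max_centroid:
                continue
            ri, ni, rj, nj = _ordered(res_i, "RING", res_j, "RING")
            records.append(
                InteractionRecord(
                    "aromatic",
                    (ri.chain_id, ri.resnum, ri.aa),
                    (rj.chain_id, rj.resnum, rj.aa),
                    (ni, nj),
                    round(d, 6),
                    None,
                    _relation(ri, rj),
                )
            )
    if c.enable_aromatic_polar:
        donors, acceptors = _hbond_tables()
        polar_atoms = {k for k in donors} | set(acceptors)
        for res, centroid in rings:
            for other in s.residues():
                if other is res or not _pair_ok(res, other, c):
                    continue
                for name, atom in other.atoms.items():
                    if (other.aa, name) not in polar_atoms:
                        continue
                    d = float(np.linalg.norm(centroid - atom.coords))
                    if d > c.aromatic_polar_max:
                        continue
                    ri, ni, rj, nj = _ordered(res, "RING", other, name)
                    records.append(
                        InteractionRecord(
                            "aromatic_polar",
                            (ri.chain_id, ri.resnum, ri.aa),
                            (rj.chain_id, rj.resnum, rj.aa),
                            (ni, nj),
                            round(d, 6),
                            None,
                            _relation(res, other),
                        )
                    )
    return sorted(set(records), key=lambda r: r.key())


def detect_all(s: Structure, c: InteractionCriteria | None = None) -> list[InteractionRecord]:
    c = c or InteractionCriteria()
    return (
        detect_hbonds(s, c)
        + detect_hydrophobic(s, c)
        + detect_salt_bridges(s, c)
        + detect_aromatic(s, c)
    )


def partner_map(
    s: Structure, site: tuple[str, int], c: InteractionCriteria | None = None
) -> dict[str, dict[tuple[str, int], str]]:
    """Partner residues of ``site`` per interaction kind, tagged inter/intra.

    Returns ``{kind: {(chain, resnum): relation}}`` for kinds hbond,
    hydrophobic and salt_bridge.
    """
    c = c or InteractionCriteria()
    chain_id, resnum = site
    if not s.has_residue(chain_id, resnum):
        raise KeyError(f"no residue {chain_id}:{resnum} in structure")
    out: dict[str, dict[tuple[str, int], str]] = {
        "hbond": {},
        "hydrophobic": {},
        "salt_bridge": {},
    }
    for rec in detect_all(s, c):
        if rec.kind not in out:
            continue
        if rec.residue_i[:2] == site:
            out[rec.kind][rec.residue_j[:2]] = rec.chain_relation
        elif rec.residue_j[:2] == site:
            out[rec.kind][rec.residue_i[:2]] = rec.chain_relation
    return out
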