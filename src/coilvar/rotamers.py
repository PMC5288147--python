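"""Side-chain rotamer enumeration, placement and steric-clash analysis.

The rotamer library is discrete and backbone-independent: three bins per
rotatable chi dihedral (gauche-, trans, gauche+ centred at -60/180/+60
degrees) with packaged per-chi bin frequencies; a rotamer's probability is
the product of its bin frequencies.  Clashes are van-der-Waals overlaps
between a site's side-chain atoms and all non-bonded atoms, with an
allowance for donor-acceptor pairs.  The rank-ordered clash scan over the
most probable rotamers stands in for forcefield minimization: its
clash-minimizing rotamer is reported as the "relieved" placement.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

from ._data import read_tsv_rows
from .sidechains import N_CHI, STANDARD_AAS, build_side_chain, residue_bonds
from .structure import BACKBONE_ATOMS, Atom, Residue, Structure

__all__ = [
    "Rotamer",
    "ClashCriteria",
    "ClashReport",
    "ScanResult",
    "enumerate_rotamers",
    "place_rotamer",
    "count_clashes",
    "scan_rotamers",
]

_CHI_BINS = (("m", -60.0), ("t", 180.0), ("p", 60.0))


@dataclass(frozen=True)
class Rotamer:
    aa: str
    chi_angles: tuple[float, ...]
    probability: float
    rank: int


@dataclass(frozen=True)
class ClashCriteria:
    """Van-der-Waals overlap convention: a pair clashes when
    r_i + r_j - d >= overlap_cutoff, minus hbond_allowance for
    donor-acceptor pairs; atoms within ``exclude_bonded_within`` bonds of
    each other are ignored.
    """

    overlap_cutoff: float = 0.6
    hbond_allowance: float = 0.4
    exclude_bonded_within: int = 4

    def __post_init__(self):
        if self.overlap_cutoff <= 0:
            raise ValueError("overlap_cutoff must be positive")


@dataclass
class ClashReport:
    site: tuple[str, int]
    rotamer: Rotamer
    clashes: list[tuple[tuple[str, int, str], tuple[str, int, str], float]]
    n_clashes: int = field(init=False)

    def __post_init__(self):
        self.n_clashes = len(self.clashes)


@dataclass
class ScanResult:
    """Rank-ordered clash reports for the top-N rotamers plus the
    clash-minimizing ("relieved") placement among them."""

    site: tuple[str, int]
    aa: str
    reports: list[ClashReport]
    best: ClashReport


@lru_cache(maxsize=None)
def _chi_frequencies() -> dict[tuple[str, int], dict[str, float]]:
    rows = read_tsv_rows("rotamer_frequencies.tsv")
    header = rows[0]
    assert header[:2] == ["aa", "chi"]
    out: dict[tuple[str, int], dict[str, float]] = {}
    for aa, chi, m, t, p in rows[1:]:
        out[(aa, int(chi))] = {"m": float(m), "t": float(t), "p": float(p)}
    return out


@lru_cache(maxsize=None)
def enumerate_rotamers(aa: str) -> tuple[Rotamer, ...]:
    """All 3^k rotamers of ``aa`` (k rotatable chis), most probable first.

    Probabilities over the library sum to 1.  Residues without rotatable
    dihedrals (Ala, Gly, Pro) return a single null rotamer of probability 1.
    Ties in probability are broken by lexicographic chi order.
    """
    if aa not in STANDARD_AAS:
        raise ValueError(f"unknown residue code {aa!r}")
    k = N_CHI[aa]
    if k == 0:
        return (Rotamer(aa, (), 1.0, 1),)
    freqs = _chi_frequencies()
    per_chi = []
    for chi_idx in range(1, k + 1):
        f = freqs[(aa, chi_idx)]
        per_chi.append([(angle, f[binname]) for binname, angle in _CHI_BINS])
    combos = []
    for combo in product(*per_chi):
        chis = tuple(c[0] for c in combo)
        prob = float(np.prod([c[1] for c in combo]))
        combos.append((chis, prob))
    combos.sort(key=lambda cp: (-cp[1], cp[0]))
    return tuple(
        Rotamer(aa, chis, prob, rank) for rank, (chis, prob) in enumerate(combos, start=1)
    )


def place_rotamer(
    s: Structure, site: tuple[str, int], mut_aa: str, r: Rotamer
) -> Structure:
    """Return a copy of ``s`` with the side chain at ``site`` replaced by
    ``mut_aa`` built at the rotamer's chi angles.  The backbone is untouched
    and the input structure is not modified.
    """
    chain_id, resnum = site
    if not s.has_residue(chain_id, resnum):
        raise KeyError(f"no residue {chain_id}:{resnum} in structure")
    out = s.copy()
    res = out.residue(chain_id, resnum)
    for req in ("N", "CA", "C"):
        if req not in res.atoms:
            raise ValueError(f"missing backbone atom {req} at {chain_id}:{resnum}")
    backbone = {n: res.coord(n) for n in BACKBONE_ATOMS if n in res.atoms}
    new_atoms = {n: res.atoms[n] for n in BACKBONE_ATOMS if n in res.atoms}
    for name, pos in build_side_chain(backbone, mut_aa, r.chi_angles).items():
        new_atoms[name] = Atom.of(name, pos)
    res.atoms = new_atoms
    res.aa = mut_aa
    return out


# -- bond graph ------------------------------------------------------------

def _bond_graph(s: Structure) -> dict[tuple[str, int, str], list[tuple[str, int, str]]]:
    graph: dict[tuple[str, int, str], list[tuple[str, int, str]]] = {}

    def add(u, v):
        graph.setdefault(u, []).append(v)
        graph.setdefault(v, []).append(u)

    for cid, residues in s.chains.items():
        prev: Residue | None = None
        for res in residues:
            for a, b in residue_bonds(res.aa):
                if a in res.atoms and b in res.atoms:
                    add((cid, res.resnum, a), (cid, res.resnum, b))
            if (
                prev is not None
                and prev.resnum == res.resnum - 1
                and "C" in prev.atoms
                and "N" in res.atoms
            ):
                add((cid, prev.resnum, "C"), (cid, res.resnum, "N"))
            prev = res
    return graph


def _within_bonds(graph, start, max_bonds: int) -> set:
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        node, dist = frontier.popleft()
        if dist == max_bonds:
            continue
        for nb in graph.get(node, ()):
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, dist + 1))
    return seen


@lru_cache(maxsize=None)
def _polarity_tables():
    donors: set[tuple[str, str]] = set()
    acceptors: set[tuple[str, str]] = set()
    for aa, atom, role, _ant in read_tsv_rows("hbond_atoms.tsv")[1:]:
        if role in ("donor", "both"):
            donors.add((aa, atom))
        if role in ("acceptor", "both"):
            acceptors.add((aa, atom))
    return donors, acceptors


def _is_da_pair(res_i: Residue, name_i: str, res_j: Residue, name_j: str) -> bool:
    donors, acceptors = _polarity_tables()

    def is_donor(res, name):
        return name == "N" or (res.aa, name) in donors

    def is_acceptor(res, name):
        return name == "O" or (res.aa, name) in acceptors

    return (is_donor(res_i, name_i) and is_acceptor(res_j, name_j)) or (
        is_donor(res_j, name_j) and is_acceptor(res_i, name_i)
    )


def count_clashes(
    s: Structure, site: tuple[str, int], c: ClashCriteria | None = None
) -> ClashReport:
    """Count vdW overlaps between the side chain at ``site`` and the rest of
    the structure (bonded neighbours within ``exclude_bonded_within`` bonds
    excluded; donor-acceptor pairs get ``hbond_allowance`` slack).
    """
    c = c or ClashCriteria()
    chain_id, resnum = site
    res = s.residue(chain_id, resnum)
    side_atoms = [(n, a) for n, a in res.atoms.items() if n not in BACKBONE_ATOMS]
    rotamer = Rotamer(res.aa, (), 1.0, 0)  # placeholder descriptor for ad-hoc counts
    if not side_atoms:
        return ClashReport(site, rotamer, [])

    all_entries = [(r, a) for r, a in s.atoms()]
    coords = np.array([a.coords for _, a in all_entries])
    tree = cKDTree(coords)
    graph = _bond_graph(s)
    max_pair = 2 * max(a.vdw_radius for _, a in all_entries)
    search_r = max_pair - c.overlap_cutoff + c.hbond_allowance + 1e-9

    clashes = []
    for name, atom in side_atoms:
        me = (chain_id, resnum, name)
        excluded = _within_bonds(graph, me, c.exclude_bonded_within)
        for j in tree.query_ball_point(atom.coords, search_r):
            res_j, atom_j = all_entries[j]
            other = (res_j.chain_id, res_j.resnum, atom_j.name)
            if other == me or other in excluded:
                continue
            # count each intra-site side-chain pair once
            if res_j.chain_id == chain_id and res_j.resnum == resnum:
                if atom_j.name not in BACKBONE_ATOMS and other < me:
                    continue
            d = float(np.linalg.norm(atom.coords - atom_j.coords))
            overlap = atom.vdw_radius + atom_j.vdw_radius - d
            if _is_da_pair(res, name, res_j, atom_j.name):
                overlap -= c.hbond_allowance
            if overlap >= c.overlap_cutoff:
                clashes.append((me, other, round(overlap, 6)))
    clashes.sort()
    return ClashReport(site, rotamer, clashes)


def scan_rotamers(
    s: Structure,
    site: tuple[str, int],
    mut_aa: str,
    c: ClashCriteria | None = None,
    top_n: int = 5,
) -> ScanResult:
    """Clash reports for the ``top_n`` most probable rotamers of ``mut_aa``
    placed at ``site``, in rank order, plus the clash-minimizing placement
    (ties resolved toward higher probability).
    """
    c = c or ClashCriteria()
    rotamers = enumerate_rotamers(mut_aa)[: max(1, top_n)]
    reports = []
    for rot in rotamers:
        mutated = place_rotamer(s, site, mut_aa, rot)
        rep = count_clashes(mutated, site, c)
        rep.rotamer = rot
        reports.append(rep)
    best = min(reports, key=lambda r: (r.n_clashes, r.rotamer.rank))
    return ScanResult(site, mut_aa, reports, best)
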