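"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately re-derive results from first principles (exhaustive
pairwise loops, rotation-space search, explicit truth tables) without going
through the library code paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from coilvar._data import read_tsv_rows


def grid_rmsd_oracle(p: np.ndarray, q: np.ndarray, coarse: int = 24) -> float:
    """Minimum RMSD over rigid superpositions via rotation-space search:
    coarse Euler-angle grid followed by local refinement.  Independent of the
    Kabsch closed form."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def cost_rotvec(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((pc @ r.T - qc) ** 2, axis=1)))

    candidates = []
    angles = np.linspace(-np.pi, np.pi, coarse, endpoint=False)
    for a in angles:
        for b in np.linspace(-np.pi / 2, np.pi / 2, coarse // 2):
            for c in angles:
                rv = Rotation.from_euler("zyz", [a, b, c]).as_rotvec()
                candidates.append((cost_rotvec(rv), tuple(rv)))
    candidates.sort()
    best = candidates[0][0]
    for v0, rv0 in candidates[:12]:
        res = minimize(
            cost_rotvec,
            np.array(rv0),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        )
        best = min(best, float(res.fun))
    return best


def brute_force_clashes(structure, site, criteria):
    """Exhaustive all-pairs clash count for the side chain at ``site``."""
    from coilvar.sidechains import residue_bonds

    chain_id, resnum = site
    backbone = {"N", "CA", "C", "O"}

    # atom list and bond graph rebuilt from scratch
    atoms = []
    for res in structure.residues():
        for name, atom in res.atoms.items():
            atoms.append((res, name, atom))
    bonds = set()
    for cid, residues in structure.chains.items():
        prev = None
        for res in residues:
            for a, b in residue_bonds(res.aa):
                if a in res.atoms and b in res.atoms:
                    bonds.add(frozenset([(cid, res.resnum, a), (cid, res.resnum, b)]))
            if prev is not None and prev.resnum == res.resnum - 1:
                if "C" in prev.atoms and "N" in res.atoms:
                    bonds.add(frozenset([(cid, prev.resnum, "C"), (cid, res.resnum, "N")]))
            prev = res

    def bond_distance(u, v, cap):
        if u == v:
            return 0
        frontier = {u}
        seen = {u}
        for depth in range(1, cap + 1):
            nxt = set()
            for x in frontier:
                for bd in bonds:
                    if x in bd:
                        (other,) = bd - {x}
                        if other not in seen:
                            nxt.add(other)
                            seen.add(other)
            if v in nxt:
                return depth
            frontier = nxt
        return cap + 1

    donors = {("*", "N")}
    acceptors = {("*", "O")}
    for aa, atom, role, _ant in read_tsv_rows("hbond_atoms.tsv")[1:]:
        if role in ("donor", "both"):
            donors.add((aa, atom))
        if role in ("acceptor", "both"):
            acceptors.add((aa, atom))

    def is_donor(res, name):
        return name == "N" or (res.aa, name) in donors

    def is_acceptor(res, name):
        return name == "O" or (res.aa, name) in acceptors

    site_atoms = [
        (res, name, atom)
        for res, name, atom in atoms
        if res.chain_id == chain_id and res.resnum == resnum and name not in backbone
    ]
    count = 0
    counted = set()
    for res_i, name_i, atom_i in site_atoms:
        u = (chain_id, resnum, name_i)
        for res_j, name_j, atom_j in atoms:
            v = (res_j.chain_id, res_j.resnum, name_j)
            if u == v or frozenset([u, v]) in counted:
                continue
            if bond_distance(u, v, criteria.exclude_bonded_within) <= criteria.exclude_bonded_within:
                continue
            d = np.linalg.norm(atom_i.coords - atom_j.coords)
            overlap = atom_i.vdw_radius + atom_j.vdw_radius - d
            if (is_donor(res_i, name_i) and is_acceptor(res_j, name_j)) or (
                is_donor(res_j, name_j) and is_acceptor(res_i, name_i)
            ):
                overlap -= criteria.hbond_allowance
            if overlap >= criteria.overlap_cutoff:
                count += 1
                counted.add(frozenset([u, v]))
    return count


def brute_force_hydrophobic_pairs(structure, criteria):
    """Exhaustive residue pairs with an apolar-apolar contact."""
    apolar = {}
    for row in read_tsv_rows("apolar_atoms.tsv")[1:]:
        apolar[row[0]] = set(row[1].split("|")) if len(row) > 1 and row[1] else set()
    residues = list(structure.residues())
    pairs = set()
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            if ri.chain_id == rj.chain_id and abs(ri.resnum - rj.resnum) < criteria.min_sequence_separation:
                continue
            hit = False
            for ni in apolar[ri.aa]:
                if ni not in ri.atoms:
                    continue
                for nj in apolar[rj.aa]:
                    if nj not in rj.atoms:
                        continue
                    if np.linalg.norm(ri.coord(ni) - rj.coord(nj)) <= criteria.hydrophobic_max_cc:
                        hit = True
            if hit:
                pairs.add(((ri.chain_id, ri.resnum), (rj.chain_id, rj.resnum)))
    return pairs


def snp_verdict_oracle(conservation_class, letter, lost_interchain, hydropathy_changed, best_clashes):
    """Truth-table re-statement of the SNP triage rule."""
    c1 = conservation_class in (":", "*")
    core = letter in ("a", "d")
    c2 = lost_interchain or (hydropathy_changed and core)
    c3 = best_clashes > 0 or core
    return "pathogenic_candidate" if (c1 and c2 and c3) else "likely_benign"
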