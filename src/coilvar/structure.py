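"""All-atom two-chain structures: PDB I/O, synthetic coiled-coil generation
and Kabsch superposition.

The synthetic generator produces a parallel two-helix coiled coil from Crick
parameters: each chain is an ideal alpha helix whose backbone cylinder
parameters are extracted from an internally built reference helix, wound
onto a supercoil path of given radius and pitch.  Minor-helix phases are
anchored to the heptad register so that core positions ('a'/'d' by default)
face the inter-axis core, and side chains are placed in their most frequent
rotamer from ideal internal coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from ._data import vdw_radii
from .geometry import dihedral, kabsch_rmsd, place_atom
from .sidechains import AA1, STANDARD_AAS, aa1to3, build_side_chain

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "CrickParams",
    "build_coiled_coil",
    "read_structure",
    "write_structure",
    "superpose_rmsd",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
HEPTAD = "abcdefg"


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class Atom:
    """One heavy atom with PDB name, element, coordinates and vdW radius."""

    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")

    @classmethod
    def of(cls, name: str, coords) -> "Atom":
        el = _element_of(name)
        return cls(name, el, np.asarray(coords, float), vdw_radii()[el])


@dataclass
class Residue:
    chain_id: str
    resnum: int
    aa: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].coords

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id,
            self.resnum,
            self.aa,
            {n: Atom(a.name, a.element, a.coords.copy(), a.vdw_radius) for n, a in self.atoms.items()},
        )


class Structure:
    """Ordered chains of residues with strictly increasing residue numbers."""

    def __init__(self, chains: dict[str, list[Residue]], metadata: str = ""):
        for cid, residues in chains.items():
            nums = [r.resnum for r in residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(f"residue numbers not strictly increasing in chain {cid}")
        self.chains = chains
        self.metadata = metadata
        self._index = {
            (cid, r.resnum): r for cid, residues in chains.items() for r in residues
        }

    def residue(self, chain_id: str, resnum: int) -> Residue:
        try:
            return self._index[(chain_id, resnum)]
        except KeyError:
            raise KeyError(f"no residue {chain_id}:{resnum} in structure") from None

    def has_residue(self, chain_id: str, resnum: int) -> bool:
        return (chain_id, resnum) in self._index

    def residues(self):
        for residues in self.chains.values():
            yield from residues

    def atoms(self):
        """Yield (residue, atom) pairs in deterministic order."""
        for res in self.residues():
            for atom in res.atoms.values():
                yield res, atom

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])

    def coords(self) -> np.ndarray:
        return np.array([a.coords for _, a in self.atoms()])

    def copy(self) -> "Structure":
        return Structure(
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            self.metadata,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        for _, atom in out.atoms():
            atom.coords = rotation @ atom.coords + np.asarray(translation, float)
        return out


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_structure(path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Insertion codes are rejected; alternate locations resolve to the highest
    occupancy; heteroatoms and waters are skipped.  Missing backbone atoms
    produce warnings, not errors.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"unreadable or empty PDB file: {path}")
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            het, resnum, icode = res.id
            if het.strip():
                continue
            if icode.strip():
                raise ValueError(
                    f"insertion code {icode!r} at {chain.id}:{resnum} not supported"
                )
            resname = res.get_resname()
            if resname not in AA1:
                warnings.warn(f"skipping non-standard residue {resname} at {chain.id}:{resnum}")
                continue
            atoms: dict[str, Atom] = {}
            for atom in res:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy())
                if atom.element == "H":
                    continue
                atoms[atom.get_name()] = Atom.of(atom.get_name(), atom.get_coord())
            residues.append(Residue(chain.id, resnum, AA1[resname], atoms))
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise ValueError(f"no protein residues found in {path}")
    st = Structure(chains, metadata=f"read from {path.name}")
    for res in st.residues():
        if not res.has_backbone():
            warnings.warn(f"missing backbone atoms in {res.chain_id}:{res.resnum}")
    return st


def write_structure(s: Structure, path) -> None:
    """Write fixed-column PDB ATOM/TER/END records."""
    lines = []
    serial = 1
    for cid, residues in s.chains.items():
        for res in residues:
            resname = aa1to3(res.aa)
            for atom in res.atoms.values():
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {atom.name:<4s}{resname:>4s} {cid}"
                    f"{res.resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append(
            f"TER   {serial:5d}      {aa1to3(residues[-1].aa):>3s} {cid}{residues[-1].resnum:4d}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Crick-parameterized coiled-coil generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrickParams:
    """Geometry of the two-helix supercoil.

    Defaults are standard left-handed dimeric coiled-coil values: supercoil
    radius 4.9 A, axial rise 1.51 A per residue, 3.5 residues per turn in the
    supercoil frame, pitch 140 A.  ``phase_a`` is the azimuth (degrees, from
    the core-facing direction) of the 'a'-position CA.
    """

    supercoil_radius: float = 4.9
    supercoil_pitch: float = 140.0
    helix_radius: float | None = None
    residues_per_turn: float = 3.5
    rise_per_residue: float = 1.51
    phase_a: float = 26.0
    parallel: bool = True

    def __post_init__(self):
        for name in ("supercoil_radius", "supercoil_pitch", "residues_per_turn", "rise_per_residue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.parallel:
            raise ValueError("only parallel dimers are supported")

    def with_(self, **kw) -> "CrickParams":
        return replace(self, **kw)


@lru_cache(maxsize=None)
def _helix_template(phi: float = -60.0, psi: float = -45.0, n: int = 41):
    """Cylinder parameters (radius, phase offset, z offset per backbone atom)
    of an ideal straight alpha helix built from internal coordinates.
    """
    bonds = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
    angles = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}
    res = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([bonds["N-CA"], 0.0, 0.0])
    c0 = place_atom(n0 + [0, 1, 0], n0, ca0, bonds["CA-C"], angles["N-CA-C"], phi)
    cur = {"N": n0, "CA": ca0, "C": c0}
    cur["O"] = place_atom(cur["N"], cur["CA"], cur["C"], bonds["C-O"], angles["CA-C-O"], psi + 180.0)
    res.append(cur)
    for _ in range(1, n):
        prev = res[-1]
        nn = place_atom(prev["N"], prev["CA"], prev["C"], bonds["C-N"], angles["CA-C-N"], psi)
        ca = place_atom(prev["CA"], prev["C"], nn, bonds["N-CA"], angles["C-N-CA"], 180.0)
        c = place_atom(prev["C"], nn, ca, bonds["CA-C"], angles["N-CA-C"], phi)
        o = place_atom(nn, ca, c, bonds["C-O"], angles["CA-C-O"], psi + 180.0)
        res.append({"N": nn, "CA": ca, "C": c, "O": o})

    cas = np.array([r["CA"] for r in res])
    centroid = cas.mean(axis=0)
    cov = (cas - centroid).T @ (cas - centroid)
    _, eigvec = np.linalg.eigh(cov)
    axis = eigvec[:, -1]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    rad0 = cas[0] - centroid - ((cas[0] - centroid) @ axis) * axis
    e1 = rad0 / np.linalg.norm(rad0)
    e2 = np.cross(axis, e1)

    def cyl(p):
        v = p - centroid
        z = v @ axis
        return np.hypot(v @ e1, v @ e2), math.atan2(v @ e2, v @ e1), z

    lo, hi = 5, n - 5
    ca_cyl = [cyl(r["CA"]) for r in res]
    ca_phase = np.unwrap([c[1] for c in ca_cyl])
    twist = float(np.degrees(np.mean(np.diff(ca_phase[lo:hi]))))
    rise = float(np.mean(np.diff([c[2] for c in ca_cyl[lo:hi]])))
    per_atom = {}
    for name in BACKBONE_ATOMS:
        rs, dphis, dzs = [], [], []
        for i in range(lo, hi):
            r_, ph_, z_ = cyl(res[i][name])
            rs.append(r_)
            dph = ph_ - ca_phase[i]
            dphis.append(math.atan2(math.sin(dph), math.cos(dph)))
            dzs.append(z_ - ca_cyl[i][2])
        per_atom[name] = (float(np.mean(rs)), float(np.degrees(np.mean(dphis))), float(np.mean(dzs)))
    return {"twist": twist, "rise": rise, "atoms": per_atom}


def _top_rotamer_chis(aa: str) -> tuple[float, ...]:
    from .rotamers import enumerate_rotamers

    return tuple(enumerate_rotamers(aa)[0].chi_angles)


def build_coiled_coil(
    seq_a: str,
    seq_b: str,
    params: CrickParams | None = None,
    register_anchor_a: tuple[int, str] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    start_a: int = 1,
    start_b: int = 1,
    register_anchor_b: tuple[int, str] | None = None,
    phase_b: float | None = None,
    z_offset_b: float = 0.0,
    chain_ids: tuple[str, str] = ("A", "B"),
    sidechains: str = "top-rotamer",
) -> Structure:
    """Generate a parallel two-chain coiled-coil heterodimer.

    ``register_anchor_a``/``register_anchor_b`` pin the heptad register of
    each chain ((resnum, letter); default: first residue is 'a').  ``phase_b``
    overrides the azimuth of chain B's 'a' position (degrees from the
    core-facing direction; default ``params.phase_a`` as for chain A).
    Gaussian coordinate noise of ``noise_sd`` A is applied with ``seed``.
    """
    params = params or CrickParams()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}")
    for seq in (seq_a, seq_b):
        bad = set(seq) - STANDARD_AAS
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    if register_anchor_a is None:
        register_anchor_a = (start_a, "a")
    if register_anchor_b is None:
        register_anchor_b = (start_b, "a")

    tmpl = _helix_template()
    sign = 1.0 if tmpl["twist"] >= 0 else -1.0
    omega1 = sign * 360.0 / params.residues_per_turn  # deg per residue, minor helix
    r_scale = 1.0
    if params.helix_radius is not None:
        r_scale = params.helix_radius / tmpl["atoms"]["CA"][0]
    r0 = params.supercoil_radius
    theta_rate = -sign * 2.0 * math.pi / params.supercoil_pitch  # opposite handedness

    rng = np.random.default_rng(seed)
    chains: dict[str, list[Residue]] = {}
    specs = [
        (chain_ids[0], seq_a, start_a, register_anchor_a, params.phase_a, 0.0, 0.0),
        (chain_ids[1], seq_b, start_b, register_anchor_b,
         params.phase_a if phase_b is None else phase_b, math.pi, z_offset_b),
    ]
    for cid, seq, start, (anch_num, anch_letter), phase_a_deg, theta0, z_off in specs:
        if anch_letter not in HEPTAD:
            raise ValueError(f"register anchor letter must be a-g, got {anch_letter!r}")
        i_anchor = anch_num - start
        i_a = i_anchor - HEPTAD.index(anch_letter)  # index of an 'a' residue
        residues = []
        for i, aa in enumerate(seq):
            phase_ca = math.radians(phase_a_deg + (i - i_a) * omega1)
            atoms: dict[str, Atom] = {}
            backbone: dict[str, np.ndarray] = {}
            for name in BACKBONE_ATOMS:
                r_at, dphi, dz = tmpl["atoms"][name]
                phase = phase_ca + math.radians(dphi)
                z = i * params.rise_per_residue + dz + z_off
                theta = theta0 + theta_rate * z
                axis_pt = np.array([r0 * math.cos(theta), r0 * math.sin(theta), z])
                inward = -np.array([math.cos(theta), math.sin(theta), 0.0])
                tangent = np.array(
                    [-r0 * theta_rate * math.sin(theta), r0 * theta_rate * math.cos(theta), 1.0]
                )
                tangent /= np.linalg.norm(tangent)
                binormal = np.cross(tangent, inward)
                pos = axis_pt + r_at * r_scale * (
                    math.cos(phase) * inward + math.sin(phase) * binormal
                )
                backbone[name] = pos
                atoms[name] = Atom.of(name, pos)
            if aa != "G":
                chis = _top_rotamer_chis(aa) if sidechains == "top-rotamer" else ()
                for name, pos in build_side_chain(backbone, aa, chis).items():
                    atoms[name] = Atom.of(name, pos)
            residues.append(Residue(cid, start + i, aa, atoms))
        chains[cid] = residues

    st = Structure(chains, metadata="synthetic coiled coil")
    if noise_sd > 0:
        for _, atom in st.atoms():
            atom.coords = atom.coords + rng.normal(0.0, noise_sd, size=3)
    return st


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _matched_coords(a: Structure, b: Structure, atom_selection: str):
    if atom_selection not in ("backbone", "all"):
        raise ValueError(f"atom_selection must be 'backbone' or 'all', got {atom_selection!r}")
    ra = list(a.residues())
    rb = list(b.residues())
    if len(ra) != len(rb):
        raise ValueError(f"residue count mismatch: {len(ra)} vs {len(rb)}")
    pa, pb = [], []
    for x, y in zip(ra, rb):
        if atom_selection == "backbone":
            names = [n for n in BACKBONE_ATOMS if n in x.atoms and n in y.atoms]
        else:
            if set(x.atoms) != set(y.atoms):
                raise ValueError(
                    f"atom set mismatch at {x.chain_id}:{x.resnum} vs {y.chain_id}:{y.resnum}"
                )
            names = sorted(x.atoms)
        for n in names:
            pa.append(x.coord(n))
            pb.append(y.coord(n))
    if not pa:
        raise ValueError("no atoms selected for superposition")
    return np.array(pa), np.array(pb)


def superpose_rmsd(a: Structure, b: Structure, atom_selection: str = "backbone") -> float:
    """Minimum RMSD (A) after optimal rigid (Kabsch) superposition."""
    pa, pb = _matched_coords(a, b, atom_selection)
    return kabsch_rmsd(pa, pb)


def backbone_dihedrals(residues: list[Residue]) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; None where neighbours or atoms are missing."""
    out = []
    for i, res in enumerate(residues):
        phi = psi = None
        prev_ = residues[i - 1] if i > 0 else None
        next_ = residues[i + 1] if i + 1 < len(residues) else None
        try:
            if prev_ is not None and prev_.resnum == res.resnum - 1:
                phi = dihedral(prev_.coord("C"), res.coord("N"), res.coord("CA"), res.coord("C"))
            if next_ is not None and next_.resnum == res.resnum + 1:
                psi = dihedral(res.coord("N"), res.coord("CA"), res.coord("C"), next_.coord("N"))
        except KeyError:
            warnings.warn(f"missing backbone atoms for dihedrals at {res.chain_id}:{res.resnum}")
            phi = psi = None
        out.append((phi, psi))
    return out
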