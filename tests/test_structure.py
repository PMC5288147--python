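import numpy as np
import pytest

from conftest import random_rotation
from coilvar.structure import (
    CrickParams,
    backbone_dihedrals,
    build_coiled_coil,
    read_structure,
    superpose_rmsd,
    write_structure,
)

HEPT = "abcdefg"


@pytest.fixture(scope="module")
def coil100():
    seq = ("LAELKNE" * 15)[:100]
    return build_coiled_coil(seq, seq, CrickParams(), (1, "a"))


class TestBuilder:
    def test_axis_separation_is_twice_supercoil_radius(self):
        seq = ("LAELKAK" * 4)[:28]
        s = build_coiled_coil(seq, seq, CrickParams(supercoil_radius=4.9), (1, "a"))
        caA = np.array([r.coord("CA") for r in s.chains["A"]])
        caB = np.array([r.coord("CA") for r in s.chains["B"]])
        # centroid of 7 consecutive CAs (= 2 full turns in the supercoil
        # frame) approximates a point on the local helix axis
        for i in range(0, 22, 7):
            d = np.linalg.norm(caA[i : i + 7].mean(axis=0) - caB[i : i + 7].mean(axis=0))
            assert d == pytest.approx(2 * 4.9, abs=0.2)

    def test_axial_span(self, coil100):
        ca = np.array([r.coord("CA") for r in coil100.chains["A"]])
        span = ca[-1][2] - ca[0][2]
        assert span == pytest.approx(99 * 1.51, abs=1.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            build_coiled_coil("A" * 10, "A" * 11, CrickParams(), (1, "a"))

    def test_nonstandard_residue_errors(self):
        with pytest.raises(ValueError):
            build_coiled_coil("AXA", "AAA", CrickParams(), (1, "a"))

    def test_helical_dihedrals(self, coil100):
        dih = backbone_dihedrals(coil100.chains["A"])[5:-5]
        for phi, psi in dih:
            assert phi == pytest.approx(-60, abs=5)
            assert psi == pytest.approx(-45, abs=5)

    def test_core_packs_inward(self, coil100):
        means = {}
        for letter in "af":
            ds = [
                np.linalg.norm(ra.coord("CB") - rb.coord("CB"))
                for i, (ra, rb) in enumerate(zip(coil100.chains["A"], coil100.chains["B"]))
                if HEPT[i % 7] == letter and "CB" in ra.atoms and "CB" in rb.atoms
            ]
            means[letter] = np.mean(ds)
        assert means["a"] < means["f"]

    def test_noise_free_is_deterministic(self):
        seq = ("LAELKNE" * 3)[:21]
        s1 = build_coiled_coil(seq, seq, CrickParams(), (1, "a"), noise_sd=0.0, seed=1)
        s2 = build_coiled_coil(seq, seq, CrickParams(), (1, "a"), noise_sd=0.0, seed=2)
        assert np.array_equal(s1.coords(), s2.coords())

    def test_noise_is_seed_reproducible(self):
        seq = ("LAELKNE" * 3)[:21]
        s1 = build_coiled_coil(seq, seq, CrickParams(), (1, "a"), noise_sd=0.2, seed=7)
        s2 = build_coiled_coil(seq, seq, CrickParams(), (1, "a"), noise_sd=0.2, seed=7)
        s3 = build_coiled_coil(seq, seq, CrickParams(), (1, "a"), noise_sd=0.2, seed=8)
        assert np.array_equal(s1.coords(), s2.coords())
        assert not np.array_equal(s1.coords(), s3.coords())

    def test_resnum_offsets(self):
        seq = "LAELKNE"
        s = build_coiled_coil(seq, seq, CrickParams(), (373, "a"), start_a=373, start_b=340)
        assert [r.resnum for r in s.chains["A"]][0] == 373
        assert [r.resnum for r in s.chains["B"]][0] == 340

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CrickParams(supercoil_radius=-1)
        with pytest.raises(ValueError):
            CrickParams(parallel=False)


class TestPdbIO:
    def test_roundtrip(self, small_coil, tmp_path):
        path = tmp_path / "coil.pdb"
        write_structure(small_coil, path)
        back = read_structure(path)
        assert list(back.chains) == list(small_coil.chains)
        for ra, rb in zip(small_coil.residues(), back.residues()):
            assert (ra.chain_id, ra.resnum, ra.aa) == (rb.chain_id, rb.resnum, rb.aa)
            assert set(ra.atoms) == set(rb.atoms)
            for name in ra.atoms:
                assert ra.coord(name) == pytest.approx(rb.coord(name), abs=1.5e-3)

    def test_two_chain_121(self, tmp_path):
        seq = ("LAELKNE" * 18)[:121]
        s = build_coiled_coil(seq, seq, CrickParams(), (373, "a"), start_a=373, start_b=340)
        path = tmp_path / "dimer.pdb"
        write_structure(s, path)
        back = read_structure(path)
        assert len(back.chains) == 2
        assert all(len(res) == 121 for res in back.chains.values())

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            read_structure(path)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(ValueError):
            read_structure(tmp_path / "nope.pdb")

    def test_insertion_code_rejected(self, tmp_path):
        path = tmp_path / "icode.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1A     0.000   0.000   0.000  1.00  0.00           N\n"
            "END\n"
        )
        with pytest.raises(ValueError):
            read_structure(path)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.30  0.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.70  0.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  C   ALA A   1       2.000   1.420   0.000  1.00  0.00           C\n"
            "ATOM      5  O   ALA A   1       3.200   1.500   0.000  1.00  0.00           O\n"
            "END\n"
        )
        s = read_structure(path)
        assert s.residue("A", 1).coord("N")[0] == pytest.approx(9.0, abs=1e-3)


class TestSuperpose:
    def test_identity(self, small_coil):
        assert superpose_rmsd(small_coil, small_coil) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, small_coil, rng):
        moved = small_coil.transformed(random_rotation(rng), np.array([10.0, -4.0, 2.0]))
        assert superpose_rmsd(small_coil, moved, "all") == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, small_coil, rng):
        noisy = small_coil.copy()
        for _, atom in noisy.atoms():
            atom.coords = atom.coords + rng.normal(0, 0.3, 3)
        a = superpose_rmsd(small_coil, noisy, "all")
        b = superpose_rmsd(noisy, small_coil, "all")
        assert a == pytest.approx(b, abs=1e-9)
        assert a > 0

    def test_count_mismatch_errors(self, small_coil):
        seq = ("LAELKNE" * 2)[:14]
        other = build_coiled_coil(seq, seq, CrickParams(), (1, "a"))
        with pytest.raises(ValueError):
            superpose_rmsd(small_coil, other)
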