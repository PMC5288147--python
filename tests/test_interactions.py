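import numpy as np
import pytest

from conftest import random_rotation
from coilvar.interactions import (
    InteractionCriteria,
    detect_all,
    detect_hbonds,
    detect_hydrophobic,
    detect_salt_bridges,
    partner_map,
)
from coilvar.structure import Atom, Residue, Structure
from oracles import brute_force_hydrophobic_pairs


def residue(chain, num, aa, atoms):
    return Residue(chain, num, aa, {n: Atom.of(n, c) for n, c in atoms.items()})


def two_residue_structure(res_a, res_b):
    if res_a.chain_id == res_b.chain_id:
        return Structure({res_a.chain_id: sorted([res_a, res_b], key=lambda r: r.resnum)})
    return Structure({res_a.chain_id: [res_a], res_b.chain_id: [res_b]})


def ser_at(chain, num, og):
    """Serine with its OG (donor+acceptor) at the given coordinate."""
    base = np.array(og) - [0.0, 0.0, 1.4]
    return residue(
        chain,
        num,
        "S",
        {
            "N": base + [-1.4, 0, -1.0],
            "CA": base + [0, 0, -1.0],
            "C": base + [1.4, 0, -1.2],
            "O": base + [2.2, 0.9, -1.2],
            "CB": base,
            "OG": np.array(og),
        },
    )


class TestHbonds:
    def test_pair_inside_criteria(self):
        a = ser_at("A", 1, [0.0, 0.0, 0.0])
        b = ser_at("B", 1, [0.0, 0.0, 2.9])
        recs = [r for r in detect_hbonds(two_residue_structure(a, b)) if r.atoms == ("OG", "OG")]
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.9, abs=1e-6)
        assert recs[0].chain_relation == "inter"

    def test_pair_outside_distance(self):
        a = ser_at("A", 1, [0.0, 0.0, 0.0])
        b = ser_at("B", 1, [0.0, 0.0, 4.2])
        assert [r for r in detect_hbonds(two_residue_structure(a, b)) if r.atoms == ("OG", "OG")] == []

    def test_angle_criterion(self):
        # acceptor placed at ~63 degrees from the donor antecedent: rejected
        a = ser_at("A", 1, [0.0, 0.0, 0.0])
        b = ser_at("B", 1, [0.0, 3.0, -1.0])
        c = InteractionCriteria(hbond_min_angle=150.0)
        assert [r for r in detect_hbonds(two_residue_structure(a, b), c) if r.atoms == ("OG", "OG")] == []

    def test_reference_model_e478_r450(self, reference_structure, default_cfg):
        pm = partner_map(reference_structure, ("A", 478), default_cfg.interaction_criteria())
        assert pm["hbond"].get(("B", 450)) == "inter"


class TestHydrophobic:
    def leu(self, chain, num, cd1):
        base = np.array(cd1) - [0, 0, 2.5]
        return residue(
            chain,
            num,
            "L",
            {
                "N": base + [-1.4, 0, -1],
                "CA": base + [0, 0, -1],
                "C": base + [1.4, 0, -1.3],
                "O": base + [2.2, 0.9, -1.3],
                "CB": base,
                "CG": base + [0, 0.4, 1.3],
                "CD1": np.array(cd1),
                "CD2": base + [1.2, 0.8, 1.8],
            },
        )

    def test_leucine_pair_in_range(self):
        s = two_residue_structure(self.leu("A", 1, [0, 0, 0]), self.leu("B", 1, [0, 0, 4.0]))
        recs = detect_hydrophobic(s)
        assert len(recs) == 1
        assert recs[0].distance <= 4.5

    def test_glycine_pair_never_matches(self):
        g1 = residue("A", 1, "G", {"N": [-1.4, 0, 0], "CA": [0, 0, 0], "C": [1.4, 0, 0], "O": [2, 1, 0]})
        g2 = residue("B", 1, "G", {"N": [-1.4, 0, 1], "CA": [0, 0, 1], "C": [1.4, 0, 1], "O": [2, 1, 1]})
        assert detect_hydrophobic(two_residue_structure(g1, g2)) == []

    def test_matches_brute_force_oracle_on_toy(self, small_coil):
        c = InteractionCriteria()
        ours = {
            (r.residue_i[:2], r.residue_j[:2]) for r in detect_hydrophobic(small_coil, c)
        }
        assert ours == brute_force_hydrophobic_pairs(small_coil, c)

    def test_reference_model_l437_partners(self, reference_structure, default_cfg):
        pm = partner_map(reference_structure, ("A", 437), default_cfg.interaction_criteria())
        assert {("B", 403), ("B", 404)} <= set(pm["hydrophobic"])


class TestSaltBridges:
    def glu(self, chain, num, oe1):
        base = np.array(oe1) - [0, 0, 1.2]
        return residue(
            chain, num, "E",
            {"N": base + [-1.4, 0, -2], "CA": base + [0, 0, -2], "C": base + [1.4, 0, -2.2],
             "O": base + [2.2, 0.9, -2.2], "CB": base + [0, 0, -1.5], "CG": base + [0, 0.3, -0.8],
             "CD": base + [0, 0, 0], "OE1": np.array(oe1), "OE2": base + [1.1, 0.4, 0.3]},
        )

    def lys(self, chain, num, nz):
        base = np.array(nz) - [0, 0, 1.5]
        return residue(
            chain, num, "K",
            {"N": base + [-1.4, 0, -3], "CA": base + [0, 0, -3], "C": base + [1.4, 0, -3.2],
             "O": base + [2.2, 0.9, -3.2], "CB": base + [0, 0, -2.3], "CG": base + [0, 0.3, -1.6],
             "CD": base + [0, 0, -0.8], "CE": base + [0, 0.2, 0], "NZ": np.array(nz)},
        )

    def test_glu_lys_at_3p2(self):
        s = two_residue_structure(self.glu("A", 1, [0, 0, 0]), self.lys("B", 1, [0, 0, 3.2]))
        recs = detect_salt_bridges(s)
        assert len(recs) == 1
        assert recs[0].distance <= 3.2 + 1e-6

    def test_like_charges_no_record(self):
        s = two_residue_structure(self.glu("A", 1, [0, 0, 0]), self.glu("B", 1, [0, 0, 3.2]))
        assert detect_salt_bridges(s) == []

    def test_posed_pair_is_both_salt_bridge_and_hbond(self):
        # Glu OE1 ~2.9 A from Lys NZ along the NZ-CE axis: qualifies for both
        s = two_residue_structure(self.glu("A", 1, [0, 0, 3.2]), self.lys("B", 1, [0, 0, 0.3]))
        sb = detect_salt_bridges(s)
        hb = detect_hbonds(s)
        assert any(r.kind == "salt_bridge" for r in sb)
        assert any(r.kind == "hbond" and "OE1" in r.atoms for r in hb)


class TestProperties:
    def test_rigid_motion_invariance(self, small_coil, rng):
        c = InteractionCriteria()
        moved = small_coil.transformed(random_rotation(rng), np.array([3.0, -8.0, 5.0]))
        before = [(r.kind, r.residue_i, r.residue_j, r.atoms) for r in detect_all(small_coil, c)]
        after = [(r.kind, r.residue_i, r.residue_j, r.atoms) for r in detect_all(moved, c)]
        assert before == after
        d_before = [r.distance for r in detect_all(small_coil, c)]
        d_after = [r.distance for r in detect_all(moved, c)]
        assert d_before == pytest.approx(d_after, abs=1e-6)

    def test_cutoff_monotonicity(self, small_coil):
        base = InteractionCriteria()
        wider = InteractionCriteria(
            hbond_max_da=base.hbond_max_da + 0.5,
            hydrophobic_max_cc=base.hydrophobic_max_cc + 0.5,
            saltbridge_max=base.saltbridge_max + 0.5,
        )
        for detector in (detect_hbonds, detect_hydrophobic, detect_salt_bridges):
            small = {(r.residue_i, r.residue_j, r.atoms) for r in detector(small_coil, base)}
            big = {(r.residue_i, r.residue_j, r.atoms) for r in detector(small_coil, wider)}
            assert small <= big

    def test_canonical_ordering(self, small_coil):
        for r in detect_all(small_coil):
            assert r.residue_i[:2] < r.residue_j[:2]

    def test_partner_map_unknown_site_errors(self, small_coil):
        with pytest.raises(KeyError):
            partner_map(small_coil, ("C", 1))

    def test_partner_map_aggregates_kinds(self, small_coil):
        pm = partner_map(small_coil, ("A", 4))
        assert set(pm) == {"hbond", "hydrophobic", "salt_bridge"}
        for partners in pm.values():
            for rel in partners.values():
                assert rel in ("inter", "intra")
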