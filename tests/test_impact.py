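import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import pytest

from coilvar.impact import (
    ImpactRecord,
    PipelineError,
    classify_snp,
    mutation_impact,
    run_pipeline,
)
from coilvar.heptad import assign_register
from coilvar.physchem import diff_profiles
from coilvar.rotamers import ClashCriteria, ClashReport, Rotamer, ScanResult
from coilvar.variants import Variant, packaged_catalog
from oracles import snp_verdict_oracle


@dataclass
class _FakeVariant:
    gene: str
    position: int
    wt_aa: str
    mut_aa: str
    category: str = "disease_mutation"


def make_impact(conservation_class, letter, lost_inter, hydropathy_changed, clashes):
    wt, mut = ("L", "T") if hydropathy_changed else ("E", "K")
    rot = Rotamer(mut, (), 1.0, 1)
    report = ClashReport(("A", 479), rot, [(("A", 479, "CB"), ("B", 446, "CB"), 0.7)] * clashes)
    lost_h = {("B", 446): "inter"} if lost_inter else {}
    return ImpactRecord(
        variant=None,
        register_letter=letter,
        role=None,
        conservation_class=conservation_class,
        property_change=diff_profiles(wt, mut),
        lost_hbonds={},
        lost_hydrophobic=lost_h,
        lost_salt_bridges={},
        scan=ScanResult(("A", 479), mut, [report], report),
    )


class TestClassifySnp:
    def test_truth_table_oracle_exhaustive(self):
        """Verdict logic checked against an independent truth table over all
        class x letter x loss x hydropathy (x clash) combinations."""
        snp = Variant("K1", "c.1G>A", "E", 443 + 35, "K", category="snp",
                      diseases=frozenset({"none"}), severity="n/a")
        for cls, letter, lost, hyd, clashes in product(
            " .:*", "abcdefg", (False, True), (False, True), (0, 3)
        ):
            impact = make_impact(cls, letter, lost, hyd, clashes)
            got = classify_snp(snp, impact).verdict
            want = snp_verdict_oracle(cls, letter, lost, hyd, clashes)
            assert got == want, (cls, letter, lost, hyd, clashes)

    def test_evidence_lists_fired_clauses(self):
        snp = Variant("K10", "c.1G>A", "E", 443, "K", category="snp",
                      diseases=frozenset({"none"}), severity="n/a")
        v = classify_snp(snp, make_impact("*", "a", True, False, 4))
        assert v.verdict == "pathogenic_candidate"
        assert set(v.evidence) == {
            "conserved_site",
            "interchain_loss_or_core_hydropathy_change",
            "residual_clashes_or_core_position",
        }
        v2 = classify_snp(snp, make_impact(":", "f", False, False, 0))
        assert v2.verdict == "likely_benign"
        assert v2.evidence == ["conserved_site"]

    def test_disease_mutation_rejected(self):
        mut = Variant("K1", "c.1G>A", "E", 478, "K")
        with pytest.raises(ValueError):
            classify_snp(mut, make_impact("*", "a", True, False, 1))


class TestMutationImpact:
    def test_sequence_mismatch_errors(self, reference_structure, default_cfg):
        reg = assign_register((373, 493), [(479, "a")], [])
        bad = Variant("K1", "c.1G>A", "K", 478, "Q")  # structure has E478
        with pytest.raises(ValueError, match="478"):
            mutation_impact(reference_structure, bad, reg, None, "A")

    def test_identity_substitution_loses_nothing(self, reference_structure):
        """Test-only no-op 'mutation': replacing a residue by itself in the
        rotamer it already occupies must lose no partners."""
        reg = assign_register((373, 493), [(479, "a")], [])
        res = reference_structure.residue("A", 380)
        fake = _FakeVariant("K1", 380, res.aa, res.aa)
        rec = mutation_impact(reference_structure, fake, reg, None, "A")
        assert rec.lost_hbonds == {}
        assert rec.lost_hydrophobic == {}
        assert rec.lost_salt_bridges == {}

    def test_lost_sets_are_subsets_of_wildtype_partners(self, reference_bundle, reference_structure, default_cfg):
        from coilvar.interactions import partner_map

        icrit = default_cfg.interaction_criteria()
        for rec in reference_bundle["impacts"]:
            chain = default_cfg.chain_for_gene(rec.variant.gene)
            wt = partner_map(reference_structure, (chain, rec.variant.position), icrit)
            assert set(rec.lost_hbonds) <= set(wt["hbond"])
            assert set(rec.lost_hydrophobic) <= set(wt["hydrophobic"])
            assert set(rec.lost_salt_bridges) <= set(wt["salt_bridge"])

    def test_e478k_loses_r450_hbond(self, reference_bundle):
        rec = next(r for r in reference_bundle["impacts"] if str(r.variant) == "K1-p.E478K")
        assert ("B", 450) in rec.lost_hbonds
        assert rec.register_letter == "g"
        assert rec.role == "ionic_rim"

    def test_l437p_loses_hydrophobic_partners(self, reference_bundle):
        rec = next(r for r in reference_bundle["impacts"] if str(r.variant) == "K1-p.L437P")
        assert {("B", 403), ("B", 404)} <= set(rec.lost_hydrophobic)
        assert rec.lost_hbonds == {}

    def test_core_disruption_flag_contract(self, reference_bundle):
        for rec in reference_bundle["impacts"] + reference_bundle["snp_impacts"]:
            expected = rec.register_letter in ("a", "d") and (
                "hydropathy" in rec.property_change.changed_axes or bool(rec.lost_hydrophobic)
            )
            assert ("core_disruption" in rec.flags) == expected


class TestPipeline:
    def test_record_counts(self, reference_bundle):
        assert len(reference_bundle["impacts"]) == 21
        assert len(reference_bundle["snp_impacts"]) == 19
        assert len(reference_bundle["verdicts"]) == 19

    def test_e443k_is_the_pathogenic_candidate(self, reference_bundle):
        verdicts = {str(v.variant): v.verdict for v in reference_bundle["verdicts"]}
        assert verdicts["K10-p.E443K"] == "pathogenic_candidate"

    def test_concordance_emitted_for_all_21(self, reference_bundle):
        assert len(reference_bundle["concordance"]) == 21
        for entry in reference_bundle["concordance"].values():
            for kind in ("hydrophobic", "hbond"):
                assert 0.0 <= entry[kind]["jaccard"] <= 1.0

    def test_group4_is_derived_view(self, reference_bundle):
        common = set(reference_bundle["interaction_loss_common"])
        for rec in reference_bundle["impacts"]:
            has_loss = bool(rec.lost_hbonds or rec.lost_hydrophobic or rec.lost_salt_bridges)
            assert (str(rec.variant) in common) == has_loss

    def test_outputs_written(self, reference_bundle, tmp_path):
        # reference_bundle already ran; check a fresh run's files and determinism
        out1 = tmp_path / "run1"
        out2 = tmp_path / "run2"
        run_pipeline(out_dir=out1)
        run_pipeline(out_dir=out2)
        for name in ("impact.tsv", "impact.json", "groups.tsv", "snp_verdicts.tsv", "qc.json"):
            assert (out1 / name).exists()
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        qc = json.loads((out1 / "qc.json").read_text())
        assert qc["allowed_or_better"] >= 0.9

    def test_missing_catalog_stage_error(self, tmp_path):
        with pytest.raises(PipelineError, match=r"\[catalog\]"):
            run_pipeline(
                out_dir=tmp_path / "x",
                overrides={"catalogs": {"mutations": str(tmp_path / "missing.tsv")}},
            )
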