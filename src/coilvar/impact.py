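"""Per-variant structural impact records and the full annotation pipeline.

For each variant the wild-type partner map is compared against the partner
map of the mutant side chain placed in its clash-minimizing rotamer; the
"lost" partner sets, property change, heptad role, conservation class and
per-rotamer clash summary are combined into one record.  A rule-based
verdict triages SNPs: pathogenic candidates must be conserved, lose an
inter-chain interaction (or change hydropathy at a core position) and
either retain clashes in the best rotamer or sit at a core register
position.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._data import read_tsv_rows
from .config import PipelineConfig, load_config, resolve_path
from .conservation import ConservationTrack, column_conservation, map_conservation, read_alignment
from .geometry import angle
from .heptad import RegisterMap, assign_register, role_of
from .interactions import (
    InteractionCriteria,
    _apolar_table,
    _charged_table,
    _hbond_tables,
    partner_map,
)
from .physchem import PropertyChange, diff_profiles
from .rotamers import (
    ClashCriteria,
    Rotamer,
    ScanResult,
    enumerate_rotamers,
    place_rotamer,
    scan_rotamers,
)
from .sidechains import build_side_chain
from .structure import (
    BACKBONE_ATOMS,
    CrickParams,
    Structure,
    build_coiled_coil,
    read_structure,
    write_structure,
)
from .validation import ramachandran_summary
from .variants import Variant, VariantCatalog, group_variants, load_catalog

__all__ = [
    "ImpactRecord",
    "SnpVerdict",
    "PipelineError",
    "mutation_impact",
    "classify_snp",
    "run_pipeline",
    "build_reference_structure",
]

log = logging.getLogger("coilvar")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ImpactRecord:
    variant: Variant
    register_letter: str | None
    role: str | None
    conservation_class: str | None
    property_change: PropertyChange
    lost_hbonds: dict[tuple[str, int], str]
    lost_hydrophobic: dict[tuple[str, int], str]
    lost_salt_bridges: dict[tuple[str, int], str]
    scan: ScanResult
    flags: set[str] = field(default_factory=set)

    @property
    def clash_summary(self) -> list[tuple[int, float, int]]:
        return [
            (r.rotamer.rank, r.rotamer.probability, r.n_clashes) for r in self.scan.reports
        ]

    def lost_any_interchain(self) -> bool:
        return any(
            rel == "inter"
            for lost in (self.lost_hbonds, self.lost_hydrophobic, self.lost_salt_bridges)
            for rel in lost.values()
        )


@dataclass
class SnpVerdict:
    variant: Variant
    verdict: str  # pathogenic_candidate | likely_benign
    evidence: list[str]


def mutation_impact(
    s: Structure,
    v: Variant,
    register: RegisterMap,
    cons: ConservationTrack | None,
    chain_id: str,
    icrit: InteractionCriteria | None = None,
    ccrit: ClashCriteria | None = None,
    top_n: int = 5,
) -> ImpactRecord:
    """Impact record for one variant on a wild-type structure.

    The structure must carry the wild-type residue at the variant site; the
    mutant is evaluated at the clash-minimizing rotamer of the top-``top_n``
    scan (the discrete stand-in for post-minimization placement).
    """
    icrit = icrit or InteractionCriteria()
    ccrit = ccrit or ClashCriteria()
    site = (chain_id, v.position)
    res = s.residue(chain_id, v.position)
    if res.aa != v.wt_aa:
        raise ValueError(
            f"structure/variant mismatch at {chain_id}:{v.position}: "
            f"structure has {res.aa}, variant expects {v.wt_aa}"
        )
    wt_pm = partner_map(s, site, icrit)
    scan = scan_rotamers(s, site, v.mut_aa, ccrit, top_n)
    mutant = place_rotamer(s, site, v.mut_aa, scan.best.rotamer)
    mut_pm = partner_map(mutant, site, icrit)

    lost = {
        kind: {p: rel for p, rel in wt_pm[kind].items() if p not in mut_pm[kind]}
        for kind in ("hbond", "hydrophobic", "salt_bridge")
    }
    letter = register.letter(v.position)
    role = role_of(letter).role if letter else None
    cclass = map_conservation(cons, v.position) if cons is not None else None
    change = diff_profiles(v.wt_aa, v.mut_aa)

    flags: set[str] = set()
    hydropathy_changed = "hydropathy" in change.changed_axes
    if letter in ("a", "d") and (hydropathy_changed or lost["hydrophobic"]):
        flags.add("core_disruption")
    if letter in ("e", "g") and (lost["hbond"] or lost["salt_bridge"]):
        flags.add("rim_disruption")
    if cclass in (":", "*"):
        flags.add("conserved_site")

    return ImpactRecord(
        variant=v,
        register_letter=letter,
        role=role,
        conservation_class=cclass,
        property_change=change,
        lost_hbonds=lost["hbond"],
        lost_hydrophobic=lost["hydrophobic"],
        lost_salt_bridges=lost["salt_bridge"],
        scan=scan,
        flags=flags,
    )


def classify_snp(v: Variant, impact: ImpactRecord) -> SnpVerdict:
    """Rule-based SNP triage.

    pathogenic_candidate iff (1) the site is conserved (':' or '*'), AND
    (2) an inter-chain interaction is lost or hydropathy changes at a core
    position, AND (3) the clash-minimizing rotamer still clashes or the
    site is a core ('a'/'d') position.
    """
    if v.category != "snp":
        raise ValueError(f"classify_snp called on non-SNP variant {v}")
    evidence = []
    c1 = impact.conservation_class in (":", "*")
    if c1:
        evidence.append("conserved_site")
    hydropathy_core = (
        "hydropathy" in impact.property_change.changed_axes
        and impact.register_letter in ("a", "d")
    )
    c2 = impact.lost_any_interchain() or hydropathy_core
    if c2:
        evidence.append("interchain_loss_or_core_hydropathy_change")
    c3 = impact.scan.best.n_clashes > 0 or impact.register_letter in ("a", "d")
    if c3:
        evidence.append("residual_clashes_or_core_position")
    verdict = "pathogenic_candidate" if (c1 and c2 and c3) else "likely_benign"
    return SnpVerdict(v, verdict, evidence)


# ---------------------------------------------------------------------------
# Reference-model construction (build + side-chain posing)
# ---------------------------------------------------------------------------

def _read_chain_sequence(spec: dict) -> str:
    from Bio import SeqIO

    seq_spec = spec["sequence"]
    path = resolve_path(seq_spec["fasta"])
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == seq_spec["record"]:
            return str(rec.seq)
    raise KeyError(f"record {seq_spec['record']} not found in {path}")


def _pose_candidates(s: Structure, site: tuple[str, int], max_rotamers: int):
    res = s.residue(*site)
    backbone = {n: res.coord(n) for n in BACKBONE_ATOMS if n in res.atoms}
    rotamers = enumerate_rotamers(res.aa)[:max_rotamers]
    out = []
    for rot in rotamers:
        atoms = dict(backbone)
        atoms.update(build_side_chain(backbone, res.aa, rot.chi_angles))
        out.append((rot, atoms))
    return res.aa, out


def _target_eval(
    kind: str,
    aa_i: str,
    atoms_i: dict,
    aa_j: str,
    atoms_j: dict,
    icrit: InteractionCriteria,
) -> tuple[float, float]:
    """(deficit, distance): deficit is 0.0 when the posed pair satisfies the
    detector criterion for ``kind`` and the distance shortfall (A) otherwise;
    distance is the relevant minimum distance."""
    if kind == "hydrophobic":
        ap_i = [atoms_i[n] for n in _apolar_table()[aa_i] if n in atoms_i]
        ap_j = [atoms_j[n] for n in _apolar_table()[aa_j] if n in atoms_j]
        if not ap_i or not ap_j:
            return float("inf"), float("inf")
        d = min(float(np.linalg.norm(p - q)) for p in ap_i for q in ap_j)
        return max(0.0, d - icrit.hydrophobic_max_cc), d
    if kind == "hbond":
        donors, acceptors = _hbond_tables()
        best_deficit = float("inf")
        margin = 0.0
        for (aa_d, atoms_d), (aa_a, atoms_a) in (
            ((aa_i, atoms_i), (aa_j, atoms_j)),
            ((aa_j, atoms_j), (aa_i, atoms_i)),
        ):
            for (daa, datom), ant in donors.items():
                if daa != aa_d or datom not in atoms_d or ant not in atoms_d:
                    continue
                for aaa, aatom in acceptors:
                    if aaa != aa_a or aatom not in atoms_a:
                        continue
                    d = float(np.linalg.norm(atoms_d[datom] - atoms_a[aatom]))
                    ok_angle = (
                        angle(atoms_a[aatom], atoms_d[datom], atoms_d[ant])
                        >= icrit.hbond_min_angle
                    )
                    deficit = max(0.0, d - icrit.hbond_max_da)
                    if deficit == 0.0 and not ok_angle:
                        deficit = 0.1  # reachable but mis-oriented
                    best_deficit = min(best_deficit, deficit)
                    if deficit == 0.0:
                        # donor far from the acceptor's CB: the bond forms at
                        # the side-chain tip and is lost if the chain shortens
                        anchor = atoms_a.get("CB", atoms_a["CA"])
                        margin = max(margin, float(np.linalg.norm(atoms_d[datom] - anchor)))
        if best_deficit == float("inf"):
            return best_deficit, best_deficit
        return best_deficit, margin
    if kind == "salt_bridge":
        charged = _charged_table()
        best = float("inf")
        pos_i = [atoms_i[n] for (aa, n), sg in charged.items() if aa == aa_i and sg == "+" and n in atoms_i]
        neg_i = [atoms_i[n] for (aa, n), sg in charged.items() if aa == aa_i and sg == "-" and n in atoms_i]
        pos_j = [atoms_j[n] for (aa, n), sg in charged.items() if aa == aa_j and sg == "+" and n in atoms_j]
        neg_j = [atoms_j[n] for (aa, n), sg in charged.items() if aa == aa_j and sg == "-" and n in atoms_j]
        for group_a, group_b in ((pos_i, neg_j), (neg_i, pos_j)):
            for p in group_a:
                for q in group_b:
                    best = min(best, float(np.linalg.norm(p - q)))
        if best == float("inf"):
            return best, best
        return max(0.0, best - icrit.saltbridge_max), best
    raise ValueError(f"unknown pose target kind {kind!r}")


def pose_sites(s: Structure, groups: list[dict], icrit: InteractionCriteria) -> Structure:
    """Re-pose side chains of the configured site groups so that the listed
    interaction targets are geometrically satisfied where the rotamer
    library allows.

    Deterministic iterated conditional modes: all sites start at their
    top-probability rotamer, then each site in turn adopts the rotamer
    minimizing (unsatisfied targets, total distance deficit, -log prob)
    holding the others fixed, sweeping until convergence.
    """
    out = s
    for group in groups:
        sites = [(str(c), int(r)) for c, r in group["sites"]]
        targets = [
            (t["kind"], (str(t["i"][0]), int(t["i"][1])), (str(t["j"][0]), int(t["j"][1])))
            for t in group["targets"]
        ]
        max_rot = int(group.get("max_rotamers_per_site", 81))
        max_sweeps = int(group.get("max_sweeps", 4))
        fixed_chis = {
            (str(f["site"][0]), int(f["site"][1])): tuple(float(x) for x in f["chi"])
            for f in group.get("fixed_poses", [])
        }
        for site in fixed_chis:
            if site not in sites:
                sites.append(site)
        cands = {site: _pose_candidates(out, site, max_rot) for site in sites}
        for site, chis in fixed_chis.items():
            res = out.residue(*site)
            backbone = {n: res.coord(n) for n in BACKBONE_ATOMS if n in res.atoms}
            atoms = dict(backbone)
            atoms.update(build_side_chain(backbone, res.aa, chis))
            pinned = Rotamer(res.aa, chis, 1.0, 0)
            cands[site] = (res.aa, [(pinned, atoms)])
        by_site: dict[tuple[str, int], list] = {site: [] for site in sites}
        for kind, si, sj in targets:
            if si in by_site:
                by_site[si].append((kind, si, sj))
            if sj in by_site:
                by_site[sj].append((kind, si, sj))

        chosen = {site: 0 for site in sites}  # index into candidate list

        def atoms_of(site):
            return cands[site][1][chosen[site]][1]

        def target_cost(kind, si, sj):
            return _target_eval(
                kind, cands[si][0], atoms_of(si), cands[sj][0], atoms_of(sj), icrit
            )

        # Satisfied contacts are preferred at the outer edge of the cutoff
        # (maximal distance): the reference model's wild-type interactions
        # are then marginal, so a shorter mutant side chain genuinely loses
        # them rather than retaining a grazing contact.
        for _sweep in range(max_sweeps):
            changed = False
            for site in sites:
                best_key, best_idx = None, chosen[site]
                for idx, (rot, _atoms) in enumerate(cands[site][1]):
                    chosen[site] = idx
                    n_unsat, deficit, margin = 0, 0.0, 0.0
                    for kind, si, sj in by_site[site]:
                        df, dist = target_cost(kind, si, sj)
                        if df > 0:
                            n_unsat += 1
                            if df != float("inf"):
                                deficit += df
                        else:
                            margin += dist
                    key = (n_unsat, round(deficit, 9), round(-margin, 9), idx)
                    if best_key is None or key < best_key:
                        best_key, best_idx = key, idx
                if best_idx != chosen[site]:
                    changed = True
                chosen[site] = best_idx
            if not changed:
                break

        unsatisfied = [t for t in targets if target_cost(*t)[0] > 0]
        for site in sites:
            aa, options = cands[site]
            rot, _atoms = options[chosen[site]]
            out = place_rotamer(out, site, aa, rot)
        log.info(
            "posed %d sites (unsatisfied targets: %d/%d%s)",
            len(sites),
            len(unsatisfied),
            len(targets),
            "; " + ", ".join(f"{k} {si}-{sj}" for k, si, sj in unsatisfied) if unsatisfied else "",
        )
    return out


def build_reference_structure(cfg: PipelineConfig, seed: int | None = None) -> Structure:
    """Build (or read) the configured heterodimer and apply pose groups."""
    if cfg.source == "read":
        if cfg.pdb_path is None:
            raise PipelineError("structure", "source 'read' requires structure.pdb_path")
        return read_structure(cfg.pdb_path)
    if cfg.source != "build":
        raise PipelineError("structure", f"unknown structure source {cfg.source!r}")
    ids = cfg.chain_ids
    if len(ids) != 2:
        raise PipelineError("structure", "exactly two chains must be configured")
    spec_a, spec_b = cfg.chain(ids[0]), cfg.chain(ids[1])
    params = cfg.crick_params()
    s = build_coiled_coil(
        _read_chain_sequence(spec_a),
        _read_chain_sequence(spec_b),
        params,
        tuple(spec_a["register_anchor"]),
        noise_sd=cfg.noise_sd,
        seed=cfg.seed if seed is None else seed,
        start_a=int(spec_a["start"]),
        start_b=int(spec_b["start"]),
        register_anchor_b=tuple(spec_b["register_anchor"]),
        phase_b=spec_b.get("phase"),
        z_offset_b=float(spec_b.get("z_offset", 0.0)),
        chain_ids=(ids[0], ids[1]),
    )
    if cfg.pose_groups:
        s = pose_sites(s, cfg.pose_groups, cfg.interaction_criteria())
    return s


# ---------------------------------------------------------------------------
# Concordance vs. the packaged published lost-partner table
# ---------------------------------------------------------------------------

def _load_table1(path) -> dict[tuple[str, str], dict[str, set[tuple[str, int]]]]:
    out = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [
        ln.split("\t") for ln in lines if ln.strip() and not ln.lstrip().startswith("#")
    ]
    header = rows[0]
    assert header[:2] == ["gene", "protein"]
    for row in rows[1:]:
        row = row + [""] * (4 - len(row))
        gene, protein, hyd, hb = row[:4]

        def parse(cell):
            out_set = set()
            for tok in cell.split("|"):
                tok = tok.strip()
                if tok:
                    g, num = tok.split(":")
                    out_set.add((g, int(num)))
            return out_set

        out[(gene, protein)] = {"hydrophobic": parse(hyd), "hbond": parse(hb)}
    return out


def jaccard_concordance(
    impacts: list[ImpactRecord], table_path, gene_of_chain: dict[str, str]
) -> dict[str, dict]:
    """Per-variant Jaccard overlap between computed lost-partner sets and
    the packaged published sets (hydrophobic and hbond kinds)."""
    table = _load_table1(table_path)
    report = {}
    for rec in impacts:
        key = (rec.variant.gene, rec.variant.protein)
        expected = table.get(key)
        if expected is None:
            continue
        entry = {}
        for kind, lost in (("hydrophobic", rec.lost_hydrophobic), ("hbond", rec.lost_hbonds)):
            ours = {(gene_of_chain[c], r) for (c, r) in lost}
            ref = expected[kind]
            union = ours | ref
            entry[kind] = {
                "computed": sorted(f"{g}:{r}" for g, r in ours),
                "published": sorted(f"{g}:{r}" for g, r in ref),
                "jaccard": (len(ours & ref) / len(union)) if union else 1.0,
            }
        report[str(rec.variant)] = entry
    return report


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _registers(cfg: PipelineConfig) -> dict[str, RegisterMap]:
    out = {}
    for cid in cfg.chain_ids:
        spec = cfg.chain(cid)
        start = int(spec["start"])
        seq = _read_chain_sequence(spec) if cfg.source == "build" else None
        end = int(spec.get("end", start + (len(seq) - 1 if seq else 0)))
        anchors = [tuple(spec["register_anchor"])]
        stutters = [tuple(x) for x in spec.get("stutters", [])]
        out[spec["gene"]] = assign_register((start, end), anchors, stutters)
    return out


def _conservation_tracks(cfg: PipelineConfig) -> dict[str, ConservationTrack]:
    out = {}
    for cid in cfg.chain_ids:
        spec = cfg.chain(cid)
        gene = spec["gene"]
        aln = read_alignment(cfg.alignment_path(gene))
        out[gene] = column_conservation(aln, reference_index=0, reference_start=int(spec["start"]))
    return out


def _impact_row(rec: ImpactRecord) -> dict:
    def fmt_lost(lost):
        return "|".join(f"{c}:{r}({rel})" for (c, r), rel in sorted(lost.items()))

    return {
        "variant": str(rec.variant),
        "gene": rec.variant.gene,
        "protein": rec.variant.protein,
        "category": rec.variant.category,
        "diseases": "|".join(sorted(rec.variant.diseases)),
        "severity": rec.variant.severity,
        "register": rec.register_letter or "-",
        "role": rec.role or "-",
        "conservation": rec.conservation_class or "-",
        "changed_axes": "|".join(sorted(rec.property_change.changed_axes)) or "-",
        "lost_hbonds": fmt_lost(rec.lost_hbonds) or "-",
        "lost_hydrophobic": fmt_lost(rec.lost_hydrophobic) or "-",
        "lost_salt_bridges": fmt_lost(rec.lost_salt_bridges) or "-",
        "best_rotamer_rank": rec.scan.best.rotamer.rank,
        "best_n_clashes": rec.scan.best.n_clashes,
        "clash_summary": "|".join(
            f"r{rank}:p={prob:.4f}:c={n}" for rank, prob, n in rec.clash_summary
        ),
        "flags": "|".join(sorted(rec.flags)) or "-",
    }


def _write_tsv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("", encoding="utf-8")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(
    config: str | Path | PipelineConfig | None = None,
    out_dir: str | Path = "coilvar_out",
    seed: int | None = None,
    overrides: dict | None = None,
) -> dict:
    """Run the full annotation pipeline and write the report bundle.

    Emits impact.tsv/impact.json (per-variant records incl. concordance),
    groups.tsv, snp_verdicts.tsv, qc.json and reference.pdb under
    ``out_dir``; returns the in-memory bundle.
    """
    if isinstance(config, PipelineConfig):
        cfg = config
        if overrides:
            raise ValueError("pass overrides together with a path, not a PipelineConfig")
    else:
        cfg = load_config(config, overrides)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        muts = load_catalog(cfg.catalog_path("mutations"))
        snps = load_catalog(cfg.catalog_path("snps"))
    except Exception as exc:
        raise PipelineError("catalog", str(exc)) from exc

    try:
        structure = build_reference_structure(cfg, seed=seed)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("structure", str(exc)) from exc

    try:
        registers = _registers(cfg)
        tracks = _conservation_tracks(cfg)
    except Exception as exc:
        raise PipelineError("annotation", str(exc)) from exc

    icrit = cfg.interaction_criteria()
    ccrit = cfg.clash_criteria()
    gene_of_chain = {cid: cfg.chain(cid)["gene"] for cid in cfg.chain_ids}

    def impact_of(v: Variant) -> ImpactRecord:
        chain_id = cfg.chain_for_gene(v.gene)
        return mutation_impact(
            structure, v, registers[v.gene], tracks[v.gene], chain_id, icrit, ccrit, cfg.top_n
        )

    try:
        impacts = [impact_of(v) for v in muts]
        snp_impacts = [impact_of(v) for v in snps]
        verdicts = [classify_snp(v, rec) for v, rec in zip(snps, snp_impacts)]
    except Exception as exc:
        raise PipelineError("impact", str(exc)) from exc

    try:
        groups = group_variants(muts)
        interaction_loss_common = sorted(
            str(r.variant)
            for r in impacts
            if r.lost_hbonds or r.lost_hydrophobic or r.lost_salt_bridges
        )
        concordance = jaccard_concordance(impacts, cfg.table1_path, gene_of_chain)
        qc = ramachandran_summary(structure)
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    # ---- outputs ----------------------------------------------------------
    impact_rows = [_impact_row(r) for r in impacts + snp_impacts]
    _write_tsv(out_dir / "impact.tsv", impact_rows)
    impact_json = {
        "records": impact_rows,
        "concordance": concordance,
        "interaction_loss_common": interaction_loss_common,
    }
    (out_dir / "impact.json").write_text(
        json.dumps(impact_json, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    group_rows = [
        {
            "group": g.group_id,
            "site": f"{g.site[0]}:{g.site[1]}" if g.site else "-",
            "members": "|".join(sorted(str(v) for v in g.members)),
        }
        for g in groups
    ] + [
        {
            "group": "interaction_loss_common",
            "site": "-",
            "members": "|".join(interaction_loss_common),
        }
    ]
    _write_tsv(out_dir / "groups.tsv", group_rows)

    verdict_rows = [
        {
            "variant": str(v.variant),
            "verdict": v.verdict,
            "evidence": "|".join(v.evidence) or "-",
        }
        for v in verdicts
    ]
    _write_tsv(out_dir / "snp_verdicts.tsv", verdict_rows)

    qc_payload = {
        "n_defined": qc.n_defined,
        "fractions": {k: round(v, 6) for k, v in qc.fractions.items()},
        "allowed_or_better": round(qc.allowed_or_better, 6),
    }
    (out_dir / "qc.json").write_text(
        json.dumps(qc_payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    write_structure(structure, out_dir / "reference.pdb")

    return {
        "structure": structure,
        "impacts": impacts,
        "snp_impacts": snp_impacts,
        "verdicts": verdicts,
        "groups": groups,
        "interaction_loss_common": interaction_loss_common,
        "concordance": concordance,
        "qc": qc_payload,
    }
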