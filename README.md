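# coilvar

Structural impact analysis of missense variants on a two-chain coiled-coil
heterodimer, exercised end to end on a synthetic Crick-parameterized model
of the keratin K1/K10 2B domain.

The pipeline combines:

* **variants** — a curated catalog of 2B-domain missense disease mutations
  and SNPs (packaged TSV fixtures), HGVS-style parsing, duplicate
  collapsing, and genotype–phenotype grouping.
* **physchem** — three-axis amino-acid classification (structural class,
  hydropathy, charge) with wild-type/mutant differencing and a literal
  override layer that reproduces the published table labels verbatim.
* **structure** — PDB I/O, Kabsch superposition, and a synthetic
  coiled-coil generator: an ideal alpha-helix backbone (cylinder parameters
  extracted from an internally built reference helix) wound onto a
  supercoil of configurable radius/pitch, heptad phases anchored so core
  positions face the interface, side chains placed from ideal internal
  coordinates (bundled chemical-component templates) in their most
  frequent rotamer, with optional seeded Gaussian coordinate noise.
* **heptad** — anchor-driven a–g register assignment with stutter support
  and the core/rim/surface position-role model.
* **interactions** — geometric detectors for hydrogen bonds, hydrophobic
  contacts, salt bridges, and aromatic interactions, plus per-site partner
  maps tagged inter/intra-chain.
* **rotamers** — a discrete backbone-independent rotamer library (3 bins
  per chi), side-chain placement, van-der-Waals clash counting, and a
  rank-ordered clash scan whose clash-minimizing rotamer stands in for
  forcefield minimization.
* **conservation** — Clustal-style three-tier column conservation classes
  from multiple sequence alignments (packaged keratin-family fixtures).
* **impact** — the per-variant record: property change, lost partners
  (wild type vs. best mutant placement), clash summary, register letter,
  conservation class, flags, a rule-based SNP pathogenicity verdict, and a
  Jaccard concordance report against the packaged published interaction
  table.
* **validation** — backbone dihedrals, four-tier Ramachandran region QC,
  and a 2.8 Å RMSD gate.

## Command line

```sh
coilvar all  --out-dir out        # full pipeline on the packaged reference model
coilvar impact --top-n 5          # per-variant impact records
coilvar snps                      # rule-based SNP triage
coilvar groups                    # genotype-phenotype groups
coilvar qc --structure model.pdb  # Ramachandran QC of a user model
coilvar build                     # write the synthetic reference model PDB
```

Outputs: `impact.tsv` / `impact.json` (records + concordance),
`groups.tsv`, `snp_verdicts.tsv`, `qc.json`, `reference.pdb`.  The default
configuration (packaged at `src/coilvar/data/default_config.yaml`) can be
overridden with `--config my.yaml`; reruns with the same config and seed
are byte-identical.

## Notes on the reference model

The packaged reference model is synthetic: real variant positions are
threaded into heptad-patterned 2B sequences, chain B's register phase is
rotated so its d/g face packs the interface, and a configured set of
wild-type side-chain poses (iterated conditional modes over the rotamer
library, preferring contacts at the outer edge of each criterion) realizes
the published wild-type interaction network.  Exact reproduction of every
published interaction cell is not promised — the concordance report
quantifies the overlap per variant.
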