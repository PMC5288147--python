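# Default pipeline configuration: the packaged synthetic K1/K10 2B
# heterodimer reference model.  Chain A threads the K1 2B range (373-493),
# chain B the K10 2B range (340-460); registers are anchored at K1:479='a'
# and K10:443='a'.  phase 51 for chain B rotates its register so the d/g
# face packs the interface, which is what makes the published wild-type
# partner pairs geometrically attainable.  coilvar://NAME refers to
# packaged data files.

structure:
  source: build          # build | read
  pdb_path: null
  crick:
    supercoil_radius: 4.9
    supercoil_pitch: 140.0
    residues_per_turn: 3.5
    rise_per_residue: 1.51
    phase_a: 26.0
  noise_sd: 0.0
  seed: 0

chains:
  A:
    gene: K1
    start: 373
    sequence: {fasta: "coilvar://k1_k10_2b.fasta", record: K1_2B}
    register_anchor: [479, a]
    stutters: []
  B:
    gene: K10
    start: 340
    sequence: {fasta: "coilvar://k1_k10_2b.fasta", record: K10_2B}
    register_anchor: [443, a]
    phase: 51.0
    z_offset: 0.0
    stutters: []

catalogs:
  mutations: "coilvar://k1_k10_mutations.tsv"
  snps: "coilvar://k1_k10_snps.tsv"

conservation:
  alignments:
    K1: "coilvar://k1_family_alignment.fasta"
    K10: "coilvar://k10_family_alignment.fasta"

concordance:
  table: "coilvar://table1_interactions.tsv"

interaction_criteria:
  hbond_max_da: 3.5
  hbond_min_angle: 120.0
  hydrophobic_max_cc: 4.5
  saltbridge_max: 4.0
  aromatic_max_centroid: 6.0

clash_criteria:
  overlap_cutoff: 0.6
  hbond_allowance: 0.4
  exclude_bonded_within: 4

top_n: 5

# Wild-type side-chain poses of the reference model: one coordinated group
# realizing the published wild-type interaction network around the 2B
# interface (iterated conditional modes over the rotamer library).
pose_groups:
  - sites:
      - [A, 437]
      - [B, 403]
      - [B, 404]
    targets:
      - {kind: hydrophobic, i: [A, 437], j: [B, 403]}
      - {kind: hydrophobic, i: [A, 437], j: [B, 404]}
  - sites:
      - [A, 468]
      - [A, 471]
      - [A, 472]
      - [A, 475]
      - [A, 476]
      - [A, 478]
      - [A, 479]
      - [A, 482]
      - [A, 485]
      - [A, 486]
      - [B, 439]
      - [B, 442]
      - [B, 443]
      - [B, 445]
      - [B, 446]
      - [B, 449]
      - [B, 450]
      - [B, 452]
      - [B, 453]
    targets:
      - {kind: hbond, i: [A, 478], j: [B, 450]}
      - {kind: hydrophobic, i: [A, 479], j: [B, 442]}
      - {kind: hydrophobic, i: [A, 479], j: [B, 445]}
      - {kind: hydrophobic, i: [A, 479], j: [B, 446]}
      - {kind: hydrophobic, i: [A, 482], j: [B, 446]}
      - {kind: hydrophobic, i: [A, 482], j: [B, 450]}
      - {kind: hbond, i: [A, 482], j: [B, 450]}
      - {kind: hydrophobic, i: [A, 485], j: [B, 453]}
      - {kind: hydrophobic, i: [A, 486], j: [B, 449]}
      - {kind: hydrophobic, i: [A, 486], j: [B, 453]}
      - {kind: hydrophobic, i: [B, 439], j: [A, 468]}
      - {kind: hydrophobic, i: [B, 439], j: [A, 471]}
      - {kind: hydrophobic, i: [B, 439], j: [A, 475]}
      - {kind: hbond, i: [B, 439], j: [B, 443]}
      - {kind: hydrophobic, i: [B, 442], j: [A, 472]}
      - {kind: hydrophobic, i: [B, 442], j: [A, 475]}
      - {kind: hydrophobic, i: [B, 442], j: [A, 476]}
      - {kind: hydrophobic, i: [B, 443], j: [A, 475]}
      - {kind: hydrophobic, i: [B, 446], j: [A, 478]}
      - {kind: hydrophobic, i: [B, 452], j: [A, 486]}
    # K10 K439 is pinned reaching up along the interface: this reproduces the
    # published picture in which the mutant lysine at K10:443 clashes with
    # K439 in its most probable rotamers and must relax to a rotamer that
    # abandons the K1:475 hydrophobic contact.
    # K1:475 and K10:443 are pinned so their hydrophobic contact runs through
    # the Glu CG (not the backbone-fixed CB): a lysine placed at 443 in its
    # clash-relieved trans rotamer points away and the contact is lost.
    fixed_poses:
      - {site: [B, 439], chi: [180.0, -60.0, 60.0, 60.0]}
      - {site: [A, 475], chi: [-60.0, 60.0]}
      - {site: [B, 443], chi: [-60.0, 180.0, 180.0]}
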