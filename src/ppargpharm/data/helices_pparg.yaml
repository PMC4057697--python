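# Helix ranges for the receptor ligand-binding domain, author numbering
# 206-477.  Frozen from literature-consistent assignments; recompute from a
# structure with interactions.compute_helix_annotation when coordinates are
# available.  "vicinity" spans the H10/11-H12 linker through the chain
# terminus and defines the focus region of the activation-helix contact
# analysis.
ranges:
  H1: [207, 219]
  H2: [225, 232]
  H2p: [238, 244]
  H3: [280, 306]
  H4: [309, 321]
  H5: [322, 337]
  beta-sheet: [338, 352]
  H6: [353, 360]
  H7: [364, 380]
  H8: [382, 390]
  H9: [393, 405]
  H10: [406, 428]
  H11: [429, 449]
  H12: [469, 473]
vicinity: [450, 477]
h12: H12
anchors:
  - {label: H3, resnum: 285}
  - {label: H3, resnum: 286}
  - {label: H3, resnum: 288}
  - {label: H3, resnum: 289}
  - {label: H4, resnum: 319}
  - {label: H5, resnum: 323}
  - {label: H5, resnum: 324}
  - {label: H5, resnum: 327}
  # commonly assigned to the beta-sheet region; logged, not enforced
  - {label: H5, resnum: 342, strict: false}
  - {label: H11, resnum: 449}
  - {label: H12, resnum: 473}
  - {label: after H12, resnum: 474}
  - {label: after H12, resnum: 477}
  - {label: H10/11-H12 linker, resnum: 466}
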