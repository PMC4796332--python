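# Default 19-SNP intronic panel configuration.
#
# Only nine locus ids here are real rs identifiers from the studied intronic
# region (the five core-motif SNPs, the region-1 boundary rs149306391, the
# region-2 boundaries rs4953354/rs7586141, and rs150877473); the remaining ten
# ids (syn_*) are SYNTHETIC placeholders, as are all ancestral/derived base
# assignments except the core motif (derived A,G,G,A,A -> "AGGAA") and
# rs150877473 (ancestral C, derived G).  Positions are synthetic but ordered.
# Replace this file with a fully specified panel when real assay metadata is
# available.
loci:
  - {id: rs115321619, ancestral: G, derived: A, pos: 46577000, core: true}
  - {id: rs73926263,  ancestral: A, derived: G, pos: 46577600, core: true}
  - {id: rs73926264,  ancestral: A, derived: G, pos: 46578100, core: true}
  - {id: rs73926265,  ancestral: G, derived: A, pos: 46578700, core: true}
  - {id: rs55981512,  ancestral: G, derived: A, pos: 46579400, core: true}
  - {id: syn_r1_a,    ancestral: C, derived: T, pos: 46580300, core: false}
  - {id: syn_r1_b,    ancestral: T, derived: C, pos: 46581200, core: false}
  - {id: syn_r1_c,    ancestral: G, derived: A, pos: 46582100, core: false}
  - {id: rs149306391, ancestral: C, derived: T, pos: 46583000, core: false}
  - {id: rs4953354,   ancestral: A, derived: G, pos: 46585000, core: false}
  - {id: syn_r2_a,    ancestral: G, derived: C, pos: 46586500, core: false}
  - {id: syn_r2_b,    ancestral: T, derived: A, pos: 46588000, core: false}
  - {id: syn_r2_c,    ancestral: C, derived: G, pos: 46589500, core: false}
  - {id: rs7586141,   ancestral: T, derived: C, pos: 46591000, core: false}
  - {id: syn_r3_a,    ancestral: A, derived: T, pos: 46593000, core: false}
  - {id: rs150877473, ancestral: C, derived: G, pos: 46594500, core: false}
  - {id: syn_r3_b,    ancestral: G, derived: T, pos: 46596000, core: false}
  - {id: syn_r3_c,    ancestral: C, derived: A, pos: 46597500, core: false}
  - {id: syn_r3_d,    ancestral: T, derived: G, pos: 46599000, core: false}
regions:
  region1: [rs115321619, rs149306391]
  region2: [rs4953354, rs7586141]
  region3: [syn_r3_a, syn_r3_d]
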