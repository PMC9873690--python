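# Default BbZIP transmembrane topology (author numbering, editable).
#
# Helix boundaries are implementation defaults bracketing the residues whose
# helix membership is established (e.g. the a3-a4 loop at 149-158, M99/A102/
# S106 in a2, H177/P180/E181/A184 in a4, Q207-A218 in a5, V272-P279 in a7).
# Treat this file as input: adjust ranges to your structure annotation.
#
# extracellular_end: which end of the residue range faces the extracellular
# side. The amphipathic a0a sits on the cytosolic face, so a0 runs in->out
# and the eight-helix core alternates from a1 (out->in) onward; inverted
# repeat mates (a1/a6, a2/a7, a3/a8, a4/a5) have opposite orientations.
segments:
  - {name: a0a, start: 7,   end: 21,  extracellular_end: end}
  - {name: a0,  start: 27,  end: 47,  extracellular_end: end}
  - {name: a1,  start: 55,  end: 78,  extracellular_end: start}
  - {name: a2,  start: 84,  end: 113, extracellular_end: end}
  - {name: a3,  start: 118, end: 148, extracellular_end: start}
  - {name: a4,  start: 159, end: 185, extracellular_end: end}
  - {name: a5,  start: 197, end: 221, extracellular_end: start}
  - {name: a6,  start: 228, end: 250, extracellular_end: end}
  - {name: a7,  start: 258, end: 281, extracellular_end: start}
  - {name: a8,  start: 289, end: 305, extracellular_end: end}
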