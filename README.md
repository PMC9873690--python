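# tmelevate

Conformational analysis toolkit for **elevator-type membrane transporters** —
proteins in which a *transport domain* carrying the substrate site slides as a
rigid body against a static *scaffold domain* to alternate access between the
two membrane faces.

Given two conformations of a transporter (or one conformation plus its
inverted-repeat definitions), the pipeline assembles the full evidence chain
for an elevator mechanism:

1. **Rigid-body domain decomposition** (`rigid_body`) — least-squares (Kabsch)
   superposition per helix, exact two-domain partitioning of the helix bundle
   by minimizing the summed squared CA residual over bipartitions, and
   screw-axis (axis / angle / pitch / hinge-point) characterization of the
   interdomain motion.
2. **Repeat-swap modelling** (`repeat_swap`) — thread each inverted-repeat TM
   onto its symmetry mate's backbone to generate the opposite-conformation
   model, and measure the vertical translocation of the transport site along
   the membrane normal.
3. **Coupling-contact consistency** (`contact_analysis`) — filter predicted
   evolutionary-coupling contacts (probability > 0.75 by default), map them
   onto helices and domains, and classify each against one or more structures
   by CA–CA distance (`consistent` / `inconsistent` / `dimer-candidate` /
   `ambiguous`), plus a census of the smooth, small-residue-rich domain
   interface.
4. **Crosslink design** (`crosslink_design`) — screen cross-domain residue
   pairs whose CB–CB distance is within linker reach (7.8 Å for S-Hg-S, 6.0 Å
   for a disulfide) in exactly one conformation, with an orientation cone that
   rejects side chains facing away from their partner: these pairs *report*
   the elevator motion in crosslinking gels.
5. **Transport-site geometry** (`transport_site`) — binuclear metal center
   (M1/M2) chelator distances and the three-group classification of
   apo-vs-holo rearrangement (`unchanged` / `side-chain-reoriented` /
   `backbone-shifted`).
6. **Synthetic ground truth** (`synthetic_data`) — noisy multi-helix bundles
   with planted block rotations, planted contact lists, and a full synthetic
   inverted-repeat elevator stand-in, so every stage is testable without any
   download.

The default residue tables (TM topology, metal-site chelators M99, H177,
N178, E181, Q207, E211 / E181, D208, E240 with bridging E181) describe BbZIP,
a bacterial ZIP-family (SLC39) divalent metal importer, but every table is an
editable input.

## Worked example

Generate the synthetic elevator study and run the pipeline over it:

```bash
tmelevate --config seed.yaml synth      # writes fixtures/ (PDBs, topology, contacts, alignment)
tmelevate --config run.yaml compare
tmelevate --config run.yaml swap
tmelevate --config run.yaml site
```

with `run.yaml` pointing `ifc`/`apo` at the generated structures (see
`tmelevate.cli` docstring for the full config schema). Output:

```
domain motion: IFC vs apo
  overall CA RMSD   :   1.32 A
  TM-core CA RMSD   :   1.32 A
  Domain I  RMSD    :   0.23 A  (a1,a4,a5,a6)
  Domain II RMSD    :   0.22 A  (a2,a3,a7,a8)
  interdomain rot.  :   9.03 deg
  hinge near        : a6 end residue 600

site translocation: +6.94 A (+ = extracellular)

 residue residue_name  ca_shift  functional_shift                 class
     210          MET  2.279089          2.202826      backbone-shifted
     408          HIS  1.829259          1.675609      backbone-shifted
     ...
     610          GLU  0.160757          0.054863             unchanged
```

Reading this: the overall CA RMSD (1.32 Å) is several times larger than
either within-domain RMSD (≈ 0.22 Å), the signature of two internally rigid
domains that moved relative to each other — here by 9.0° about a hinge at the
extracellular end of helix a6, exactly the rotation the generator planted.
The repeat-swap model lifts the transport-site centroid by +6.9 Å toward the
extracellular side (+8.0 Å for the chelators on the transport domain; the one
scaffold-side chelator stays put and dilutes the centroid). The site report
classifies each chelator's apo-state rearrangement: the two residues whose
backbone drifts, three whose side chains swing away, and three that hold
their geometry — the planted disassembly pattern of the primary metal site.

The same commands run on real coordinates by pointing the config at deposited
PDB files and a repeat-alignment FASTA.

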