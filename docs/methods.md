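# Methods

## Scope and model

The package analyses the conformational cycle of elevator-type membrane
transporters: a transport domain (here labelled Domain I) carrying the
substrate site slides as a rigid body against a static scaffold domain
(Domain II). Four independent lines of computational evidence are produced
from coordinates alone: (i) a two-domain rigid-body decomposition of the
change between two solved conformations, (ii) an opposite-conformation model
built by repeat-swap threading of the internal inverted repeats, (iii) the
consistency of predicted evolutionary-coupling contacts with each available
conformation, and (iv) geometric design of cysteine crosslink pairs that can
trap one conformation. All distances are Å, angles degrees, residue numbers
author numbering as deposited (never renumbered).

## Rigid-body machinery

**Superposition.** Least-squares rigid superposition uses the closed-form
Kabsch/SVD solution with the reflection guard (determinant sign on the
smallest singular value). RMSD is the post-fit residual root mean square.
Inputs must contain ≥ 3 non-collinear paired points; collinear input raises
rather than silently returning one of the degenerate optima.

**Rotation angle.** Computed as `atan2(|skew(R)|/2, (trace(R)−1)/2)`, which
is algebraically the arccos-of-trace angle but numerically stable near 0°
(round-trip of a rotation with its inverse returns 0° to 1e-9, which the
arccos form cannot do).

**Screw decomposition.** The axis direction is the unit eigenvector of R for
eigenvalue 1 (sign fixed against the skew part), pitch is the translation
projected on the axis, and the axis point is the minimum-norm least-squares
solution of `(I − R) p = t⊥`. The reported "hinge" is this axis point plus
the nearest helix-terminal CA, which turns a verbal hinge location ("the
extracellular end of helix X") into a checkable quantity. Transforms with
rotation < 0.5° are rejected as ill-conditioned for axis extraction.

**Domain partitioning.** Per-helix transforms between the two conformations
are clustered by the dissimilarity `angle(R₁R₂ᵀ) + λ·|t₁ − t₂|` (λ = 1 °/Å).
A single-helix fit only weakly constrains rotation about the helix's own
axis, so this clustering is used solely to decide whether there is any
relative motion at all: if average linkage merges everything below τ = 3
°-equivalents, a single-domain partition is returned. Otherwise the
two-domain assignment is found by exact search: for bundles of ≤ 16 helices
every bipartition is scored by the summed squared CA residual of its two
domain-level superpositions (computed from per-helix sufficient statistics,
so the search is O(2ⁿ) cheap 3×3 SVDs) and the minimizer wins; larger
bundles fall back to iterative reassignment from a two-cluster seeding. The
domain containing the anchor helix (default `a4`, which carries most metal
chelators in ZIP transporters) is labelled Domain I. λ and τ remain exposed
parameters.

**Interdomain motion report.** Per-domain RMSDs come from within-domain
superpositions; the interdomain rotation is the rotation angle of the
Domain-I transform measured after aligning the models on Domain II CA atoms
(the scaffold frame of an elevator mechanism). The report carries both the
all-shared-CA RMSD and the TM-core-only RMSD, since published selections are
often ambiguous between the two.

## Repeat-swap threading

Inverted-repeat membrane proteins encode both alternating-access states in
one structure. Given an aligned-FASTA residue pairing between repeat mates
(one record pair per TM pairing, headers `><helix> mate=<helix>
start=<residue>`; gap columns pair nothing), each aligned residue keeps its
identity and number but adopts the backbone (N, CA, C, O) coordinates of its
mate; CB comes from the mate when present, else from ideal tetrahedral
geometry. The pairing is validated as an involution, so applying the swap
twice restores the input backbone exactly — a property the tests assert at
1e-6 Å. TM stretches that cannot be aligned are completed as ideal α-helices
(rise 1.5 Å, 100°/residue): an ideal helix with a three-residue overlap is
superposed onto the nearest threaded neighbours and its extension supplies
the missing backbone, flagged low-confidence and excluded from downstream
candidate enumeration. Inter-TM loops are omitted and recorded as chain
breaks; no refinement, loop building or side-chain modelling is attempted —
the rigid-body geometry under test is set by the threading alone.

**Site translocation.** The swapped model is superposed onto the input over
scaffold (Domain II) CA atoms and the site's CA-centroid displacement is
projected onto the membrane normal (positive = extracellular). The membrane
normal is the dominant principal direction of the per-helix axis unit
vectors (each helix axis is the principal component of its CA cloud,
oriented by the topology's declared extracellular end); the frame origin is
the TM CA centroid. The site residue set is an argument, so metal-proximal
subsets or single residues can be measured the same way.

## Contact consistency and interface census

Coupling tables are consumed as CSV (`i, A_i, j, A_j, probability` with a
configurable alias map), deduplicated to `i < j`. Filtering keeps
interhelical records with probability > 0.75 (configurable) and counts them
per helix pair and per domain type. Against each structure a contact is
measured as CA–CA distance: *consistent* if ≤ 8 Å in any structure,
*inconsistent* if > 10 Å in all structures where measurable, otherwise
*ambiguous*; the band between the two thresholds avoids hard calls on
borderline geometry. Inconsistent pairs lying wholly in the scaffold domain
are promoted to *dimer-candidate*, since scaffold-mediated dimers can
satisfy them across protomers. CA distances (not CB or heavy-atom minima)
match the convention in which such tables are usually reported; both
thresholds are parameters.

The domain-interface census marks a residue interfacial when its CB (virtual
for Gly) lies within 4.5 Å of any CB across the domain boundary, and reports
the fraction of small residues (Gly/Ala/Ser) — the smooth-interface
signature of sliding domains. Cutoff sensitivity over 4–6 Å is available as
a one-call table.

## Crosslink reporter design

For a candidate pair the CB–CB distance is computed in both conformations;
feasibility means distance ≤ linker reach (7.8 Å for a mercury S-Hg-S
bridge; 6.0 Å preset for a direct disulfide). The orientation filter
requires, on both residues, that the CA→CB vector make ≤ 90° with the
CA→CA(partner) direction — a geometric proxy for "the side chain faces its
partner" that correctly rejects residues on the far face of their helix.
Verdicts: *reporter* (feasible in exactly one conformation, facing there),
*orientation-blocked* (feasible in one, facing away), *never-* /
*always-feasible*. Without an explicit candidate list all cross-domain pairs
resolved in both conformations are enumerated, minus low-confidence rebuilt
residues. Verdict feasibility is monotone in linker reach by construction.

## Transport-site geometry

The binuclear metal center is described by its chelator sets (M1, M2, and
the bridging carboxylate common to both). Site positions come from metal
hetero records when present; for an apo structure they are transferred from
a metal-bound reference superposed on transport-domain CA atoms. Side-chain
functional positions use a fixed table (His: ring N nearer the site;
Glu/Asp: carboxylate-oxygen centroid; Met SD; Asn OD1; Gln OE1; Ser OG; CB
fallback when side-chain atoms are unresolved). Apo-vs-holo comparison
superposes the apo model onto the holo model over Domain I (isolating
site-local rearrangement from the whole-domain motion) and classifies each
chelator: *unchanged* (CA shift < t₁ = 1.0 Å and functional shift < t₂ =
1.5 Å), *side-chain-reoriented* (CA < t₁, functional ≥ t₂),
*backbone-shifted* (CA ≥ t₁). Raising t₁ can only demote backbone-shifted
calls, never create them.

## Synthetic data: what it emulates and what it does not

`build_bundle` emits two conformations of an ideal-geometry helix bundle.
Helices are built residue-by-residue from canonical backbone covalent
parameters at α-helical torsions (φ = −57°, ψ = −47°), giving 3.80 Å CA–CA
steps and ~1.5 Å rise; CB atoms are ideal tetrahedral. Defaults: 8 helices
of 24 residues on a ring with the canonical ~9.4 Å helix-packing distance,
alternating orientations. A chosen helix subset receives a planted rigid
motion in conformation B, and independent Gaussian noise (default σ = 0.2 Å,
emulating coordinate error) is added per atom per conformation. Everything
is bit-reproducible from (spec, seed); one generator per call, no global
state.

`elevator_study` builds the full stand-in for an inverted-repeat elevator
transporter: two four-helix repeats related by an exact two-fold axis in the
membrane plane, with the transport domain parked 4 Å below its symmetric
position. Because repeat-swap threading of a C2-related bundle maps the
structure onto its symmetry image, the parking offset is what the swap model
recovers as conformational change — a vertical site translocation of
exactly twice the offset (+8 Å), which is how the generator plants a known
elevator slide without hand-placing an outward-facing model. The apo state
adds a 9° rotation of the transport domain about a hinge at the
extracellular end of helix a6 plus planted per-residue site rearrangements
(three chelators untouched, three side-chain swings, two backbone drifts),
mirroring the disassembly pattern expected on metal release.

The generators emulate rigid-body geometry and coordinate noise only: no
side chains beyond one functional atom per chelator, no loops, no membrane,
no B-factors, no sequence realism beyond a small-residue-rich pattern.
Passing tests therefore demonstrate the correctness and noise robustness of
the geometric machinery — not performance on crystallographic artefacts
(alternative conformations, disorder, lattice contacts) that real data add.
Checks against deposited BbZIP coordinates live in the acceptance tests and
activate when the user supplies the structure files (they are not
redistributable with the package); the bundled BbZIP topology config is a
constraint-consistent default meant to be edited against the user's own
secondary-structure annotation.

## Measured estimator precision

With the default bundle (8×24 residues, 9.4 Å packing) and noise applied to
both conformations, domain-partition recovery by the exact bipartition
search is correct in 300/300 seeded trials at σ = 0.3 Å for planted
rotations of 3–15°. The interdomain rotation estimate (Kabsch domain fits,
the maximum-likelihood estimator under this noise model) shows |error| mean
0.14°, p95 0.33°, max 0.43° over 300 trials at σ = 0.2 Å, degrading to mean
0.21°, p95 0.49°, max 0.64° at σ = 0.3 Å. The angle-recovery acceptance test
therefore runs at the σ = 0.2 default (100 trials, 0.5° bound), with
partition exactness additionally verified at σ = 0.3; the σ = 0.3 angle tail
is an information limit of the data, not of the estimator.

## Numerical choices and degenerate inputs

- Altloc resolution: highest occupancy wins, ties broken by label order —
  loading is deterministic.
- Glycine never carries a real CB; virtual CBs use a fixed linear
  combination of the local backbone frame (|CA–CB| = 1.53 Å,
  rotation-equivariant to 1e-9).
- Collinear superposition inputs, membrane frames without a unique dominant
  axis, and screw axes below 0.5° all raise typed errors instead of
  returning arbitrary representatives.
- arccos arguments are clamped to [−1, 1]; the angle itself uses the atan2
  form (see above).
- Helix axes use the CA principal component, not the end-to-end chord,
  which carries a helical-phase bias of several degrees.
- PDB output keeps the format's 1e-3 Å precision; round-trip is asserted at
  that tolerance.

## Known limitations

- The swapped model is a backbone-level rigid-geometry model: rebuilt
  segments are ideal helices, loops are absent, side chains end at CB. It
  is a hypothesis generator for crosslink design and site translocation,
  not a refined structure.
- Contact classification is single-chain; dimer-candidates are flagged but
  no inter-protomer geometry is computed.
- The orientation cone is a coarse proxy; rotamer-level accessibility is
  out of scope.
- The membrane frame assumes a reasonably upright TM bundle; strongly
  tilted or kinked bundles should supply a frame from external annotation.
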