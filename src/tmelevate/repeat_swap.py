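"""Repeat-swap threading: build the opposite conformation of an internally
pseudo-symmetric transporter.

Membrane transporters built from inverted structural repeats encode both
alternating-access conformations in one structure: threading each repeat's
sequence onto its symmetry mate's coordinates produces a model of the other
state. This module consumes a residue-level repeat alignment (aligned FASTA
blocks, one record pair per TM pairing), swaps backbone coordinates between
aligned mates, rebuilds unalignable TM stretches as ideal helices, and
quantifies how far a site (e.g. the metal transport site) travels along the
membrane normal between the input conformation and the swapped model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from ._geometry import ideal_helix_backbone
from .errors import AlignmentValidationError, ContractError, MissingResidueError
from .rigid_body import DomainPartition, superpose
from .structure_io import (
    AtomRecord,
    MembraneFrame,
    StructureModel,
    TMTopology,
    select_coords,
    shared_residues,
)

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class RepeatAlignment:
    """Residue-level correspondence between inverted-repeat TM mates.

    ``pairs`` maps each aligned residue to its mate in both directions (an
    involution). ``unaligned_segments`` lists maximal runs of TM residues
    that sit in a gap column and therefore cannot be threaded.
    """

    pairs: dict[int, int]
    pairings: list[tuple[str, str]]
    unaligned_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        for i, j in self.pairs.items():
            if self.pairs.get(j) != i:
                raise AlignmentValidationError(f"pairing not an involution at {i}<->{j}")

    def unaligned_residues(self) -> set[int]:
        return {r for lo, hi in self.unaligned_segments for r in range(lo, hi + 1)}


@dataclass
class SwapModel:
    """Threaded alternative-conformation model plus provenance bookkeeping."""

    model: StructureModel
    provenance: dict[int, int]       # residue -> source residue whose backbone it adopted
    low_confidence: set[int]         # rebuilt / unalignable residues
    chain_breaks: list[tuple[int, int]]  # omitted inter-TM connections


def _runs(numbers: Iterable[int]) -> list[tuple[int, int]]:
    nums = sorted(set(numbers))
    if not nums:
        return []
    runs, lo, prev = [], nums[0], nums[0]
    for n in nums[1:]:
        if n != prev + 1:
            runs.append((lo, prev))
            lo = n
        prev = n
    runs.append((lo, prev))
    return runs


def load_repeat_alignment(path: str | Path, topology: TMTopology) -> RepeatAlignment:
    """Parse aligned-FASTA repeat blocks into a validated :class:`RepeatAlignment`.

    Each record header reads ``><helix> mate=<helix> start=<residue>``;
    records come in mate pairs with equal alignment length. Gap columns
    yield no pair; residues falling in gap columns are collected into
    ``unaligned_segments``. Every aligned residue must lie inside its
    declared TM segment.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records or len(records) % 2:
        raise AlignmentValidationError(f"{path}: expected an even number of FASTA records")
    meta = {}
    for rec in records:
        fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv)
        if "mate" not in fields or "start" not in fields:
            raise AlignmentValidationError(
                f"{path}: record {rec.id!r} needs 'mate=' and 'start=' in its header")
        meta[rec.id] = (fields["mate"], int(fields["start"]), str(rec.seq))

    pairs: dict[int, int] = {}
    pairings: list[tuple[str, str]] = []
    unaligned: set[int] = set()
    done = set()
    for name, (mate, start, seq) in meta.items():
        if name in done:
            continue
        if mate not in meta or meta[mate][0] != name:
            raise AlignmentValidationError(f"{path}: {name!r} and its mate are not reciprocal")
        done.update({name, mate})
        pairings.append((name, mate))
        mate_start, mate_seq = meta[mate][1], meta[mate][2]
        if len(seq) != len(mate_seq):
            raise AlignmentValidationError(
                f"{path}: blocks {name}/{mate} differ in alignment length")
        seg_a, seg_b = topology[name], topology[mate]
        pos_a, pos_b = start, mate_start
        for col, (ca, cb) in enumerate(zip(seq, mate_seq)):
            res_a = pos_a if ca != "-" else None
            res_b = pos_b if cb != "-" else None
            if res_a is not None and res_a not in seg_a:
                raise AlignmentValidationError(
                    f"{path}: residue {res_a} outside declared TM {name} ({seg_a.start}-{seg_a.end})")
            if res_b is not None and res_b not in seg_b:
                raise AlignmentValidationError(
                    f"{path}: residue {res_b} outside declared TM {mate} ({seg_b.start}-{seg_b.end})")
            if res_a is not None and res_b is not None:
                pairs[res_a] = res_b
                pairs[res_b] = res_a
            elif res_a is not None:
                unaligned.add(res_a)
            elif res_b is not None:
                unaligned.add(res_b)
            pos_a += ca != "-"
            pos_b += cb != "-"
    return RepeatAlignment(pairs=pairs, pairings=pairings,
                           unaligned_segments=_runs(unaligned))


def _rebuild_segment(out_atoms: dict[int, dict[str, np.ndarray]], lo: int, hi: int,
                     seg_lo: int, seg_hi: int) -> dict[int, dict[str, np.ndarray]] | None:
    """Ideal-helix completion of residues lo..hi, anchored on threaded neighbours.

    An ideal helix with a 3-residue overlap is superposed onto the nearest
    three threaded residues (below the segment if available, else above) and
    its extension supplies the missing backbone (rise 1.5 A, 100 deg/residue).
    """
    n_seg = hi - lo + 1
    before = [r for r in range(lo - 3, lo) if r >= seg_lo and r in out_atoms
              and all(a in out_atoms[r] for a in ("N", "CA", "C"))]
    after = [r for r in range(hi + 1, hi + 4) if r <= seg_hi and r in out_atoms
             and all(a in out_atoms[r] for a in ("N", "CA", "C"))]
    use_before = len(before) == 3
    if not use_before and len(after) != 3:
        return None
    helix = ideal_helix_backbone(n_seg + 3)
    anchors = before if use_before else after
    anchor_idx = range(0, 3) if use_before else range(n_seg, n_seg + 3)
    ideal_pts = np.array([helix[a][i] for i in anchor_idx for a in ("N", "CA", "C")])
    target_pts = np.array([out_atoms[r][a] for r in anchors for a in ("N", "CA", "C")])
    t, _ = superpose(ideal_pts, target_pts)
    built: dict[int, dict[str, np.ndarray]] = {}
    offset = 3 if use_before else 0
    for k, res in enumerate(range(lo, hi + 1)):
        i = k + offset
        atoms = {a: t.apply(helix[a][i][None, :])[0] for a in BACKBONE}
        atoms["CB"] = t.apply(helix["CB"][i][None, :])[0]
        built[res] = atoms
    return built


def thread_swap(ifc: StructureModel, alignment: RepeatAlignment,
                topology: TMTopology, label: str = "OFC-model",
                rebuild_unaligned: bool = True) -> SwapModel:
    """Thread every repeat TM onto its mate's backbone coordinates.

    Each aligned residue keeps its own identity and number but adopts the
    backbone (N, CA, C, O) of its mate; CB comes from the mate when present,
    else is built by ideal geometry from the adopted backbone. Unalignable
    TM stretches are completed as ideal helices (flagged low-confidence);
    inter-TM loops are omitted and recorded as chain breaks.
    """
    missing = [r for r in alignment.pairs
               if not all(ifc.has_atom(r, a) for a in ("N", "CA", "C"))]
    if missing:
        raise MissingResidueError(sorted(set(missing)),
                                  f"{ifc.label!r}: backbone incomplete for threading")

    out_atoms: dict[int, dict[str, np.ndarray]] = {}
    provenance: dict[int, int] = {}
    for res, src in alignment.pairs.items():
        atoms: dict[str, np.ndarray] = {}
        for a in BACKBONE:
            if ifc.has_atom(src, a):
                atoms[a] = ifc.atom_position(src, a).copy()
        if ifc.residue_name(res) != "GLY":
            atoms["CB"] = ifc.cb_position(src).copy()
        out_atoms[res] = atoms
        provenance[res] = src

    low_confidence: set[int] = set()
    if rebuild_unaligned:
        for lo, hi in alignment.unaligned_segments:
            helix = topology.helix_of(lo)
            seg = topology[helix] if helix else None
            built = None
            if seg is not None:
                built = _rebuild_segment(out_atoms, lo, hi, seg.start, seg.end)
            if built:
                for res, atoms in built.items():
                    if ifc.has_residue(res) and ifc.residue_name(res) == "GLY":
                        atoms.pop("CB", None)
                    out_atoms[res] = atoms
            low_confidence.update(range(lo, hi + 1))

    records = []
    for res, atoms in out_atoms.items():
        resname = ifc.residue_name(res) if ifc.has_residue(res) else "ALA"
        for a, pos in atoms.items():
            records.append(AtomRecord("A", res, resname, a, pos))
    model = StructureModel(label, records)
    breaks = []
    runs = _runs(model.residue_numbers())
    for (lo1, hi1), (lo2, hi2) in zip(runs, runs[1:]):
        breaks.append((hi1, lo2))
    return SwapModel(model=model, provenance=provenance,
                     low_confidence=low_confidence, chain_breaks=breaks)


def site_translocation(ifc: StructureModel, ofc: StructureModel,
                       site_residues: Iterable[int], frame: MembraneFrame,
                       partition: DomainPartition, topology: TMTopology) -> float:
    """Signed vertical travel (A, + = extracellular) of a site between states.

    The swapped model is first superposed onto the input conformation over
    the scaffold (Domain II) CA atoms — the static reference of an elevator
    mechanism — and the site's CA-centroid displacement is projected onto
    the membrane normal.
    """
    scaffold = shared_residues(ifc, ofc, partition.residues("II", topology))
    if len(scaffold) < 3:
        raise ContractError("fewer than 3 shared Domain II residues for scaffold alignment")
    t, _ = superpose(select_coords(ofc, scaffold), select_coords(ifc, scaffold))
    site = sorted(set(site_residues))
    c_ifc = select_coords(ifc, site, "CA").mean(axis=0)
    c_ofc = t.apply(select_coords(ofc, site, "CA")).mean(axis=0)
    return float(np.dot(c_ofc - c_ifc, frame.normal))
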