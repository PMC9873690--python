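"""Structure input/output, TM topology, atom selection and membrane frame.

The in-memory currency of the pipeline is :class:`StructureModel`: an ordered
list of atom records for one protein chain, with hetero records (metals,
waters, ligands) kept separately. Coordinates are Angstrom throughout and
residues use author numbering as deposited — no renumbering anywhere.

Glycine never carries a real CB; wherever a CB is requested for a residue
that lacks one, an ideal tetrahedral virtual CB is constructed from N/CA/C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import gemmi
import numpy as np
import yaml

from ._geometry import principal_axis, virtual_cb
from .errors import (
    ChainNotFoundError,
    DegenerateGeometryError,
    MissingResidueError,
    StructureFormatError,
    TopologyValidationError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

SMALL_RESIDUES = frozenset({"GLY", "ALA", "SER"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom: chain, author residue number, residue/atom names, position (A)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)


class StructureModel:
    """Ordered residues of one chain with per-atom coordinates.

    Parameters
    ----------
    label:
        Free-text tag carried through reports (e.g. ``"IFC-holo"``).
    atoms:
        Polymer atom records, sorted internally by residue number.
    hetero:
        Non-polymer records (metal ions, waters, ligands).
    """

    def __init__(self, label: str, atoms: Iterable[AtomRecord],
                 hetero: Iterable[AtomRecord] = ()):
        self.label = label
        self.atoms: list[AtomRecord] = sorted(
            atoms, key=lambda a: (a.chain_id, a.residue_number))
        self.hetero: list[AtomRecord] = list(hetero)
        self._index: dict[tuple[int, str], AtomRecord] = {}
        self._resnames: dict[int, str] = {}
        for a in self.atoms:
            if a.residue_name == "GLY" and a.atom_name == "CB":
                continue  # glycine never carries a CB
            self._index[(a.residue_number, a.atom_name)] = a
            self._resnames[a.residue_number] = a.residue_name
        for num in self._resnames:
            if (num, "CA") not in self._index:
                raise ValueError(f"residue {num} has no CA atom")

    # ---- residue-level access -------------------------------------------------
    def residue_numbers(self) -> list[int]:
        return sorted(self._resnames)

    def residue_name(self, residue_number: int) -> str:
        try:
            return self._resnames[residue_number]
        except KeyError:
            raise MissingResidueError([residue_number]) from None

    @property
    def sequence(self) -> dict[int, str]:
        """residue_number -> one-letter code (X for nonstandard)."""
        return {n: _THREE_TO_ONE.get(r, "X") for n, r in self._resnames.items()}

    def has_residue(self, residue_number: int) -> bool:
        return residue_number in self._resnames

    def has_atom(self, residue_number: int, atom_name: str) -> bool:
        return (residue_number, atom_name) in self._index

    def atom_position(self, residue_number: int, atom_name: str) -> np.ndarray:
        try:
            return self._index[(residue_number, atom_name)].position
        except KeyError:
            raise MissingResidueError(
                [residue_number],
                f"residue {residue_number} atom {atom_name} absent from {self.label!r}",
            ) from None

    def cb_position(self, residue_number: int) -> np.ndarray:
        """Real CB, or an ideal virtual CB built from N/CA/C (always for Gly)."""
        if self.has_atom(residue_number, "CB"):
            return self.atom_position(residue_number, "CB")
        needed = ("N", "CA", "C")
        if not all(self.has_atom(residue_number, a) for a in needed):
            raise MissingResidueError(
                [residue_number],
                f"residue {residue_number}: no CB and incomplete backbone for a virtual CB",
            )
        n, ca, c = (self.atom_position(residue_number, a) for a in needed)
        return virtual_cb(n, ca, c)

    # ---- geometry -------------------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    label: str | None = None) -> "StructureModel":
        """Return a rigidly transformed copy (hetero records move with it)."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)

        def move(rec: AtomRecord) -> AtomRecord:
            return AtomRecord(rec.chain_id, rec.residue_number, rec.residue_name,
                              rec.atom_name, rot @ rec.position + tr)

        return StructureModel(label or self.label,
                              [move(a) for a in self.atoms],
                              [move(h) for h in self.hetero])

    def subset(self, residues: Iterable[int], label: str | None = None) -> "StructureModel":
        keep = set(residues)
        return StructureModel(label or self.label,
                              [a for a in self.atoms if a.residue_number in keep],
                              list(self.hetero))

    def __len__(self) -> int:
        return len(self._resnames)

    def __repr__(self) -> str:
        return f"<StructureModel {self.label!r}: {len(self)} residues, {len(self.atoms)} atoms>"


@dataclass(frozen=True)
class HelixSegment:
    """One TM helix: inclusive author-numbering range plus which end faces out."""

    name: str
    start: int
    end: int
    extracellular_end: Literal["start", "end"] = "end"

    def __post_init__(self):
        if self.start >= self.end:
            raise TopologyValidationError(
                f"segment {self.name}: start {self.start} >= end {self.end}")
        if self.extracellular_end not in ("start", "end"):
            raise TopologyValidationError(
                f"segment {self.name}: extracellular_end must be 'start' or 'end'")

    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def __contains__(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end


@dataclass
class TMTopology:
    """Named, non-overlapping helix segments of one transporter."""

    segments: list[HelixSegment]

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(names) != len(set(names)):
            raise TopologyValidationError("duplicate segment names")
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise TopologyValidationError(
                    f"segments {a.name} and {b.name} overlap ({a.start}-{a.end} vs {b.start}-{b.end})")

    def __getitem__(self, name: str) -> HelixSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def helix_of(self, residue_number: int) -> str | None:
        for s in self.segments:
            if residue_number in s:
                return s.name
        return None

    def core(self, names: Sequence[str] = ("a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8")) -> "TMTopology":
        """The eight-helix transport core (drops peripheral N-terminal helices)."""
        missing = [n for n in names if n not in self.names()]
        if missing:
            raise TopologyValidationError(f"core helices missing from topology: {missing}")
        return TMTopology([self[n] for n in names])


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane coordinate frame: unit normal (positive = extracellular) + origin."""

    normal: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "origin", np.asarray(self.origin, float))

    def height(self, point: np.ndarray) -> float:
        """Signed position along the normal (A, + = extracellular side)."""
        return float(np.dot(np.asarray(point, float) - self.origin, self.normal))


# ---------------------------------------------------------------------------
# File input/output
# ---------------------------------------------------------------------------

def load_structure(path: str | Path, chain: str | None = None,
                   label: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a single-chain :class:`StructureModel`.

    Altloc ambiguity is resolved to the highest-occupancy location (ties by
    altloc label order), making loading deterministic. Waters, metal ions and
    other non-polymer residues are kept as hetero records.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]
    chain_names = [ch.name for ch in model]
    if not chain_names:
        raise StructureFormatError(f"{path} contains no chains (not a structure file?)")
    if chain is None:
        chain = chain_names[0]
    if chain not in chain_names:
        raise ChainNotFoundError(f"chain {chain!r} not in {path} (has {chain_names})")

    atoms: list[AtomRecord] = []
    hetero: list[AtomRecord] = []
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            is_polymer = res.name in _THREE_TO_ONE
            # resolve altlocs: per atom name keep highest occupancy, ties by label
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or (at.occ, -ord(at.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
                    best[at.name] = at
            for name, at in best.items():
                if res.name == "GLY" and name == "CB":
                    continue
                rec = AtomRecord(ch.name, res.seqid.num, res.name, name,
                                 np.array([at.pos.x, at.pos.y, at.pos.z]))
                (atoms if is_polymer else hetero).append(rec)
    if not atoms:
        raise StructureFormatError(f"chain {chain!r} of {path} has no polymer atoms")
    return StructureModel(label or path.stem, atoms, hetero)


def write_structure(model: StructureModel, path: str | Path,
                    remarks: Sequence[str] = ()) -> None:
    """Write a model as PDB (coordinates kept to the format's 1e-3 A precision)."""
    st = gemmi.Structure()
    st.name = model.label
    gm = gemmi.Model("1")
    by_chain: dict[str, list[AtomRecord]] = {}
    for rec in model.atoms + model.hetero:
        by_chain.setdefault(rec.chain_id, []).append(rec)
    for chain_id, recs in by_chain.items():
        ch = gemmi.Chain(chain_id)
        by_res: dict[tuple[int, str], list[AtomRecord]] = {}
        for rec in recs:
            by_res.setdefault((rec.residue_number, rec.residue_name), []).append(rec)
        for (num, rname), group in sorted(by_res.items()):
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(num, " ")
            res.het_flag = "A" if rname in _THREE_TO_ONE else "H"
            for rec in group:
                at = gemmi.Atom()
                at.name = rec.atom_name
                at.element = gemmi.Element(rec.atom_name[:1] if rec.atom_name[:2] not in ("CD", "ZN", "HG", "MG", "MN", "FE") or rname in _THREE_TO_ONE else rec.atom_name[:2])
                at.pos = gemmi.Position(*rec.position)
                at.occ = 1.0
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    doc_lines = "".join(f"REMARK 300 {r}\n" for r in remarks)
    pdb_string = st.make_pdb_string()
    Path(path).write_text(doc_lines + pdb_string)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def load_topology(path: str | Path) -> TMTopology:
    """Read a YAML topology config: ``segments: [{name, start, end, extracellular_end}]``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "segments" not in data:
        raise TopologyValidationError(f"{path}: expected a mapping with a 'segments' list")
    segments = []
    for entry in data["segments"]:
        try:
            segments.append(HelixSegment(
                name=str(entry["name"]),
                start=int(entry["start"]),
                end=int(entry["end"]),
                extracellular_end=entry.get("extracellular_end", "end"),
            ))
        except KeyError as exc:
            raise TopologyValidationError(f"{path}: segment entry missing key {exc}") from exc
    return TMTopology(segments)


def default_bbzip_topology() -> TMTopology:
    """The bundled BbZIP helix-range config (editable defaults, see package data)."""
    from importlib.resources import files
    return load_topology(str(files("tmelevate") / "data" / "bbzip_topology.yaml"))


# ---------------------------------------------------------------------------
# Selection and membrane frame
# ---------------------------------------------------------------------------

def select_coords(model: StructureModel, residues: Iterable[int],
                  atom_kind: Literal["CA", "CB", "backbone"] = "CA") -> np.ndarray:
    """Coordinates for a residue set in ascending residue order.

    ``CA``/``CB`` give one row per residue (virtual CB where needed);
    ``backbone`` gives four rows (N, CA, C, O) per residue.
    """
    wanted = sorted(set(residues))
    missing = [r for r in wanted if not model.has_residue(r)]
    if missing:
        raise MissingResidueError(missing, f"{model.label!r} lacks residues {missing}")
    rows: list[np.ndarray] = []
    if atom_kind == "CA":
        rows = [model.atom_position(r, "CA") for r in wanted]
    elif atom_kind == "CB":
        rows = [model.cb_position(r) for r in wanted]
    elif atom_kind == "backbone":
        incomplete = [r for r in wanted
                      if not all(model.has_atom(r, a) for a in BACKBONE_ATOMS)]
        if incomplete:
            raise MissingResidueError(incomplete,
                                      f"{model.label!r}: incomplete backbone at {incomplete}")
        for r in wanted:
            rows.extend(model.atom_position(r, a) for a in BACKBONE_ATOMS)
    else:
        raise ValueError(f"unknown atom_kind {atom_kind!r}")
    return np.array(rows)


def shared_residues(a: StructureModel, b: StructureModel,
                    residues: Iterable[int] | None = None) -> list[int]:
    """Residue numbers with a CA in both models (optionally within a subset)."""
    common = set(a.residue_numbers()) & set(b.residue_numbers())
    if residues is not None:
        common &= set(residues)
    return sorted(common)


def helix_axis(model: StructureModel, segment: HelixSegment) -> np.ndarray:
    """Unit vector along a helix, oriented toward its extracellular end.

    Uses the principal direction of the CA cloud (the end-to-end chord is
    biased by the helical phase of the terminal residues), signed by the
    chord and the segment's declared extracellular end.
    """
    present = [r for r in segment.residues() if model.has_residue(r)]
    if len(present) < 3:
        raise DegenerateGeometryError(f"segment {segment.name}: fewer than 3 residues present")
    cas = np.array([model.atom_position(r, "CA") for r in present])
    chord = cas[-1] - cas[0]
    if np.linalg.norm(chord) < 1e-6:
        raise DegenerateGeometryError(f"segment {segment.name}: degenerate axis")
    vec = principal_axis(cas)
    if np.dot(vec, chord) < 0:
        vec = -vec
    if segment.extracellular_end == "start":
        vec = -vec
    return vec


def estimate_membrane_frame(model: StructureModel, topology: TMTopology) -> MembraneFrame:
    """Estimate the membrane normal and origin from TM helix axes.

    The normal is the dominant principal direction of the set of per-helix
    axis unit vectors (each oriented extracellularly); its sign is fixed so
    extracellular helix ends project positively. The origin is the centroid
    of all TM CA atoms.
    """
    if len(topology.segments) < 3:
        raise DegenerateGeometryError("need at least 3 TM segments for a membrane frame")
    axes = np.array([helix_axis(model, seg) for seg in topology.segments])
    centered = axes  # axes are directions; principal direction of the vector set
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] < 1e-9 or (svals.size > 1 and svals[0] - svals[1] < 1e-9 * max(1.0, svals[0])):
        raise DegenerateGeometryError("helix axes do not define a unique membrane normal")
    normal = vt[0]
    if np.dot(axes.mean(axis=0), normal) < 0:
        normal = -normal
    ca_coords = []
    for seg in topology.segments:
        for r in seg.residues():
            if model.has_residue(r):
                ca_coords.append(model.atom_position(r, "CA"))
    origin = np.mean(ca_coords, axis=0)
    return MembraneFrame(normal=normal, origin=origin)
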