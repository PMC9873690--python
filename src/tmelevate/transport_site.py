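"""Binuclear metal center (BMC) geometry and its apo/holo rearrangement.

ZIP-family transporters carry a pair of metal sites — M1, the primary
transport site, and M2 — bridged by a shared carboxylate. On metal release
the site disassembles unevenly: some chelators stay put, some swing only
their side chain away, and some drift with their backbone. This module
measures chelator-to-site distances in a metal-bound structure, transfers
the site positions into an apo structure by transport-domain superposition,
and classifies each chelator's rearrangement into those three groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, MissingResidueError
from .rigid_body import DomainPartition, superpose
from .structure_io import StructureModel, TMTopology, select_coords, shared_residues

# side-chain functional position per residue type; carboxylates use the
# centroid of the two oxygens, His the ring nitrogen nearer the site
_FUNCTIONAL_ATOMS: dict[str, tuple[str, ...]] = {
    "HIS": ("NE2", "ND1"),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "MET": ("SD",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "CYS": ("SG",),
    "TYR": ("OH",),
}

METAL_ELEMENTS = {"CD", "ZN", "MN", "FE", "CO", "NI", "CU", "HG", "MG"}


@dataclass(frozen=True)
class BMCDefinition:
    """Chelating residues of the two metal sites; the bridge belongs to both."""

    m1_chelators: frozenset[int]
    m2_chelators: frozenset[int]
    bridging: int

    def __post_init__(self):
        object.__setattr__(self, "m1_chelators", frozenset(self.m1_chelators))
        object.__setattr__(self, "m2_chelators", frozenset(self.m2_chelators))
        if self.bridging not in self.m1_chelators or self.bridging not in self.m2_chelators:
            raise ValueError("bridging residue must chelate both M1 and M2")

    def all_residues(self) -> list[int]:
        return sorted(self.m1_chelators | self.m2_chelators)


def default_bbzip_bmc() -> BMCDefinition:
    """The BbZIP site: M1 = {M99, H177, N178, E181, Q207, E211}, M2 = {E181, D208, E240}."""
    return BMCDefinition(m1_chelators=frozenset({99, 177, 178, 181, 207, 211}),
                         m2_chelators=frozenset({181, 208, 240}),
                         bridging=181)


@dataclass
class SiteGeometry:
    """Measured site geometry of one model (all positions in that model's frame)."""

    label: str
    metal_positions: dict[str, np.ndarray]            # "M1"/"M2" -> position
    ca_positions: dict[int, np.ndarray]
    functional_positions: dict[int, np.ndarray]
    ca_site_distance: dict[int, float]                # chelator CA -> its site
    functional_site_distance: dict[int, float]        # functional atom -> its site
    metals_from_reference: bool = False


def find_metals(model: StructureModel) -> list[np.ndarray]:
    """Positions of metal-ion hetero records (Cd, Zn, ...)."""
    return [h.position for h in model.hetero
            if h.residue_name.strip().upper() in METAL_ELEMENTS
            or h.atom_name.strip().upper() in METAL_ELEMENTS]


def functional_position(model: StructureModel, residue: int,
                        toward: np.ndarray | None = None) -> np.ndarray:
    """Side-chain functional position of a chelator (falls back to CB).

    Carboxylates average their two oxygens; His picks the ring nitrogen
    nearer ``toward`` when given. Residues without tabulated side-chain
    atoms, or with those atoms unresolved, use the (possibly virtual) CB.
    """
    resname = model.residue_name(residue)
    names = _FUNCTIONAL_ATOMS.get(resname, ())
    present = [model.atom_position(residue, a) for a in names if model.has_atom(residue, a)]
    if not present:
        return model.cb_position(residue)
    if resname == "HIS" and len(present) > 1 and toward is not None:
        return min(present, key=lambda p: np.linalg.norm(p - toward))
    if resname in ("GLU", "ASP") and len(present) > 1:
        return np.mean(present, axis=0)
    return present[0]


def _assign_metal_sites(metals: list[np.ndarray], model: StructureModel,
                        bmc: BMCDefinition) -> dict[str, np.ndarray]:
    """Label metal positions M1/M2 by proximity to each site's chelator centroid."""
    m1_centroid = np.mean([model.cb_position(r) for r in sorted(bmc.m1_chelators)], axis=0)
    if len(metals) == 1:
        return {"M1": metals[0]}
    ordered = sorted(metals, key=lambda p: float(np.linalg.norm(p - m1_centroid)))
    return {"M1": ordered[0], "M2": ordered[1]}


def bmc_geometry(model: StructureModel, bmc: BMCDefinition,
                 metals: Mapping[str, np.ndarray] | None = None,
                 holo_reference: StructureModel | None = None,
                 partition: DomainPartition | None = None,
                 topology: TMTopology | None = None) -> SiteGeometry:
    """Chelator-to-site distances for one model.

    Site positions come from, in order of preference: the ``metals``
    mapping; metal hetero records in the model itself; or — for an apo
    model — a metal-bound ``holo_reference`` superposed onto the model over
    the transport-domain (Domain I) CA atoms, which transfers the reference
    site positions into the apo frame. The last route requires ``partition``
    and ``topology``.
    """
    missing = [r for r in bmc.all_residues() if not model.has_residue(r)]
    if missing:
        raise MissingResidueError(missing, f"{model.label!r}: chelators missing {missing}")

    from_reference = False
    if metals is not None:
        metal_map = {k: np.asarray(v, float) for k, v in metals.items()}
    else:
        own = find_metals(model)
        if own:
            metal_map = _assign_metal_sites(own, model, bmc)
        elif holo_reference is not None:
            if partition is None or topology is None:
                raise ContractError("holo-reference route needs partition and topology")
            ref_metals = find_metals(holo_reference)
            if not ref_metals:
                raise ContractError(f"holo reference {holo_reference.label!r} has no metals")
            dom1 = shared_residues(holo_reference, model, partition.residues("I", topology))
            t, _ = superpose(select_coords(holo_reference, dom1),
                             select_coords(model, dom1))
            moved = [t.apply(p[None, :])[0] for p in ref_metals]
            metal_map = _assign_metal_sites(moved, model, bmc)
            from_reference = True
        else:
            raise ContractError(
                f"{model.label!r}: no metal positions and no holo reference given")

    ca_pos, func_pos, ca_d, func_d = {}, {}, {}, {}
    for res in bmc.all_residues():
        site = "M1" if res in bmc.m1_chelators else "M2"
        if site not in metal_map:  # single-metal case
            site = next(iter(metal_map))
        target = metal_map[site]
        ca_pos[res] = model.atom_position(res, "CA")
        func_pos[res] = functional_position(model, res, toward=target)
        ca_d[res] = float(np.linalg.norm(ca_pos[res] - target))
        func_d[res] = float(np.linalg.norm(func_pos[res] - target))
    return SiteGeometry(label=model.label, metal_positions=metal_map,
                        ca_positions=ca_pos, functional_positions=func_pos,
                        ca_site_distance=ca_d, functional_site_distance=func_d,
                        metals_from_reference=from_reference)


def classify_displacements(apo_geom: SiteGeometry, holo_geom: SiteGeometry,
                           t1: float = 1.0, t2: float = 1.5) -> dict[int, str]:
    """Three-group classification of chelator rearrangement.

    Both geometries must be expressed in a common frame (see
    :func:`compare_sites`). Per residue: *unchanged* when the CA moved less
    than ``t1`` and the functional atom less than ``t2``;
    *side-chain-reoriented* when only the functional atom moved;
    *backbone-shifted* when the CA itself moved at least ``t1`` (A).
    """
    out = {}
    for res in sorted(set(apo_geom.ca_positions) & set(holo_geom.ca_positions)):
        ca_shift = float(np.linalg.norm(apo_geom.ca_positions[res] - holo_geom.ca_positions[res]))
        func_shift = float(np.linalg.norm(apo_geom.functional_positions[res]
                                          - holo_geom.functional_positions[res]))
        if ca_shift >= t1:
            out[res] = "backbone-shifted"
        elif func_shift >= t2:
            out[res] = "side-chain-reoriented"
        else:
            out[res] = "unchanged"
    return out


def compare_sites(apo: StructureModel, holo: StructureModel, bmc: BMCDefinition,
                  partition: DomainPartition, topology: TMTopology,
                  t1: float = 1.0, t2: float = 1.5) -> pd.DataFrame:
    """Apo-vs-holo site comparison in the transport-domain frame.

    The apo model is superposed onto the holo model over Domain I CA atoms
    (the transport domain carries the site, so this isolates site-local
    rearrangement from whole-domain motion as seen from the scaffold), then
    each chelator's CA and functional-atom shifts are classified.
    """
    dom1 = shared_residues(apo, holo, partition.residues("I", topology))
    t, _ = superpose(select_coords(apo, dom1), select_coords(holo, dom1))
    apo_aligned = apo.transformed(t.rotation, t.translation)
    holo_geom = bmc_geometry(holo, bmc)
    apo_geom = bmc_geometry(apo_aligned, bmc, metals={
        k: v for k, v in holo_geom.metal_positions.items()})
    classes = classify_displacements(apo_geom, holo_geom, t1, t2)
    rows = []
    for res in bmc.all_residues():
        rows.append({
            "residue": res,
            "residue_name": holo.residue_name(res),
            "ca_shift": float(np.linalg.norm(apo_geom.ca_positions[res]
                                             - holo_geom.ca_positions[res])),
            "functional_shift": float(np.linalg.norm(apo_geom.functional_positions[res]
                                                     - holo_geom.functional_positions[res])),
            "class": classes[res],
        })
    return pd.DataFrame(rows)
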