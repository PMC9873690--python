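"""Evolutionary-coupling contacts: filtering, helix mapping, structure
consistency and the domain-interface census.

Coupling tables are consumed, never inferred: the input is a CSV export of
predicted residue-residue contacts with probabilities (the usual coupling-
analysis export dialect with ``i, A_i, j, A_j, probability`` columns).
Contacts are tested against one or more structures by CA-CA distance: a
pair predicted to interact but far apart in every known conformation is
evidence for an unseen conformation — or, when both residues lie in the
dimerization scaffold, for an inter-protomer contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import StructureFormatError
from .rigid_body import DomainPartition
from .structure_io import SMALL_RESIDUES, StructureModel, TMTopology

DEFAULT_ALIASES = {
    "i": ("i", "pos_i", "res_i"),
    "j": ("j", "pos_j", "res_j"),
    "probability": ("probability", "prob", "p", "score"),
}


@dataclass(frozen=True)
class ContactRecord:
    """Predicted contact between residues ``i < j`` with probability in [0, 1]."""

    i: int
    j: int
    probability: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("contact with itself")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if self.i > self.j:
            i, j = self.j, self.i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class ContactClassification:
    """A contact judged against one or more structures."""

    record: ContactRecord
    ca_distance: dict[str, float]    # structure label -> CA-CA distance (A)
    category: str                    # consistent | inconsistent | dimer-candidate | ambiguous
    domain_type: str                 # intra-I | intra-II | inter | other
    helices: tuple[str | None, str | None]
    notes: list[str] = field(default_factory=list)


def load_contacts(path: str | Path, aliases: dict | None = None) -> list[ContactRecord]:
    """Read a contact CSV; records are deduplicated with (i, j) ordered i < j."""
    df = pd.read_csv(path)
    alias_map = {**DEFAULT_ALIASES, **(aliases or {})}
    cols = {}
    for key, options in alias_map.items():
        found = next((c for c in options if c in df.columns), None)
        if found is None:
            raise StructureFormatError(
                f"{path}: no column for {key!r} (looked for {options}; has {list(df.columns)})")
        cols[key] = found
    seen: dict[tuple[int, int], ContactRecord] = {}
    for _, row in df.iterrows():
        rec = ContactRecord(int(row[cols["i"]]), int(row[cols["j"]]),
                            float(row[cols["probability"]]))
        seen.setdefault(rec.pair, rec)
    return list(seen.values())


def _domain_type(hi: str | None, hj: str | None, partition: DomainPartition) -> str:
    if hi is None or hj is None:
        return "other"
    di, dj = partition.domain_of(hi), partition.domain_of(hj)
    if "unassigned" in (di, dj):
        return "other"
    if di == dj:
        return f"intra-{di}"
    return "inter"


def filter_and_map(records: Iterable[ContactRecord], topology: TMTopology,
                   partition: DomainPartition, p_min: float = 0.75):
    """Keep interhelical contacts above ``p_min`` and count them per helix pair.

    Returns ``(kept, matrix, totals)``: the surviving records, a symmetric
    helix-by-helix count matrix (DataFrame), and per-domain-type totals.
    """
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("p_min must be in [0, 1]")
    names = topology.names()
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    totals = {"intra-I": 0, "intra-II": 0, "inter": 0, "other": 0}
    kept = []
    for rec in records:
        if rec.probability <= p_min:
            continue
        hi, hj = topology.helix_of(rec.i), topology.helix_of(rec.j)
        if hi is None or hj is None or hi == hj:
            continue
        kept.append(rec)
        matrix.loc[hi, hj] += 1
        matrix.loc[hj, hi] += 1
        totals[_domain_type(hi, hj, partition)] += 1
    return kept, matrix, totals


def classify_contacts(records: Iterable[ContactRecord],
                      structures: Sequence[StructureModel],
                      partition: DomainPartition, topology: TMTopology,
                      d_consistent: float = 8.0,
                      d_inconsistent: float = 10.0) -> list[ContactClassification]:
    """Judge each contact against every structure by CA-CA distance.

    A contact is *consistent* if it comes within ``d_consistent`` in ANY
    structure, *inconsistent* if it exceeds ``d_inconsistent`` in ALL
    structures where it can be measured, otherwise *ambiguous*. Inconsistent
    pairs lying entirely in the scaffold (Domain II) are promoted to
    *dimer-candidate*: they may be satisfied across a dimer interface.
    """
    if not d_consistent < d_inconsistent:
        raise ValueError("need d_consistent < d_inconsistent")
    out = []
    for rec in records:
        dists: dict[str, float] = {}
        notes: list[str] = []
        for st in structures:
            if st.has_residue(rec.i) and st.has_residue(rec.j):
                d = float(np.linalg.norm(st.atom_position(rec.i, "CA")
                                         - st.atom_position(rec.j, "CA")))
                dists[st.label] = d
            else:
                notes.append(f"{st.label}: residue missing, skipped")
        if not dists:
            category = "ambiguous"
            notes.append("not measurable in any structure")
        elif min(dists.values()) <= d_consistent:
            category = "consistent"
        elif all(d > d_inconsistent for d in dists.values()):
            category = "inconsistent"
        else:
            category = "ambiguous"
        hi, hj = topology.helix_of(rec.i), topology.helix_of(rec.j)
        domain_type = _domain_type(hi, hj, partition)
        if category == "inconsistent" and domain_type == "intra-II":
            category = "dimer-candidate"
        out.append(ContactClassification(record=rec, ca_distance=dists,
                                         category=category, domain_type=domain_type,
                                         helices=(hi, hj), notes=notes))
    return out


def classification_table(classifications: Iterable[ContactClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        row = {"i": c.record.i, "j": c.record.j, "probability": c.record.probability,
               "helix_i": c.helices[0], "helix_j": c.helices[1],
               "domain_type": c.domain_type, "category": c.category}
        for label, d in c.ca_distance.items():
            row[f"ca_dist[{label}]"] = d
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Domain-interface census
# ---------------------------------------------------------------------------

def interface_census(model: StructureModel, partition: DomainPartition,
                     topology: TMTopology, contact_cutoff: float = 4.5) -> dict:
    """Residues whose CB sits within ``contact_cutoff`` of the other domain.

    Smooth, small-residue-rich domain interfaces are the signature of
    sliding rigid-body (elevator) motions; the census reports the interface
    residue set and the fraction that are small (Gly, Ala, Ser).
    """
    groups: dict[str, list[int]] = {"I": [], "II": []}
    for res in model.residue_numbers():
        helix = topology.helix_of(res)
        if helix is None:
            continue
        dom = partition.domain_of(helix)
        if dom in groups and all(model.has_atom(res, a) for a in ("N", "CA", "C")):
            groups[dom].append(res)
    if not groups["I"] or not groups["II"]:
        return {"interface_residues": [], "n_interface": 0, "small_fraction": float("nan")}
    cb = {dom: np.array([model.cb_position(r) for r in residues])
          for dom, residues in groups.items()}
    tree_i, tree_ii = cKDTree(cb["I"]), cKDTree(cb["II"])
    pairs = tree_i.query_ball_tree(tree_ii, r=contact_cutoff)
    interface: set[int] = set()
    for idx_i, hits in enumerate(pairs):
        if hits:
            interface.add(groups["I"][idx_i])
            interface.update(groups["II"][h] for h in hits)
    interface_sorted = sorted(interface)
    small = [r for r in interface_sorted if model.residue_name(r) in SMALL_RESIDUES]
    frac = len(small) / len(interface_sorted) if interface_sorted else float("nan")
    return {"interface_residues": interface_sorted, "n_interface": len(interface_sorted),
            "small_residues": small, "small_fraction": frac,
            "cutoff": contact_cutoff}


def interface_sensitivity(model: StructureModel, partition: DomainPartition,
                          topology: TMTopology,
                          cutoffs: Sequence[float] = (4.0, 4.5, 5.0, 5.5, 6.0)) -> pd.DataFrame:
    """Interface size and small-residue fraction across a range of CB cutoffs."""
    rows = [interface_census(model, partition, topology, c) for c in cutoffs]
    return pd.DataFrame([{"cutoff": r["cutoff"], "n_interface": r["n_interface"],
                          "small_fraction": r["small_fraction"]} for r in rows])
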