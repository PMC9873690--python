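"""Design of conformation-reporting cysteine crosslink pairs.

A residue pair reports an elevator motion when a crosslink between
introduced cysteines is geometrically feasible in exactly one conformation:
the crosslink then traps (or fails to form in) one state, giving a gel-shift
readout of the motion. Feasibility is judged on CB-CB distance against the
linker's reach — ~7.8 A for a mercury-mediated S-Hg-S bridge, ~6.0 A for a
direct disulfide — plus an orientation check that both beta-carbons point
toward each other rather than away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .rigid_body import DomainPartition
from .structure_io import StructureModel, TMTopology

HG_LINKER_MAX = 7.8        # S-Hg-S maximum CB separation (A)
DISULFIDE_LINKER_MAX = 6.0  # direct S-S preset (A)


@dataclass
class CrosslinkCandidate:
    """One cross-domain pair with per-conformation distances and a verdict."""

    pair: tuple[int, int]
    cb_distance: dict[str, float]          # conformation label -> CB-CB (A)
    feasible_in: set[str]                  # conformations with distance <= linker_max
    orientation_ok: dict[str, bool]
    verdict: str  # reporter | never-feasible | always-feasible | orientation-blocked


def pair_distance(model: StructureModel, a: int, b: int,
                  atom_kind: Literal["CA", "CB"] = "CB") -> float:
    """Euclidean distance between two residues' CA or CB atoms (virtual CB ok)."""
    if atom_kind == "CA":
        pa, pb = model.atom_position(a, "CA"), model.atom_position(b, "CA")
    elif atom_kind == "CB":
        pa, pb = model.cb_position(a), model.cb_position(b)
    else:
        raise ValueError(f"unknown atom_kind {atom_kind!r}")
    return float(np.linalg.norm(pa - pb))


def orientation_filter(model: StructureModel, a: int, b: int,
                       max_angle: float = 90.0) -> bool:
    """True when each residue's CB points toward its partner.

    The criterion is a cone test: the angle between CA->CB and CA->CA(partner)
    must not exceed ``max_angle`` (degrees) on either side. A residue whose
    side chain projects from the far face of its helix fails even when the
    CB-CB distance is short.
    """
    for x, y in ((a, b), (b, a)):
        ca_x = model.atom_position(x, "CA")
        cb_x = model.cb_position(x)
        ca_y = model.atom_position(y, "CA")
        v_side = cb_x - ca_x
        v_partner = ca_y - ca_x
        denom = np.linalg.norm(v_side) * np.linalg.norm(v_partner)
        if denom < 1e-9:
            return False
        cos_ang = np.clip(np.dot(v_side, v_partner) / denom, -1.0, 1.0)
        if np.degrees(np.arccos(cos_ang)) > max_angle:
            return False
    return True


def screen_reporter_pairs(ifc: StructureModel, ofc: StructureModel,
                          partition: DomainPartition, topology: TMTopology,
                          linker_max: float = HG_LINKER_MAX,
                          candidates: Sequence[tuple[int, int]] | None = None,
                          exclude: Iterable[int] = (),
                          max_angle: float = 90.0) -> list[CrosslinkCandidate]:
    """Screen residue pairs for conformation-reporting crosslink potential.

    Without an explicit candidate list, all cross-domain pairs (one residue
    in Domain I, one in Domain II, both resolved in both conformations, and
    not in ``exclude`` — e.g. low-confidence rebuilt residues) are
    enumerated. Verdicts follow the reporter rule: feasible (CB-CB <=
    ``linker_max``) in exactly one conformation, with the side chains facing
    each other there.
    """
    if linker_max <= 0:
        raise ValueError("linker_max must be positive")
    excluded = set(exclude)
    if candidates is None:
        def usable(res):
            return (ifc.has_residue(res) and ofc.has_residue(res)
                    and res not in excluded)
        dom_i = [r for r in partition.residues("I", topology) if usable(r)]
        dom_ii = [r for r in partition.residues("II", topology) if usable(r)]
        candidates = list(product(dom_i, dom_ii))

    out = []
    for a, b in candidates:
        dists = {m.label: pair_distance(m, a, b, "CB") for m in (ifc, ofc)}
        feasible = {label for label, d in dists.items() if d <= linker_max}
        orient = {m.label: orientation_filter(m, a, b, max_angle) for m in (ifc, ofc)}
        if not feasible:
            verdict = "never-feasible"
        elif len(feasible) == len(dists):
            verdict = "always-feasible"
        else:
            only = next(iter(feasible))
            verdict = "reporter" if orient[only] else "orientation-blocked"
        out.append(CrosslinkCandidate(pair=(a, b), cb_distance=dists,
                                      feasible_in=feasible, orientation_ok=orient,
                                      verdict=verdict))
    return out


def candidate_table(candidates: Iterable[CrosslinkCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {"res_i": c.pair[0], "res_j": c.pair[1], "verdict": c.verdict}
        for label, d in c.cb_distance.items():
            row[f"cb_dist[{label}]"] = d
            row[f"orientation_ok[{label}]"] = c.orientation_ok[label]
        rows.append(row)
    return pd.DataFrame(rows)
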