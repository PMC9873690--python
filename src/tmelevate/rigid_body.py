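"""Superposition, screw-axis decomposition and rigid-domain partitioning.

The central question these tools answer: when a transporter is seen in two
conformations, which transmembrane helices move together as rigid bodies,
and what is the rotation/translation (and its hinge) relating the moving
block to the static one?

Conventions: a :class:`Transform` maps mobile coordinates onto the reference
(``x' = R x + t``); angles are degrees; distances Angstrom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ContractError, DegenerateGeometryError
from .structure_io import StructureModel, TMTopology, select_coords, shared_residues


@dataclass(frozen=True)
class Transform:
    """Proper rigid transform ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, float)
        tr = np.asarray(self.translation, float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other: (self o other)(x) = self(other(x))."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_row(self) -> list[float]:
        """Serialize as 12 numbers: 9 rotation entries (row-major) + translation."""
        return [*self.rotation.ravel().tolist(), *self.translation.tolist()]

    @classmethod
    def from_row(cls, row) -> "Transform":
        row = np.asarray(row, float)
        return cls(row[:9].reshape(3, 3), row[9:12])


@dataclass(frozen=True)
class ScrewAxis:
    """Axis/angle/pitch form of a rigid transform.

    ``point_on_axis`` is the point of minimum displacement; applying the
    parent transform moves it only parallel to ``direction``. ``pitch`` is
    the translation along the axis per application of the transform.
    """

    direction: np.ndarray
    point_on_axis: np.ndarray
    angle: float  # degrees, in [0, 180]
    pitch: float  # Angstrom along direction

    def __post_init__(self):
        d = np.asarray(self.direction, float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("screw direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "point_on_axis", np.asarray(self.point_on_axis, float))


@dataclass
class DomainPartition:
    """Assignment of helix names to rigid domains I / II (or 'unassigned')."""

    assignment: dict[str, str]
    single_domain: bool = False

    def domain(self, label: str) -> list[str]:
        return sorted(h for h, d in self.assignment.items() if d == label)

    def domain_of(self, helix: str) -> str:
        return self.assignment.get(helix, "unassigned")

    def residues(self, label: str, topology: TMTopology) -> list[int]:
        out: list[int] = []
        for name in self.domain(label):
            out.extend(topology[name].residues())
        return sorted(out)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition (Kabsch) of paired point sets.

    Returns the transform taking ``mobile`` onto ``reference`` and the RMSD
    of the residuals after applying it.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ContractError(f"point sets differ in shape: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ContractError("need >= 3 paired 3D points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    # collinearity check: rotation about the common line is unconstrained
    if np.linalg.svd(a, compute_uv=False)[1] < 1e-8:
        raise DegenerateGeometryError("mobile points are collinear; superposition ill-posed")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tr = rc - rot @ mc
    resid = a @ rot.T - b
    rmsd = float(np.sqrt((resid ** 2).sum() / len(mobile)))
    return Transform(rot, tr), rmsd


def rmsd_between(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between paired point sets (superposition residual)."""
    return superpose(mobile, reference)[1]


def rotation_angle(t: Transform) -> float:
    """Rotation magnitude in degrees, in [0, 180].

    Computed as atan2(|skew(R)|/2, (trace(R)-1)/2): equivalent to the
    arccos-of-trace form but numerically stable near 0 degrees, where the
    arccos derivative blows up and round-off in the trace would otherwise
    dominate.
    """
    r = t.rotation
    s = 0.5 * np.linalg.norm([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    c = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arctan2(s, c)))


def screw_decompose(t: Transform, min_angle: float = 0.5) -> ScrewAxis:
    """Axis, angle, axis point and pitch of a rigid transform.

    Raises for near-identity rotations (angle < ``min_angle`` degrees), where
    the axis direction is numerically meaningless.
    """
    angle = rotation_angle(t)
    if angle < min_angle:
        raise DegenerateGeometryError(
            f"rotation angle {angle:.3f} deg < {min_angle} deg: screw axis ill-conditioned; "
            "raise min_angle only if you accept an arbitrary axis")
    # axis: eigenvector of R for eigenvalue 1, sign fixed against the skew part
    r = t.rotation
    w, v = np.linalg.eig(r)
    direction = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    direction /= np.linalg.norm(direction)
    skew = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    if np.dot(direction, skew) < 0 and np.linalg.norm(skew) > 1e-12:
        direction = -direction
    pitch = float(np.dot(t.translation, direction))
    # point on axis: least-squares solution of (I - R) p = t_perp, p ⟂ direction
    t_perp = t.translation - pitch * direction
    p, *_ = np.linalg.lstsq(np.eye(3) - r, t_perp, rcond=None)
    p = p - np.dot(p, direction) * direction  # minimum-norm representative
    return ScrewAxis(direction=direction, point_on_axis=p, angle=angle, pitch=pitch)


# ---------------------------------------------------------------------------
# Per-helix transforms and domain decomposition
# ---------------------------------------------------------------------------

def per_helix_transforms(a: StructureModel, b: StructureModel,
                         topology: TMTopology) -> dict[str, tuple[Transform, float]]:
    """Superpose each helix of ``a`` onto ``b`` over shared CA atoms.

    Helices with fewer than 3 shared residues are skipped with a warning.
    """
    out: dict[str, tuple[Transform, float]] = {}
    for seg in topology.segments:
        common = shared_residues(a, b, seg.residues())
        if len(common) < 3:
            warnings.warn(f"helix {seg.name}: {len(common)} shared residues; skipped",
                          stacklevel=2)
            continue
        ca_a = select_coords(a, common, "CA")
        ca_b = select_coords(b, common, "CA")
        out[seg.name] = superpose(ca_a, ca_b)
    return out


def transform_dissimilarity(t1: Transform, t2: Transform, lam: float = 1.0) -> float:
    """Distance between two rigid transforms, in rotation-degrees.

    ``angle(R1 R2^T) + lam * |t1 - t2|`` with ``lam`` in degrees per Angstrom.
    """
    rel = Transform(t1.rotation @ t2.rotation.T, np.zeros(3))
    return rotation_angle(rel) + lam * float(np.linalg.norm(t1.translation - t2.translation))


def _helix_ca(model_a: StructureModel, model_b: StructureModel, topology: TMTopology,
              name: str) -> tuple[np.ndarray, np.ndarray]:
    common = shared_residues(model_a, model_b, topology[name].residues())
    return select_coords(model_a, common, "CA"), select_coords(model_b, common, "CA")


def decompose_domains(a: StructureModel, b: StructureModel, topology: TMTopology,
                      lam: float = 1.0, tau: float = 3.0,
                      anchor_helix: str = "a4", max_iter: int = 10) -> DomainPartition:
    """Partition helices into two rigid domains from the a->b conformational change.

    A single-helix superposition constrains rotation about the helix's own
    axis only weakly, so per-helix transforms are used only to decide
    whether there is any relative motion at all: when average-linkage
    clustering of the pairwise transform dissimilarities (rotation degrees
    plus ``lam`` deg/A times translation difference) merges everything below
    ``tau``, the models move as one rigid body and a single-domain partition
    is returned.

    Otherwise the two-domain assignment is found by exact search: for
    bundles up to 16 helices every bipartition is scored by the summed
    squared CA residual of its two domain-level superpositions and the
    minimizer wins; larger bundles fall back to iterative reassignment from
    a two-cluster seeding. The group containing ``anchor_helix`` is
    labelled Domain I (for ZIP transporters that is the transport domain,
    which carries the metal sites).
    """
    transforms = per_helix_transforms(a, b, topology)
    names = [s.name for s in topology.segments if s.name in transforms]
    if len(names) < 2:
        raise ContractError("need at least two helices with transforms")
    n = len(names)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = transform_dissimilarity(transforms[names[i]][0], transforms[names[j]][0], lam)
            dmat[i, j] = dmat[j, i] = d
    z = linkage(squareform(dmat, checks=False), method="average")
    if len(set(fcluster(z, t=tau, criterion="distance"))) == 1:
        return DomainPartition({h: "I" for h in names}, single_domain=True)

    coords = {h: _helix_ca(a, b, topology, h) for h in names}

    # per-helix sufficient statistics; unions combine in O(1), so scoring a
    # bipartition needs only two 3x3 SVDs instead of two full Kabsch fits
    moments = {}
    for h in names:
        pa, pb = coords[h]
        ma, mb = pa.mean(axis=0), pb.mean(axis=0)
        moments[h] = (len(pa), ma, mb,
                      (pa - ma).T @ (pb - mb),
                      float(((pa - ma) ** 2).sum()), float(((pb - mb) ** 2).sum()))

    def fit_ssr(members: tuple[str, ...]) -> float:
        ntot = sum(moments[h][0] for h in members)
        ma = sum(moments[h][0] * moments[h][1] for h in members) / ntot
        mb = sum(moments[h][0] * moments[h][2] for h in members) / ntot
        cov = np.zeros((3, 3))
        pa = pb = 0.0
        for h in members:
            n_h, ma_h, mb_h, c_h, pa_h, pb_h = moments[h]
            cov += c_h + n_h * np.outer(ma_h - ma, mb_h - mb)
            pa += pa_h + n_h * float(((ma_h - ma) ** 2).sum())
            pb += pb_h + n_h * float(((mb_h - mb) ** 2).sum())
        svals = np.linalg.svd(cov, compute_uv=False)
        d = np.sign(np.linalg.det(cov)) or 1.0
        return pa + pb - 2.0 * (svals[0] + svals[1] + d * svals[2])

    def domain_fit(members) -> Transform:
        pa = np.vstack([coords[h][0] for h in sorted(members)])
        pb = np.vstack([coords[h][1] for h in sorted(members)])
        return superpose(pa, pb)[0]

    if n <= 16:
        best: tuple[float, frozenset[str]] | None = None
        for mask in range(1, 2 ** (n - 1)):  # fix the last helix out of 'group'
            group = tuple(names[i] for i in range(n) if mask >> i & 1)
            rest = tuple(h for h in names if h not in group)
            if not group or not rest:
                continue
            ssr = fit_ssr(group) + fit_ssr(rest)
            if best is None or ssr < best[0]:
                best = (ssr, frozenset(group))
        group_1 = set(best[1])
        group_2 = set(names) - group_1
    else:
        labels = fcluster(z, t=2, criterion="maxclust")
        group_1 = {names[i] for i in range(n) if labels[i] == 1}
        group_2 = set(names) - group_1

        def residual(h: str, t: Transform) -> float:
            pa, pb = coords[h]
            diff = t.apply(pa) - pb
            return float(np.sqrt((diff ** 2).sum() / len(pa)))

        for _ in range(max_iter):
            t1, t2 = domain_fit(group_1), domain_fit(group_2)
            new_1 = {h for h in names if residual(h, t1) <= residual(h, t2)}
            new_2 = set(names) - new_1
            if not new_1 or not new_2:
                return DomainPartition({h: "I" for h in names}, single_domain=True)
            if new_1 == group_1:
                break
            group_1, group_2 = new_1, new_2

    # the exact search can still land on a no-motion split under pure noise
    if transform_dissimilarity(domain_fit(group_1), domain_fit(group_2), lam) < tau:
        return DomainPartition({h: "I" for h in names}, single_domain=True)

    if anchor_helix in group_2:
        group_1, group_2 = group_2, group_1
    elif anchor_helix not in group_1:
        warnings.warn(f"anchor helix {anchor_helix!r} has no transform; "
                      "labelling first cluster as Domain I", stacklevel=2)
    assignment = {h: ("I" if h in group_1 else "II") for h in names}
    return DomainPartition(assignment)


@dataclass
class DomainMotionReport:
    """Rigid-body motion summary between two conformations."""

    label_a: str
    label_b: str
    partition: DomainPartition
    domain_rmsd: dict[str, float]          # within-domain superposition RMSD (A)
    overall_rmsd: float                     # all shared CA (whole models)
    core_rmsd: float                        # shared CA restricted to TM helices
    interdomain_rotation: float             # degrees, Domain I after Domain II alignment
    screw: ScrewAxis | None
    hinge_helix_end: tuple[str, int] | None  # nearest helix-terminal CA to the axis

    def to_dict(self) -> dict:
        d = {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "partition": dict(self.partition.assignment),
            "single_domain": self.partition.single_domain,
            "domain_rmsd": self.domain_rmsd,
            "overall_rmsd": self.overall_rmsd,
            "tm_core_rmsd": self.core_rmsd,
            "interdomain_rotation_deg": self.interdomain_rotation,
        }
        if self.screw is not None:
            d["screw"] = {
                "direction": self.screw.direction.tolist(),
                "point_on_axis": self.screw.point_on_axis.tolist(),
                "angle_deg": self.screw.angle,
                "pitch_A": self.screw.pitch,
            }
            d["hinge_nearest_helix_end"] = list(self.hinge_helix_end) if self.hinge_helix_end else None
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_table(self) -> str:
        lines = [f"domain motion: {self.label_a} vs {self.label_b}",
                 f"  overall CA RMSD   : {self.overall_rmsd:6.2f} A",
                 f"  TM-core CA RMSD   : {self.core_rmsd:6.2f} A"]
        for dom in ("I", "II"):
            if dom in self.domain_rmsd:
                helices = ",".join(self.partition.domain(dom))
                lines.append(f"  Domain {dom:<2} RMSD    : {self.domain_rmsd[dom]:6.2f} A  ({helices})")
        lines.append(f"  interdomain rot.  : {self.interdomain_rotation:6.2f} deg")
        if self.screw is not None and self.hinge_helix_end is not None:
            h, r = self.hinge_helix_end
            lines.append(f"  hinge near        : {h} end residue {r}")
        return "\n".join(lines)


def _axis_line_distance(point: np.ndarray, axis: ScrewAxis) -> float:
    v = point - axis.point_on_axis
    return float(np.linalg.norm(v - np.dot(v, axis.direction) * axis.direction))


def domain_motion_report(a: StructureModel, b: StructureModel, topology: TMTopology,
                         partition: DomainPartition) -> DomainMotionReport:
    """Per-domain RMSDs and the interdomain rotation after scaffold alignment.

    The interdomain rotation is measured by first aligning the two models on
    Domain II (the scaffold) and then superposing Domain I; its screw axis is
    reported along with the helix-terminal CA closest to the axis — the
    operational 'hinge point'.
    """
    if partition.single_domain or not partition.domain("II"):
        raise ContractError("partition has no Domain II; no interdomain motion to report")
    all_shared = shared_residues(a, b)
    overall = rmsd_between(select_coords(a, all_shared), select_coords(b, all_shared))
    tm_res = [r for s in topology.segments for r in s.residues()]
    core_shared = shared_residues(a, b, tm_res)
    core = rmsd_between(select_coords(a, core_shared), select_coords(b, core_shared))

    domain_rmsd: dict[str, float] = {}
    domain_transform: dict[str, Transform] = {}
    for dom in ("I", "II"):
        res = shared_residues(a, b, partition.residues(dom, topology))
        t, r = superpose(select_coords(a, res), select_coords(b, res))
        domain_rmsd[dom] = r
        domain_transform[dom] = t

    # align on Domain II, then measure the residual Domain I transform
    t2 = domain_transform["II"]
    res1 = shared_residues(a, b, partition.residues("I", topology))
    a1 = t2.apply(select_coords(a, res1))
    b1 = select_coords(b, res1)
    t1_rel, _ = superpose(a1, b1)
    angle = rotation_angle(t1_rel)
    screw = None
    hinge = None
    try:
        screw = screw_decompose(t1_rel)
    except DegenerateGeometryError:
        pass
    if screw is not None:
        # nearest helix-end CA (in the Domain-II-aligned frame of model a)
        best = None
        for seg in topology.segments:
            present = [r for r in seg.residues() if a.has_residue(r)]
            if not present:
                continue
            for term in (present[0], present[-1]):
                pos = t2.apply(a.atom_position(term, "CA")[None, :])[0]
                d = _axis_line_distance(pos, screw)
                if best is None or d < best[0]:
                    best = (d, (seg.name, term))
        hinge = best[1] if best else None
    return DomainMotionReport(
        label_a=a.label, label_b=b.label, partition=partition,
        domain_rmsd=domain_rmsd, overall_rmsd=overall, core_rmsd=core,
        interdomain_rotation=angle, screw=screw, hinge_helix_end=hinge,
    )
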