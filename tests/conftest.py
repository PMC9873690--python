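"""Shared fixtures: a tiny hand-written PDB, the synthetic elevator study,
and its repeat-swap products."""

from __future__ import annotations

import numpy as np
import pytest

from tmelevate.repeat_swap import load_repeat_alignment, thread_swap
from tmelevate.synthetic_data import elevator_study


def pdb_line(serial, name, resname, chain, resseq, x, y, z,
             altloc=" ", occ=1.00, het=False):
    rec = "HETATM" if het else "ATOM  "
    atom_field = f"{name:<4}" if len(name) > 3 else f" {name:<3}"
    return (f"{rec}{serial:5d} {atom_field}{altloc}{resname:<3} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {name[0]:>2}")


TINY_PDB_LINES = [
    # residue 1: MET with an altloc pair on CA (B has higher occupancy)
    pdb_line(1, "N", "MET", "A", 1, 0.000, 0.000, 0.000),
    pdb_line(2, "CA", "MET", "A", 1, 1.458, 0.000, 0.000, altloc="A", occ=0.40),
    pdb_line(3, "CA", "MET", "A", 1, 1.458, 0.100, 0.000, altloc="B", occ=0.60),
    pdb_line(4, "C", "MET", "A", 1, 2.009, 1.420, 0.000),
    pdb_line(5, "O", "MET", "A", 1, 1.251, 2.390, 0.000),
    pdb_line(6, "CB", "MET", "A", 1, 2.000, -0.700, -1.200),
    # residue 2: GLY (no CB)
    pdb_line(7, "N", "GLY", "A", 2, 3.332, 1.536, 0.000),
    pdb_line(8, "CA", "GLY", "A", 2, 4.040, 2.803, 0.119),
    pdb_line(9, "C", "GLY", "A", 2, 5.500, 2.600, 0.500),
    pdb_line(10, "O", "GLY", "A", 2, 6.000, 1.500, 0.400),
    # residue 3: ALA
    pdb_line(11, "N", "ALA", "A", 3, 6.200, 3.700, 0.900),
    pdb_line(12, "CA", "ALA", "A", 3, 7.630, 3.640, 1.250),
    pdb_line(13, "C", "ALA", "A", 3, 8.400, 4.900, 0.850),
    pdb_line(14, "O", "ALA", "A", 3, 7.900, 6.000, 1.100),
    pdb_line(15, "CB", "ALA", "A", 3, 8.300, 2.400, 0.650),
    # a metal ion as hetero record
    pdb_line(16, "CD", "CD", "A", 101, 4.000, 0.000, 2.000, het=True),
    "END",
]


@pytest.fixture()
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(TINY_PDB_LINES) + "\n")
    return path


@pytest.fixture(scope="session")
def study():
    return elevator_study(seed=0)


@pytest.fixture(scope="session")
def study_alignment(study, tmp_path_factory):
    path = tmp_path_factory.mktemp("aln") / "repeats.fasta"
    path.write_text(study.alignment_fasta)
    return load_repeat_alignment(path, study.topology)


@pytest.fixture(scope="session")
def study_swap(study, study_alignment):
    return thread_swap(study.holo, study_alignment, study.topology)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
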