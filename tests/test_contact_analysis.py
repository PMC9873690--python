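"""Contact filtering, structure-consistency classification and interface census."""

import numpy as np
import pytest

from tmelevate.contact_analysis import (ContactRecord, classify_contacts,
                                        filter_and_map, interface_census,
                                        interface_sensitivity, load_contacts)
from tmelevate.errors import StructureFormatError
from tmelevate.rigid_body import DomainPartition
from tmelevate.structure_io import (AtomRecord, HelixSegment, StructureModel,
                                    TMTopology)
from tmelevate.synthetic_data import contacts_to_csv, synth_contacts

from conftest import random_rotation


class TestLoadContacts:
    def test_toy_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("i,A_i,j,A_j,probability\n10,A,50,L,0.9\n11,G,60,V,0.5\n12,S,70,F,0.2\n")
        records = load_contacts(p)
        assert len(records) == 3
        assert records[0].probability == pytest.approx(0.9)

    def test_duplicate_reversed_pair_deduplicated(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("i,j,probability\n10,50,0.9\n50,10,0.8\n")
        records = load_contacts(p)
        assert len(records) == 1
        assert records[0].pair == (10, 50)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("x,y\n1,2\n")
        with pytest.raises(StructureFormatError, match="no column"):
            load_contacts(p)

    def test_alias_columns(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("pos_i,pos_j,score\n1,9,0.7\n")
        assert load_contacts(p)[0].probability == pytest.approx(0.7)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ContactRecord(5, 5, 0.9)
        with pytest.raises(ValueError):
            ContactRecord(1, 2, 1.5)


class TestFilterAndMap:
    def test_all_below_threshold_filtered(self, study):
        records = [ContactRecord(110, 210, 0.5), ContactRecord(111, 211, 0.74)]
        kept, matrix, totals = filter_and_map(records, study.topology, study.partition)
        assert kept == [] and matrix.values.sum() == 0

    def test_planted_helix_pair_localized(self, study):
        records = [ContactRecord(210, 510, 0.9), ContactRecord(212, 512, 0.95)]
        kept, matrix, totals = filter_and_map(records, study.topology, study.partition)
        assert matrix.loc["a2", "a5"] == 2 and matrix.loc["a5", "a2"] == 2
        assert matrix.values.sum() == 4  # nothing anywhere else
        assert totals["inter"] == 2

    def test_intrahelix_pairs_dropped(self, study):
        records = [ContactRecord(110, 115, 0.99)]
        kept, matrix, _ = filter_and_map(records, study.topology, study.partition)
        assert kept == [] and matrix.values.sum() == 0

    def test_matrix_symmetric_and_totals_consistent(self, study):
        recs, _ = synth_contacts(study.holo, study.topology, 15, 15, seed=2)
        records = [ContactRecord(i, j, p) for i, j, p in recs]
        kept, matrix, totals = filter_and_map(records, study.topology,
                                              study.partition, p_min=0.0)
        assert (matrix.values == matrix.values.T).all()
        assert matrix.values.sum() == 2 * sum(totals.values())


class TestClassifyContacts:
    def test_close_pair_consistent(self, study):
        rec = [ContactRecord(110, 111, 0.9)]
        cls = classify_contacts(rec, [study.holo], study.partition, study.topology)
        assert cls[0].category == "consistent"

    def test_planted_truth_recovered_perfectly(self, study):
        recs, truth = synth_contacts(study.holo, study.topology, 12, 12, seed=4)
        records = [ContactRecord(i, j, p) for i, j, p in recs]
        cls = classify_contacts(records, [study.holo], study.partition, study.topology)
        for c in cls:
            if truth[c.record.pair]:
                assert c.category == "consistent"
            else:
                assert c.category in ("inconsistent", "dimer-candidate")

    def test_rotated_copy_gives_identical_categories(self, study):
        rng = np.random.default_rng(8)
        recs, _ = synth_contacts(study.holo, study.topology, 8, 8, seed=6)
        records = [ContactRecord(i, j, p) for i, j, p in recs]
        rotated = study.holo.transformed(random_rotation(rng), rng.normal(size=3),
                                         label="rotated")
        c1 = classify_contacts(records, [study.holo], study.partition, study.topology)
        c2 = classify_contacts(records, [rotated], study.partition, study.topology)
        assert [c.category for c in c1] == [c.category for c in c2]

    def test_second_conformation_rescues_contact(self, study, study_swap):
        """A cross-domain pair far apart in the inward-facing state but close in
        the swapped outward-facing model is consistent once both are provided."""
        ofc = study_swap.model
        pair = None
        for a in study.partition.residues("II", study.topology):
            for b in study.partition.residues("I", study.topology):
                if not (ofc.has_residue(a) and ofc.has_residue(b)):
                    continue
                d_ifc = np.linalg.norm(study.holo.atom_position(a, "CA")
                                       - study.holo.atom_position(b, "CA"))
                d_ofc = np.linalg.norm(ofc.atom_position(a, "CA")
                                       - ofc.atom_position(b, "CA"))
                if d_ifc > 11.0 and d_ofc <= 8.0:
                    pair = (a, b)
                    break
            if pair:
                break
        assert pair, "stand-in should plant an OFC-rescued contact"
        rec = [ContactRecord(*pair, 0.9)]
        only_ifc = classify_contacts(rec, [study.holo], study.partition, study.topology)
        both = classify_contacts(rec, [study.holo, ofc], study.partition, study.topology)
        assert only_ifc[0].category == "inconsistent"
        assert both[0].category == "consistent"

    def test_scaffold_pairs_promoted_to_dimer_candidate(self, study):
        # opposite ends of the antiparallel a3/a8 pair: far apart, intra-II
        rec = [ContactRecord(302, 800, 0.9)]
        cls = classify_contacts(rec, [study.holo], study.partition, study.topology)
        assert cls[0].domain_type == "intra-II"
        assert cls[0].category == "dimer-candidate"

    def test_missing_residue_noted_not_fatal(self, study):
        rec = [ContactRecord(110, 9999, 0.9)]
        cls = classify_contacts(rec, [study.holo], study.partition, study.topology)
        assert cls[0].category == "ambiguous"
        assert cls[0].notes


def _flat_interface_model():
    """Two facing 5-residue rows 4 A apart (CB-CB), plus 5 distant residues."""
    atoms = []
    def add_residue(num, resname, x, y, face):
        # CB points along +-x toward the partner row
        atoms.extend([
            AtomRecord("A", num, resname, "N", (x, y - 0.5, -0.5)),
            AtomRecord("A", num, resname, "CA", (x, y, 0.0)),
            AtomRecord("A", num, resname, "C", (x, y + 0.7, 0.6)),
            AtomRecord("A", num, resname, "CB", (x + 1.5 * face, y, 0.0)),
        ])
    for k in range(5):
        add_residue(100 + k, "ALA", -3.5, 4.0 * k, +1)   # domain I row, CB at -2.0
        add_residue(200 + k, "LEU", 3.5, 4.0 * k, -1)    # domain II row, CB at +2.0
    for k in range(5):
        add_residue(110 + k, "PHE", -40.0, 4.0 * k, +1)  # far away, domain I
    topo = TMTopology([HelixSegment("h1", 100, 120), HelixSegment("h2", 200, 220)])
    part = DomainPartition({"h1": "I", "h2": "II"})
    return StructureModel("interface", atoms), topo, part


class TestInterfaceCensus:
    def test_constructed_interface_half_small(self):
        model, topo, part = _flat_interface_model()
        census = interface_census(model, part, topo, contact_cutoff=4.5)
        assert census["n_interface"] == 10
        assert census["small_fraction"] == pytest.approx(0.5)

    def test_distant_helices_no_interface(self):
        model, topo, part = _flat_interface_model()
        census = interface_census(model, part, topo, contact_cutoff=1.0)
        assert census["n_interface"] == 0

    def test_standin_interface_is_smooth(self, study):
        census = interface_census(study.holo, study.partition, study.topology)
        assert census["n_interface"] >= 10
        assert 0.2 <= census["small_fraction"] <= 0.8

    def test_sensitivity_monotone_in_cutoff(self, study):
        table = interface_sensitivity(study.holo, study.partition, study.topology)
        sizes = table["n_interface"].tolist()
        assert sizes == sorted(sizes)
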