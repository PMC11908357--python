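import copy

import numpy as np
import pytest

from plcurate import protein_fixer as pf
from plcurate.config import WorkflowConfig
from plcurate.fixtures import FixtureSpec, build_helix, make_fixture
from plcurate.structure_io import parse_mmcif_header, parse_pdb


def _fixture_protein(defect=None, subs=((5, "LYS"), (9, "ASP"),
                                        (12, "HIS"), (16, "SER"))):
    spec = FixtureSpec(seed=19, substitutions=subs,
                       defects=(defect,) if defect else ())
    fb = make_fixture(spec)
    st = parse_pdb(fb.pdb_text, entry_id="FIX1")
    meta = parse_mmcif_header(fb.cif_text)
    protein = copy.deepcopy(st)
    protein.chains = [c for c in protein.chains if c.is_polymer]
    return protein, meta


class TestDetect:
    def test_complete_chain_reports_nothing(self):
        protein, meta = _fixture_protein()
        report = pf.detect_missing(protein, meta)
        assert report.nothing_missing

    def test_terminal_segment_detected_and_skipped(self):
        protein, meta = _fixture_protein("delete_terminal_segment:3")
        report = pf.detect_missing(protein, meta)
        (seg,) = report.missing_segments
        assert seg.is_terminal and seg.length == 3
        assert report.to_repair_segments == []
        assert report.to_skip_segments == [seg]

    def test_internal_gap_detected_for_repair(self):
        protein, meta = _fixture_protein("delete_internal_segment:4")
        report = pf.detect_missing(protein, meta)
        (seg,) = report.missing_segments
        assert not seg.is_terminal and seg.length == 4
        assert report.to_repair_segments == [seg]

    def test_long_gap_partitioned_to_skip(self):
        protein, meta = _fixture_protein("delete_internal_segment:12",
                                         subs=())
        cfg = WorkflowConfig()
        report = pf.detect_missing(protein, meta, cfg)
        (seg,) = report.missing_segments
        assert seg.length == 12 > cfg.missing_segment_max
        assert report.to_skip_segments == [seg]

    def test_missing_side_chain_atom_detected(self):
        protein, meta = _fixture_protein("delete_side_chain_atom:5/NZ")
        report = pf.detect_missing(protein, meta)
        assert (("A", 5, "", "LYS"), ["NZ"]) in report.missing_atoms

    def test_chain_absent_from_header_is_metadata_error(self):
        protein, meta = _fixture_protein()
        meta.full_sequences.clear()
        with pytest.raises(pf.MetadataError):
            pf.detect_missing(protein, meta)


class TestRepair:
    def test_missing_atom_rebuilt_at_sane_geometry(self):
        protein, meta = _fixture_protein("delete_side_chain_atom:5/NZ")
        report = pf.detect_missing(protein, meta)
        repaired, notes = pf.repair_protein(protein, report)
        res = repaired.chain("A").residue(5)
        nz = res.atom("NZ")
        assert nz is not None and not nz.is_experimental
        d = np.linalg.norm(nz.position - res.atom("CE").position)
        assert 1.2 < d < 1.8                      # CE-NZ bond range
        assert any("NZ" in n for n in notes)

    def test_internal_gap_rebuilt_with_flagged_atoms(self):
        protein, meta = _fixture_protein("delete_internal_segment:4")
        report = pf.detect_missing(protein, meta)
        n_before = protein.n_atoms()
        repaired, notes = pf.repair_protein(protein, report)
        chain = repaired.chain("A")
        assert len(chain.residues) == 20
        added = [a for _, r, a in repaired.iter_atoms()
                 if not a.is_experimental]
        assert len(added) == repaired.n_atoms() - n_before
        assert all(8 <= r.seq_number <= 11 for _, r, a in repaired.iter_atoms()
                   if not a.is_experimental)
        # rebuilt backbone must be chemically bonded to its anchors
        c7 = chain.residue(7).atom("C").position
        n8 = chain.residue(8).atom("N").position
        assert np.linalg.norm(c7 - n8) < 1.8

    def test_terminal_and_long_gaps_left_absent(self):
        protein, meta = _fixture_protein("delete_terminal_segment:3")
        report = pf.detect_missing(protein, meta)
        repaired, notes = pf.repair_protein(protein, report)
        assert len(repaired.chain("A").residues) == 17
        assert any("chain break preserved" in n for n in notes)

    def test_experimental_atoms_never_move(self):
        protein, meta = _fixture_protein("delete_internal_segment:4")
        before = {(c.chain_id, r.seq_number, a.name): a.position.copy()
                  for c, r, a in protein.iter_atoms()}
        report = pf.detect_missing(protein, meta)
        repaired, _ = pf.repair_protein(protein, report)
        for c, r, a in repaired.iter_atoms():
            if a.is_experimental:
                assert np.array_equal(
                    a.position, before[(c.chain_id, r.seq_number, a.name)])

    def test_repair_is_idempotent(self):
        protein, meta = _fixture_protein("delete_side_chain_atom:5/NZ")
        report = pf.detect_missing(protein, meta)
        repaired, _ = pf.repair_protein(protein, report)
        n = repaired.n_atoms()
        report2 = pf.detect_missing(repaired, meta)
        assert report2.nothing_missing
        again, notes = pf.repair_protein(repaired, report2)
        assert again.n_atoms() == n and notes == []


@pytest.fixture(scope="module")
def protonated():
    protein, _ = _fixture_protein()
    return pf.protonate_protein(protein)


class TestProtonation:

    def test_lysine_gets_three_protons_on_nz(self, protonated):
        res = protonated.chain("A").residue(5)
        hz = [a for a in res.atoms if a.element == "H"
              and a.name.startswith("HZ")]
        assert len(hz) == 3

    def test_aspartate_carboxylate_unprotonated(self, protonated):
        res = protonated.chain("A").residue(9)
        od = [a.name for a in res.atoms if a.element == "H"
              and a.name.startswith("HD")]
        assert od == []

    def test_histidine_neutral_single_ring_proton(self, protonated):
        res = protonated.chain("A").residue(12)
        ring_h = [a for a in res.atoms if a.element == "H"
                  and a.name[:3] in ("HD1", "HE2")]
        assert len(ring_h) == 1

    def test_hydrogens_flagged_not_experimental(self, protonated):
        for _, _, a in protonated.iter_atoms():
            if a.element == "H":
                assert not a.is_experimental

    def test_count_conservation_and_idempotence(self):
        protein, _ = _fixture_protein()
        n_heavy = protein.n_atoms()
        once = pf.protonate_protein(protein)
        n_h = sum(1 for _, _, a in once.iter_atoms() if a.element == "H")
        assert once.n_atoms() == n_heavy + n_h
        twice = pf.protonate_protein(once)
        assert twice.n_atoms() == once.n_atoms()

    def test_his_variant_prefers_free_acceptor_near_polar_atom(self):
        # polar neighbour close to ND1 and nothing near NE2: the proton
        # goes on NE2 so ND1 stays free to accept (HIE)
        protein, _ = _fixture_protein()
        his = protein.chain("A").residue(12)
        nd1 = his.atom("ND1")
        polar = np.array([nd1.position + np.array([0, 0, 2.9])])
        assert pf._his_variant(his, polar) == "HIE"
        # and the mirror case selects HID
        ne2 = his.atom("NE2")
        polar = np.array([ne2.position + np.array([0, 0, 2.9])])
        assert pf._his_variant(his, polar) == "HID"

    def test_disulfide_cysteines_not_protonated(self):
        helix = build_helix(12, {4: "CYS", 8: "CYS"})
        chain = helix.chains[0]
        sg1 = chain.residue(4).atom("SG")
        sg2 = chain.residue(8).atom("SG")
        sg2.position = sg1.position + np.array([2.0, 0.0, 0.0])
        out = pf.protonate_protein(helix)
        for seq in (4, 8):
            hs = [a for a in out.chain("A").residue(seq).atoms
                  if a.element == "H" and a.name.startswith("HG")]
            assert hs == []
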