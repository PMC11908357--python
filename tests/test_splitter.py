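import numpy as np
import pytest

from plcurate import splitter as sp
from plcurate.config import WorkflowConfig
from plcurate.structure_io import AtomRecord, ChainRecord, ResidueRecord, Structure


def _atom(serial, name, element, xyz, kind="ATOM"):
    return AtomRecord(serial=serial, name=name, element=element, alt_loc="",
                      position=np.array(xyz, float), record_kind=kind)


def _toy_structure(chain_b_offset=5.0, het_offset=3.0):
    """Chain A (polymer) on the x axis, chain C polymer at a configurable
    offset, one ATP copy in two chains, one Zn ion near chain A."""
    a = ChainRecord(chain_id="A", is_polymer=True, residues=[
        ResidueRecord(name="ALA", seq_number=i, atoms=[
            _atom(i * 10, "CA", "C", [float(i), 0, 0])])
        for i in range(1, 6)])
    c = ChainRecord(chain_id="C", is_polymer=True, residues=[
        ResidueRecord(name="GLY", seq_number=1, atoms=[
            _atom(100, "CA", "C", [2.0, 1.0 + chain_b_offset, 0])])])
    lig1 = ChainRecord(chain_id="L", residues=[
        ResidueRecord(name="ATP", seq_number=1, atoms=[
            _atom(200, "C1", "C", [2.0, 1.0, 0], kind="HETATM"),
            _atom(201, "C2", "C", [3.0, 1.0, 0], kind="HETATM"),
            _atom(202, "N1", "N", [4.0, 1.0, 0], kind="HETATM"),
            _atom(203, "O1", "O", [5.0, 1.0, 0], kind="HETATM")])])
    lig2 = ChainRecord(chain_id="M", residues=[
        ResidueRecord(name="ATP", seq_number=1, atoms=[
            _atom(300, "C1", "C", [2.0, -1.0, 0], kind="HETATM"),
            _atom(301, "C2", "C", [3.0, -1.0, 0], kind="HETATM"),
            _atom(302, "N1", "N", [4.0, -1.0, 0], kind="HETATM"),
            _atom(303, "O1", "O", [5.0, -1.0, 0], kind="HETATM")])])
    zn = ChainRecord(chain_id="Z", residues=[
        ResidueRecord(name="ZN", seq_number=1, atoms=[
            _atom(400, "ZN", "Zn", [1.0, het_offset, 0], kind="HETATM")])])
    return Structure(entry_id="TOY1", chains=[a, c, lig1, lig2, zn])


def test_ccd_spec_yields_one_instance_per_copy():
    st = _toy_structure()
    spec = sp.LigandSpec(kind="ccd", ccd_code="ATP")
    instances = sp.identify_ligands(st, [spec])
    assert len(instances) == 2
    assert [i.chain_id for i in instances] == ["L", "M"]   # deterministic order
    assert all(len(i.atoms) == 4 for i in instances)


def test_polymer_spec_bounds():
    st = _toy_structure()
    five_mer = sp.LigandSpec(kind="polymer", chain_id="A")
    inst = sp.identify_ligands(st, [five_mer])[0]
    assert inst.n_residues == 5

    cfg = WorkflowConfig()
    big = Structure(entry_id="X", chains=[ChainRecord(
        chain_id="P", is_polymer=True, residues=[
            ResidueRecord(name="ALA", seq_number=i, atoms=[
                _atom(i, "CA", "C", [float(i), 0, 0])])
            for i in range(1, 26)])])
    with pytest.raises(sp.PolymerClassViolation):
        sp.identify_ligands(big, [sp.LigandSpec(kind="polymer", chain_id="P")],
                            cfg)
    single = sp.LigandSpec(kind="polymer", chain_id="C")
    with pytest.raises(sp.PolymerClassViolation):
        sp.identify_ligands(st, [single])


def test_unmatched_spec_raises():
    with pytest.raises(sp.LigandNotFoundError):
        sp.identify_ligands(_toy_structure(),
                            [sp.LigandSpec(kind="ccd", ccd_code="GTP")])


@pytest.mark.parametrize("offset,included", [(9.5, True), (10.5, False)])
def test_association_cutoff_bracketing(offset, included):
    st = _toy_structure(chain_b_offset=offset)
    lig = sp.identify_ligands(st, [sp.LigandSpec(kind="ccd", ccd_code="ATP")])[0]
    bundle = sp.extract_complex(st, lig)
    assert ("C" in [c.chain_id for c in bundle.protein.chains]) == included


@pytest.mark.parametrize("offset,is_additive", [(3.0, True), (4.5, False)])
def test_additive_cutoff_bracketing(offset, is_additive):
    st = _toy_structure(chain_b_offset=50.0, het_offset=offset)
    lig = sp.identify_ligands(st, [sp.LigandSpec(kind="ccd", ccd_code="ATP")])[0]
    bundle = sp.extract_complex(st, lig)
    assert (any(r.name == "ZN" for r in bundle.additives)) == is_additive


def test_other_ligand_copy_never_an_additive():
    st = _toy_structure()
    ligs = sp.identify_ligands(st, [sp.LigandSpec(kind="ccd", ccd_code="ATP")])
    keys = {(li.chain_id, r.seq_number, r.insertion_code)
            for li in ligs for r in li.residues}
    own = {(ligs[0].chain_id, r.seq_number, r.insertion_code)
           for r in ligs[0].residues}
    bundle = sp.extract_complex(st, ligs[0],
                                exclude_ligand_residues=keys - own)
    assert all(r.name != "ATP" for r in bundle.additives)


def test_orphan_ligand_rejected():
    st = _toy_structure()
    far = ChainRecord(chain_id="F", residues=[
        ResidueRecord(name="XYZ", seq_number=1, atoms=[
            _atom(500, "C1", "C", [500, 500, 500], kind="HETATM"),
            _atom(501, "C2", "C", [501, 500, 500], kind="HETATM"),
            _atom(502, "C3", "C", [502, 500, 500], kind="HETATM"),
            _atom(503, "C4", "C", [503, 500, 500], kind="HETATM")])])
    st.chains.append(far)
    lig = sp.identify_ligands(st, [sp.LigandSpec(kind="ccd", ccd_code="XYZ")])[0]
    with pytest.raises(sp.OrphanLigandError):
        sp.extract_complex(st, lig)


def test_roles_are_disjoint(clean_complex):
    lig_serials = {a.serial for a in clean_complex.ligand.atoms}
    prot_serials = {a.serial for _, _, a in clean_complex.protein.iter_atoms()}
    add_serials = {a.serial for r in clean_complex.additives for a in r.atoms}
    assert not (lig_serials & prot_serials)
    assert not (lig_serials & add_serials)
    assert not (prot_serials & add_serials)


def test_extraction_deterministic(clean_structure, cfg):
    lig = sp.identify_ligands(clean_structure,
                              [sp.LigandSpec(kind="ccd", ccd_code="LIG")])[0]
    b1 = sp.extract_complex(clean_structure, lig, cfg)
    b2 = sp.extract_complex(clean_structure, lig, cfg)
    assert [c.chain_id for c in b1.protein.chains] == \
        [c.chain_id for c in b2.protein.chains]
    assert [r.key for r in b1.additives] == [r.key for r in b2.additives]


@pytest.mark.parametrize("adapter,rows,expected", [
    (sp.specs_from_simple_csv,
     [{"entry_id": "1abc", "ccd_or_span": "ATP"},
      {"entry_id": "1abc", "ccd_or_span": "B:1-5"}],
     [("ccd", "ATP"), ("polymer", None)]),
    (sp.specs_from_biolip,
     [{"pdb_id": "1abc", "ligand_ccd": "peptide", "ligand_chain": "B"},
      {"pdb_id": "1abc", "ligand_ccd": "HEM", "ligand_chain": "A"}],
     [("polymer", None), ("ccd", "HEM")]),
    (sp.specs_from_moad,
     [{"pdb_id": "1abc", "ligand_name": "NAG NAG BMA", "ligand_chain": "C"},
      {"pdb_id": "1abc", "ligand_name": "GDP", "ligand_chain": "A"}],
     [("polymer", None), ("ccd", "GDP")]),
    (sp.specs_from_pdbbind,
     [{"pdb_id": "1abc", "ligand_name": "5-mer", "ligand_chain": "B"},
      {"pdb_id": "1abc", "ligand_name": "(ATP)", "ligand_chain": "A"}],
     [("polymer", None), ("ccd", "ATP")]),
])
def test_dialect_adapters(adapter, rows, expected):
    specs = adapter(rows, "1ABC")
    assert [(s.kind, s.ccd_code) for s in specs] == expected
    assert adapter(rows, "9zzz") == []
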