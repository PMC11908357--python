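import copy

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from plcurate import analysis as an
from plcurate.config import WorkflowConfig
from plcurate.fixtures import build_helix, ligand_instance_from_smiles
from plcurate.splitter import LigandInstance, LigandSpec
from plcurate.structure_io import AtomRecord, ChainRecord, ResidueRecord


class TestPeriodicDifference:
    def test_wraparound_pair(self):
        assert an.periodic_difference(-179.0, 179.0) == pytest.approx(2.0)

    def test_matches_enumerated_brute_force(self):
        # oracle: smallest |a - b + 360k| over k
        grid = np.arange(-180.0, 180.1, 7.5)
        for a in grid:
            for b in grid:
                brute = min(abs(a - b + 360.0 * k) for k in (-2, -1, 0, 1, 2))
                assert an.periodic_difference(a, b) == pytest.approx(brute)

    def test_symmetric_torsion_period(self):
        # chemically equivalent terminal atoms fold by 180 degrees
        assert an.periodic_difference(10.0, 190.0, period=180.0) == \
            pytest.approx(0.0)


def _rotamer_pair(chi1_shift):
    """Two copies of a helix with one LYS; chain b's LYS chi1 rotated."""
    a = build_helix(10, {5: "LYS"}).chains[0]
    b = copy.deepcopy(a)
    b.chain_id = "B"
    res = b.residue(5)
    n, ca, cb = (res.atom(x).position for x in ("N", "CA", "CB"))
    axis = cb - ca
    axis /= np.linalg.norm(axis)
    ang = np.radians(chi1_shift)

    def rotate(p):
        v = p - cb
        return cb + (v * np.cos(ang) + np.cross(axis, v) * np.sin(ang)
                     + axis * np.dot(axis, v) * (1 - np.cos(ang)))
    for name in ("CG", "CD", "CE", "NZ"):
        res.atom(name).position = rotate(res.atom(name).position)
    lig = ligand_instance_from_smiles("NC(=N)c1ccccc1", seed=3)
    centroid = np.mean([r.atom("CA").position for r in a.residues], axis=0)
    shift = centroid + np.array([6.0, 0, 0]) - lig.coordinates().mean(axis=0)
    for atom in lig.residues[0].atoms:
        atom.position = atom.position + shift
    return a, b, lig


class TestCompareRotamers:
    @pytest.mark.parametrize("shift,changed", [(65.0, True), (55.0, False)])
    def test_cutoff_bracketing(self, shift, changed):
        a, b, lig = _rotamer_pair(shift)
        cmp = an.compare_rotamers(a, b, lig, site_cutoff=30.0)
        assert cmp.changed[5] == changed

    def test_symmetric_in_chain_order(self):
        a, b, lig = _rotamer_pair(65.0)
        c1 = an.compare_rotamers(a, b, lig, site_cutoff=30.0)
        c2 = an.compare_rotamers(b, a, lig, site_cutoff=30.0)
        assert c1.changed == c2.changed
        assert (c1.n_near_site, c1.n_changed) == (c2.n_near_site, c2.n_changed)

    def test_ala_gly_excluded_from_counts(self):
        a, b, lig = _rotamer_pair(65.0)
        cmp = an.compare_rotamers(a, b, lig, site_cutoff=1000.0)
        assert cmp.n_near_site == 1          # only the LYS carries chi

    def test_sequence_mismatch_raises(self):
        a, b, lig = _rotamer_pair(65.0)
        b.residue(5).name = "ARG"
        with pytest.raises(an.PairingError):
            an.compare_rotamers(a, b, lig, site_cutoff=30.0)


def _quaternion_oracle_rmsd(P, Q):
    """Horn's closed-form quaternion method, independent of the
    implementation under test."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx = P.T @ Q
    K = np.array([
        [Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2], Sxx[1, 2] - Sxx[2, 1],
         Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] - Sxx[1, 0]],
        [Sxx[1, 2] - Sxx[2, 1], Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2],
         Sxx[0, 1] + Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2]],
        [Sxx[2, 0] - Sxx[0, 2], Sxx[0, 1] + Sxx[1, 0],
         -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2], Sxx[1, 2] + Sxx[2, 1]],
        [Sxx[0, 1] - Sxx[1, 0], Sxx[2, 0] + Sxx[0, 2],
         Sxx[1, 2] + Sxx[2, 1], -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]]])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P ** 2) + np.sum(Q ** 2) - 2.0 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


class TestRMSD:
    def test_identity_is_zero(self):
        pts = np.random.default_rng(0).normal(size=(7, 3))
        assert an.compute_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 3))
        assert an.compute_rmsd(pts, pts + [1.0, 0, 0]) == \
            pytest.approx(0.0, abs=1e-9)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        # sqrt of a catastrophically-cancelled msd: ~1e-8 float noise floor
        assert an.compute_rmsd(pts, pts @ R.T + [2, -3, 1]) == \
            pytest.approx(0.0, abs=1e-6)

    def test_matches_quaternion_oracle_on_small_instances(self):
        rng = np.random.default_rng(2)
        for n in (4, 5, 6):
            for _ in range(10):
                P = rng.normal(size=(n, 3))
                Q = rng.normal(size=(n, 3))
                assert an.compute_rmsd(P, Q) == pytest.approx(
                    _quaternion_oracle_rmsd(P, Q), abs=1e-9)

    def test_size_mismatch_raises(self):
        with pytest.raises(an.CorrespondenceError):
            an.compute_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


def _mol(smiles):
    m = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 3
    AllChem.EmbedMolecule(m, params)
    return m


class TestProperties:
    def test_benzene_counts_and_mass(self):
        p = an.ligand_properties(_mol("c1ccccc1"))
        assert p.n_heavy_atoms == 6
        assert p.n_rotatable_bonds == 0
        assert p.n_hbd == 0
        assert p.molecular_weight == pytest.approx(6 * 12.011 + 6 * 1.008,
                                                   abs=0.02)

    def test_carbon_dioxide_heavy_atoms(self):
        p = an.ligand_properties(_mol("O=C=O"))
        assert p.n_heavy_atoms == 3

    @pytest.mark.parametrize("smiles,hbd,hba,rot", [
        ("CC(=O)Oc1ccccc1C(=O)O", 1, 3, 2),        # aspirin (Lipinski defs)
        ("CCO", 1, 1, 0),
        ("NCCO", 2, 2, 1),
        ("c1ccc(cc1)C(=O)N", 1, 1, 1),
    ])
    def test_count_descriptors_hand_checked(self, smiles, hbd, hba, rot):
        p = an.ligand_properties(_mol(smiles))
        assert (p.n_hbd, p.n_hba, p.n_rotatable_bonds) == (hbd, hba, rot)

    def test_qed_in_unit_interval(self):
        for smiles in ("c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "NCCO"):
            assert 0.0 <= an.ligand_properties(_mol(smiles)).qed <= 1.0


def test_min_interface_distance_matches_brute_force():
    rng = np.random.default_rng(7)
    prot = rng.uniform(-5, 5, size=(40, 3))
    lig = rng.uniform(-5, 5, size=(6, 3))
    brute = min(np.linalg.norm(p - l) for p in prot for l in lig)
    assert an.min_interface_distance(prot, lig) == pytest.approx(brute)
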