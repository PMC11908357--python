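"""Dataset characterization: rotamer changes, RMSD, ligand properties.

Crystals of homo-multimers resolve each chain against its own electron
density, so copies of the same chain are genuinely independent samples of
the binding site; comparing their side-chain rotamer states (a change is
any chi torsion differing by more than 60 degrees, under periodic
difference) quantifies that variation. RMSD after optimal rigid
superposition summarizes global agreement, and standard drug-likeness
descriptors characterize the ligand chemistry of a curated set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from scipy.spatial import cKDTree

from ._residues import CHI_ATOMS, CHI_SYMMETRIC
from .config import WorkflowConfig
from .splitter import LigandInstance
from .structure_io import ChainRecord, ResidueRecord

logger = logging.getLogger(__name__)


class PairingError(ValueError):
    pass


class CorrespondenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (-180, 180]."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return float(ang) if ang != -180.0 else 180.0


def periodic_difference(a: float, b: float, period: float = 360.0) -> float:
    """Magnitude of the angular difference on a circle of the given period."""
    d = abs(a - b) % period
    return min(d, period - d)


def chi_angles(res: ResidueRecord) -> List[Optional[float]]:
    """Side-chain chi1..chi4 for one residue (None where atoms are absent;
    empty list for residues without chi torsions, GLY/ALA)."""
    quads = CHI_ATOMS.get(res.name, [])
    out: List[Optional[float]] = []
    for quad in quads:
        atoms = [res.atom(n) for n in quad]
        if any(a is None for a in atoms):
            out.append(None)
        else:
            out.append(dihedral(*(a.position for a in atoms)))
    return out


@dataclass
class RotamerComparison:
    residues: List[Tuple[int, str]] = field(default_factory=list)
    chi_a: Dict[int, List[Optional[float]]] = field(default_factory=dict)
    chi_b: Dict[int, List[Optional[float]]] = field(default_factory=dict)
    changed: Dict[int, bool] = field(default_factory=dict)

    @property
    def n_near_site(self) -> int:
        return len(self.residues)

    @property
    def n_changed(self) -> int:
        return sum(1 for v in self.changed.values() if v)


def _chi_changed(chis_a: Sequence[Optional[float]],
                 chis_b: Sequence[Optional[float]],
                 resname: str, cutoff: float) -> bool:
    for k, (a, b) in enumerate(zip(chis_a, chis_b), start=1):
        if a is None or b is None:
            continue
        period = 180.0 if (resname, k) in CHI_SYMMETRIC else 360.0
        if periodic_difference(a, b, period) > cutoff:
            return True
    return False


def compare_rotamers(chain_a: ChainRecord, chain_b: ChainRecord,
                     ligand: LigandInstance, site_cutoff: float = 10.0,
                     cfg: Optional[WorkflowConfig] = None) -> RotamerComparison:
    """Rotamer-state changes between two identical chains near a ligand.

    Residues are paired by sequence position (the chains must share their
    sequence over the paired span); a residue is near the site when any of
    its heavy atoms in either chain lies within ``site_cutoff`` of a ligand
    heavy atom; a change is any defined chi differing by more than the
    configured cutoff under periodic difference, with terminal two-fold
    symmetric torsions folded by 180 degrees. GLY/ALA carry no chi and are
    excluded from the counts. Symmetric in the two chains.
    """
    cfg = cfg or WorkflowConfig()
    by_seq_b = {r.key: r for r in chain_b.residues}
    lig_tree = cKDTree(ligand.coordinates())

    result = RotamerComparison()
    for res_a in chain_a.residues:
        res_b = by_seq_b.get(res_a.key)
        if res_b is None:
            continue
        if res_a.name != res_b.name:
            raise PairingError(
                f"sequence mismatch at {res_a.seq_number}: "
                f"{res_a.name} vs {res_b.name}")
        if not CHI_ATOMS.get(res_a.name):
            continue
        near = False
        for r in (res_a, res_b):
            coords = np.array([a.position for a in r.heavy_atoms()])
            if coords.size and lig_tree.query(coords)[0].min() < site_cutoff:
                near = True
                break
        if not near:
            continue
        ca, cb = chi_angles(res_a), chi_angles(res_b)
        result.residues.append((res_a.seq_number, res_a.name))
        result.chi_a[res_a.seq_number] = ca
        result.chi_b[res_a.seq_number] = cb
        result.changed[res_a.seq_number] = _chi_changed(
            ca, cb, res_a.name, cfg.rotamer_angle_cutoff)
    return result


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def compute_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of two matched point sets after optimal rigid superposition
    (least-squares rotation and translation, Kabsch SVD)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise CorrespondenceError(
            f"point sets must match one-to-one, got {a.shape} vs {b.shape}")
    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    U, S, Vt = np.linalg.svd(bc.T @ ac)
    if np.linalg.det(U @ Vt) < 0:        # keep a proper rotation
        S = S.copy()
        S[-1] *= -1.0
    msd = (np.sum(ac ** 2) + np.sum(bc ** 2) - 2.0 * np.sum(S)) / len(a)
    return float(np.sqrt(max(msd, 0.0)))


# ---------------------------------------------------------------------------
# ligand descriptors
# ---------------------------------------------------------------------------

@dataclass
class PropertyProfile:
    molecular_weight: float
    clogp: float
    tpsa: float
    n_rotatable_bonds: int
    n_heavy_atoms: int
    n_hbd: int
    n_hba: int
    qed: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def ligand_properties(mol) -> PropertyProfile:
    """Eight standard drug-likeness descriptors of a chemistry-complete
    molecule (TPSA by fragment contributions, QED by the desirability
    composite, rotatable bonds excluding amide and ring bonds)."""
    rdmol = mol.to_rdkit() if hasattr(mol, "to_rdkit") else mol
    # descriptors are defined on the implicit-hydrogen graph
    rdmol = Chem.RemoveHs(Chem.Mol(rdmol))
    profile = PropertyProfile(
        molecular_weight=Descriptors.MolWt(rdmol),
        clogp=Crippen.MolLogP(rdmol),
        tpsa=rdMolDescriptors.CalcTPSA(rdmol),
        n_rotatable_bonds=Lipinski.NumRotatableBonds(rdmol),
        n_heavy_atoms=rdmol.GetNumHeavyAtoms(),
        n_hbd=Lipinski.NumHDonors(rdmol),
        n_hba=Lipinski.NumHAcceptors(rdmol),
        qed=QED.qed(rdmol),
    )
    assert 0.0 <= profile.qed <= 1.0
    return profile


def min_interface_distance(protein_coords: np.ndarray,
                           ligand_coords: np.ndarray) -> float:
    """Minimum protein-ligand heavy-atom distance (the quantity behind the
    steric-clash diagnostics)."""
    tree = cKDTree(np.asarray(protein_coords, float))
    return float(tree.query(np.asarray(ligand_coords, float))[0].min())
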