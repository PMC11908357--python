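"""Constrained energy minimization of the recombined complex.

The fixed protein and fixed ligand are merged into one system and relaxed
under a classical force field with every experimentally resolved atom
frozen: only hydrogens (protein and ligand) and atoms added by the repair
module may move. This resolves residual steric clashes among added atoms
and lets the protein-ligand hydrogen-bond network settle, without touching
any deposited coordinate.

The constraint is a contract — zero displacement of experimental atoms —
not a prescription for how to achieve it; here it is enforced with fixed
points in the minimizer, which removes the frozen coordinates from the
optimization entirely. The force field is UFF, applied uniformly to the
protein and ligand; minimization is in vacuum with no periodic box, since
only local hydrogen/added-atom relaxation is required. Additives are
excluded from the minimized system (they are deposited separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem.rdForceFieldHelpers import (UFFGetMoleculeForceField,
                                            UFFHasAllMoleculeParams)
from rdkit.Geometry import Point3D

from .config import WorkflowConfig
from .ligand_fixer import MoleculeGraph
from .protein_fixer import build_protein_mol
from .structure_io import Structure

logger = logging.getLogger(__name__)


class RefinementError(ValueError):
    """Parameterization or minimization failure; the entry is excluded."""


@dataclass
class RefinementResult:
    protein: Structure
    ligand: MoleculeGraph
    converged: bool
    energy_initial: float
    energy_final: float
    max_moved_constrained: float
    n_fixed: int
    n_movable: int


def minimize_complex(protein: Structure, ligand: MoleculeGraph,
                     cfg: Optional[WorkflowConfig] = None) -> RefinementResult:
    """Minimize the protein-ligand system with experimental atoms frozen.

    The protein must already be hydrogenated (its hydrogens carry
    ``is_experimental=False``); the ligand must be chemistry-complete with
    explicit hydrogens. Coordinates are written back into the inputs'
    copies held by the result. Deterministic: no stochastic steps.
    """
    cfg = cfg or WorkflowConfig()
    try:
        prot_mol = build_protein_mol(protein, cfg)
    except Exception as exc:
        raise RefinementError(f"protein not parameterizable: {exc}") from exc
    lig_mol = Chem.Mol(ligand.to_rdkit())
    if lig_mol.GetNumConformers() == 0:
        raise RefinementError("ligand has no 3D coordinates")

    combo = Chem.CombineMols(prot_mol, lig_mol)
    try:
        Chem.SanitizeMol(combo)
        if not UFFHasAllMoleculeParams(combo):
            raise RefinementError("force-field parameters missing for system")
        ff = UFFGetMoleculeForceField(combo, ignoreInterfragInteractions=False)
    except RefinementError:
        raise
    except Exception as exc:
        raise RefinementError(f"force-field setup failed: {exc}") from exc

    n_prot = prot_mol.GetNumAtoms()
    prot_atoms = [a for _, _, a in protein.iter_atoms()]
    assert len(prot_atoms) == n_prot, "protein atom order mismatch"

    fixed_idx: List[int] = []
    for i, atom in enumerate(prot_atoms):
        if atom.is_experimental:
            fixed_idx.append(i)
    for j, atom in enumerate(lig_mol.GetAtoms()):
        # ligand heavy atoms originate from the crystal; hydrogens are added
        if atom.GetAtomicNum() > 1:
            fixed_idx.append(n_prot + j)
    for i in fixed_idx:
        ff.AddFixedPoint(i)
    n_movable = combo.GetNumAtoms() - len(fixed_idx)

    conf = combo.GetConformer()
    before = np.array([list(conf.GetAtomPosition(i))
                       for i in range(combo.GetNumAtoms())])
    e0 = ff.CalcEnergy()
    if not np.isfinite(e0):
        # residual overlap among added atoms: deterministically nudge only
        # the movable atoms and retry once
        logger.warning("non-finite initial energy; perturbing movable atoms")
        rng = np.random.default_rng(0)
        movable = sorted(set(range(combo.GetNumAtoms())) - set(fixed_idx))
        for i in movable:
            p = before[i] + rng.normal(scale=0.05, size=3)
            conf.SetAtomPosition(i, Point3D(*p))
        e0 = ff.CalcEnergy()
        if not np.isfinite(e0):
            raise RefinementError("initial energy non-finite after perturbation")

    status = ff.Minimize(maxIts=cfg.minimize_max_iterations,
                         energyTol=1e-8, forceTol=1e-4)
    e1 = ff.CalcEnergy()
    if e1 > e0 + cfg.minimize_energy_tol:
        raise RefinementError(
            f"energy increased during minimization ({e0:.1f} -> {e1:.1f})")

    after = np.array([list(conf.GetAtomPosition(i))
                      for i in range(combo.GetNumAtoms())])
    max_moved = float(np.linalg.norm(
        after[fixed_idx] - before[fixed_idx], axis=1).max()) if fixed_idx else 0.0

    # write refined coordinates back
    out_protein = protein
    for i, atom in enumerate(prot_atoms):
        if not atom.is_experimental:
            atom.position = after[i].copy()
    out_lig = Chem.Mol(ligand.to_rdkit())
    lconf = out_lig.GetConformer()
    for j in range(out_lig.GetNumAtoms()):
        lconf.SetAtomPosition(j, Point3D(*after[n_prot + j]))

    logger.info("minimization: E %.1f -> %.1f kcal/mol, %d fixed / %d movable,"
                " converged=%s", e0, e1, len(fixed_idx), n_movable, status == 0)
    return RefinementResult(
        protein=out_protein, ligand=MoleculeGraph(rdmol=out_lig),
        converged=status == 0, energy_initial=float(e0),
        energy_final=float(e1), max_moved_constrained=max_moved,
        n_fixed=len(fixed_idx), n_movable=n_movable)
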