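"""Deterministic synthetic protein-ligand complexes for offline testing.

Real curation inputs are crystallographic depositions; none can ship with
the package, so this module builds toy complexes that exercise every stage:
a small folded receptor (an ideal-geometry polyalanine alpha-helix, with
optional named side-chain substitutions), a co-crystallized small-molecule
ligand embedded from SMILES with hydrogens stripped and bond orders absent
— exactly the information content of a deposited HETATM block — plus a
matching mmCIF-style header carrying the full receptor sequence.

Defects are injectable one by one (or combined) so that each rejection
filter and each fixer failure mode fires on a known input, and every
fixture carries a machine-readable manifest of the outcome the pipeline
must produce for it. Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._residues import HEAVY_ATOMS
from .protein_fixer import (A_CA_C_N, A_CA_C_O, A_C_N_CA, A_N_CA_C,
                            A_N_CA_CB, B_CA_C, B_CA_CB, B_C_N, B_C_O,
                            B_N_CA, T_CB, nerf as _nerf)
from .structure_io import AtomRecord, ChainRecord, ResidueRecord, Structure, write_pdb

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = (
    A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0   # ideal alpha-helix
_T_CB = T_CB


class FixtureSpecError(ValueError):
    pass


def ligand_instance_from_smiles(smiles: str, seed: int = 0,
                                ccd_code: str = "LIG"):
    """A stand-alone stripped ligand (heavy atoms + coordinates only), the
    information content a deposited HETATM block provides. Used to exercise
    the ligand-fixing path without a full complex."""
    from .splitter import LigandInstance, LigandSpec
    mol = _embed_ligand(smiles, seed)
    conf = mol.GetConformer()
    res = ResidueRecord(name=ccd_code, seq_number=1)
    counts: Dict[str, int] = {}
    for i, atom in enumerate(mol.GetAtoms()):
        el = atom.GetSymbol()
        counts[el] = counts.get(el, 0) + 1
        p = conf.GetAtomPosition(i)
        res.atoms.append(AtomRecord(
            serial=i + 1, name=f"{el.upper()}{counts[el]}"[:4], element=el,
            alt_loc="", position=np.array([p.x, p.y, p.z]), occupancy=1.0,
            record_kind="HETATM"))
    return LigandInstance(spec=LigandSpec(kind="ccd", ccd_code=ccd_code),
                          chain_id="B", residues=[res])


# drug-like molecules spanning the common organic element set, acid/base
# motifs and ring systems; used for the ligand round-trip property
DRUGLIKE_PANEL = [
    "CC(=O)Oc1ccccc1C(=O)O",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(=O)Nc1ccc(O)cc1",
    "NC(=N)c1ccccc1",
    "C1CNCCN1",
    "NCCc1ccc(O)c(O)c1",
    "CN1CCC[C@H]1c1cccnc1",
    "OC(=O)c1ccccc1O",
    "Clc1ccccc1-c1nc2ccccc2[nH]1",
    "CC(N)Cc1ccccc1",
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "NS(=O)(=O)c1ccc(N)cc1",
    "Nc1ncnc2n(cnc12)C",
    "OCC(O)C(O)C(O)C(O)CO",
    "CC(C)NCC(O)COc1ccccc1",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "CN(C)CCCN1c2ccccc2Sc2ccccc21",
    "OC(=O)CCc1ccccc1",
    "Oc1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1",
    "NCCCC[C@H](N)C(=O)O",
    "OC(=O)[C@@H](N)Cc1c[nH]cn1",
    "CSCC[C@H](N)C(=O)O",
    "CC(C)(C)NCC(O)c1ccc(O)c(O)c1",
    "COc1cc2c(cc1OC)CCN(C)C2",
    "Fc1ccc(cc1)C(=O)c1ccc(F)cc1",
    "CC1=CC(=O)CC(C)(C)C1",
    "O=C1NC(=O)NC(=O)C1",
    "Clc1ccc(cc1)S(=O)(=O)N",
    "CC(C)C[C@H](N)C(=O)O",
    "c1ccc(cc1)C(=O)NCCN",
    "COC(=O)c1ccccc1N",
    "CN1CCN(CC1)c1ccccc1",
    "Oc1ccc(CC=C)cc1",
    "NC(=O)c1ccc[nH]1",
    "S=C(N)Nc1ccccc1",
    "OCc1ccc(O)cc1",
    "CCOC(=O)c1ccccc1",
    "Brc1ccc(cc1)C(=O)O",
    "Ic1ccc(cc1)C(=O)N",
    "CC(=O)NC1CCCCC1",
    "O=C(Nc1ccccc1)c1ccccc1",
    "CN(C)c1ccc(cc1)C=O",
    "OC(=O)c1cc(O)c(O)c(O)c1",
    "NCc1ccc(Cl)cc1",
    "CC1CCC(CC1)NC(=O)C",
    "c1ccc(cc1)CSc1ccccc1",
    "OCCN1CCN(CC1)c1ccc(F)cc1",
    "CC(C)(C)c1ccc(O)cc1",
    "O=S(=O)(c1ccccc1)c1ccccc1",
    "NC(=O)C1CCCN1C(=O)C",
    "COc1ccccc1OCC(O)CN",
    "Cc1ccc(cc1)S(=O)(=O)Nc1ccccn1",
    "OC(c1ccccc1)c1ccccc1",
]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    length: int = 20
    substitutions: Tuple[Tuple[int, str], ...] = ()   # (1-based seq, resname)
    ligand_smiles: str = "NC(=N)c1ccccc1"             # benzamidine
    placement: float = 4.0                            # min ligand-protein dist A
    defects: Tuple[str, ...] = ()                     # e.g. "create_clash:1.5"

    def with_defects(self, *defects: str) -> "FixtureSpec":
        return replace(self, defects=tuple(defects))


@dataclass
class FixtureBundle:
    pdb_text: str
    cif_text: str
    ref_smiles: str
    manifest: Dict

    def write(self, out_dir: Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "structure.pdb").write_text(self.pdb_text)
        (out_dir / "header.cif").write_text(self.cif_text)
        (out_dir / "ref_smiles.csv").write_text(
            "code,smiles\nLIG," + self.ref_smiles + "\n")
        (out_dir / "ligands.csv").write_text(
            f"entry_id,ccd_or_span\n{self.manifest['entry_id']},LIG\n")
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        return out_dir


def build_helix(length: int, substitutions: Dict[int, str]) -> Structure:
    """Ideal alpha-helix (phi=-57, psi=-47) with standard bond geometry.

    Substituted residues get full idealized side chains placed on the
    CB anchor by the same template machinery the repair module uses.
    """
    from .protein_fixer import place_missing_atoms

    for seq, name in substitutions.items():
        if name not in HEAVY_ATOMS:
            raise FixtureSpecError(f"unknown substitution residue {name}")
        if not (1 <= seq <= length):
            raise FixtureSpecError(f"substitution position {seq} out of range")

    chain = ChainRecord(chain_id="A", is_polymer=True)
    serial = 1
    prev = {}     # N, CA, C of previous residue
    for i in range(1, length + 1):
        name = substitutions.get(i, "ALA")
        res = ResidueRecord(name=name, seq_number=i)
        if i == 1:
            n = np.zeros(3)
            ca = n + np.array([_B_N_CA, 0.0, 0.0])
            ang = np.radians(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]) * -1
            c = ca + _B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
        else:
            n = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
            ca = _nerf(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
            c = _nerf(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _PHI)
        o_tors = _PSI + 180.0 if i < length else _PSI + 180.0
        # O placed from (N, CA, C) with psi+180 torsion
        o = _nerf(n, ca, c, _B_C_O, _A_CA_C_O, o_tors)
        positions = {"N": n, "CA": ca, "C": c, "O": o}
        if name != "GLY":
            positions["CB"] = _nerf(c, n, ca, _B_CA_CB, _A_N_CA_CB, _T_CB)
        for atom_name in (["N", "CA", "C", "O"] +
                          (["CB"] if name != "GLY" else [])):
            res.atoms.append(AtomRecord(
                serial=serial, name=atom_name, element=atom_name[0],
                alt_loc="", position=positions[atom_name], occupancy=1.0,
                record_kind="ATOM"))
            serial += 1
        if name not in ("ALA", "GLY"):
            extra = [nm for nm in HEAVY_ATOMS[name] if res.atom(nm) is None]
            added = place_missing_atoms(res, extra, serial)
            for a in added:           # fixture side chains are "deposited"
                a.occupancy = 1.0
                a.is_experimental = True
            res.atoms.extend(added)
            serial += len(added)
        # OXT on the C-terminal residue
        if i == length:
            oxt = _nerf(n, ca, c, _B_C_O, _A_CA_C_O, o_tors + 180.0)
            res.atoms.append(AtomRecord(
                serial=serial, name="OXT", element="O", alt_loc="",
                position=oxt, occupancy=1.0, record_kind="ATOM"))
            serial += 1
        chain.residues.append(res)
        prev = {"N": n, "CA": ca, "C": c}
    return Structure(entry_id="FIX1", chains=[chain])


def _embed_ligand(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2 ** 31 - 1) or 1
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise FixtureSpecError(f"cannot embed ligand SMILES {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    return Chem.RemoveHs(mol)


def _place_ligand(lig_coords: np.ndarray, prot_coords: np.ndarray,
                  target: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate (seeded) and translate the ligand along +x from the receptor
    centroid until the minimum heavy-atom distance equals ``target``."""
    # seeded random rotation
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    lig = (lig_coords - lig_coords.mean(axis=0)) @ R.T
    centroid = prot_coords.mean(axis=0)
    direction = np.array([1.0, 0.0, 0.0])

    def min_dist(t: float) -> float:
        moved = lig + centroid + direction * t
        d = np.linalg.norm(moved[:, None, :] - prot_coords[None, :, :], axis=-1)
        return float(d.min())

    lo, hi = 0.0, 60.0
    for _ in range(80):       # bisection: min_dist is increasing in t out here
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return lig + centroid + direction * hi


def _parse_defect(d: str) -> Tuple[str, Optional[str]]:
    if ":" in d:
        name, arg = d.split(":", 1)
        return name, arg
    return d, None


_KNOWN_DEFECTS = {
    "strip_bond_orders", "delete_ligand_atom", "delete_side_chain_atom",
    "delete_internal_segment", "delete_terminal_segment",
    "add_covalent_conect", "swap_element_to", "create_clash", "tiny_ligand",
    "corrupt_reference_all_single",
}


def _all_single_smiles(smiles: str) -> str:
    """The classic corrupted-reference artifact: every bond demoted to a
    single bond (heavy-atom graph unchanged, hybridizations wrong)."""
    mol = Chem.MolFromSmiles(smiles)
    rw = Chem.RWMol(mol)
    for b in rw.GetBonds():
        b.SetBondType(Chem.BondType.SINGLE)
        b.SetIsAromatic(False)
    for a in rw.GetAtoms():
        a.SetIsAromatic(False)
        a.SetNoImplicit(False)
        a.SetNumExplicitHs(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate one synthetic complex with its expected-outcome manifest."""
    defects = dict(_parse_defect(d) for d in spec.defects)
    unknown = set(defects) - _KNOWN_DEFECTS
    if unknown:
        raise FixtureSpecError(f"unknown defect(s): {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    substitutions = dict(spec.substitutions)
    structure = build_helix(spec.length, substitutions)
    chain = structure.chains[0]

    ligand_smiles = spec.ligand_smiles
    if "tiny_ligand" in defects:
        ligand_smiles = "O=C=O"
        if "delete_ligand_atom" in defects:
            raise FixtureSpecError(
                "contradictory defects: tiny_ligand + delete_ligand_atom")
    lig_mol = _embed_ligand(ligand_smiles, spec.seed + 1)
    conf = lig_mol.GetConformer()
    lig_coords = np.array([list(conf.GetAtomPosition(i))
                           for i in range(lig_mol.GetNumAtoms())])
    prot_coords = np.array([a.position for _, _, a in structure.iter_atoms()])

    target = spec.placement
    if "create_clash" in defects:
        target = float(defects["create_clash"] or 1.5)
    placed = _place_ligand(lig_coords, prot_coords, target, rng)

    # assemble ligand residue + CONECT from the generating molecule
    lig_chain = ChainRecord(chain_id="B", is_polymer=False)
    lig_res = ResidueRecord(name="LIG", seq_number=1)
    serial0 = max(a.serial for _, _, a in structure.iter_atoms()) + 1
    elem_counts: Dict[str, int] = {}
    for i, atom in enumerate(lig_mol.GetAtoms()):
        el = atom.GetSymbol()
        elem_counts[el] = elem_counts.get(el, 0) + 1
        lig_res.atoms.append(AtomRecord(
            serial=serial0 + i, name=f"{el.upper()}{elem_counts[el]}"[:4],
            element=el, alt_loc="", position=placed[i], occupancy=1.0,
            record_kind="HETATM"))
    lig_chain.residues.append(lig_res)
    structure.chains.append(lig_chain)
    conect = {frozenset((serial0 + b.GetBeginAtomIdx(), serial0 + b.GetEndAtomIdx()))
              for b in lig_mol.GetBonds()}

    manifest: Dict = {
        "entry_id": structure.entry_id,
        "seed": spec.seed,
        "defects": list(spec.defects),
        "ligand_smiles": ligand_smiles,
        "expected": {"stage": "success", "filters_failed": [],
                     "ligand_fix_status": "fixed", "repairs": []},
    }
    expected = manifest["expected"]
    ref_smiles = ligand_smiles

    # ---- defect injection -------------------------------------------------
    if "swap_element_to" in defects:
        new_el = defects["swap_element_to"] or "Se"
        # swap a terminal carbon to keep the graph otherwise sane
        victim = max(lig_res.atoms, key=lambda a: a.serial)
        victim.element = new_el
        victim.name = new_el.upper() + "9"
        expected["stage"] = "filters"
        expected["filters_failed"].append("rare-element")

    if "delete_ligand_atom" in defects:
        # remove a degree-1 heavy atom so connectivity stays intact
        degrees = {a.GetIdx(): a.GetDegree() for a in lig_mol.GetAtoms()}
        victim_idx = next(i for i, d in sorted(degrees.items()) if d == 1)
        victim_serial = serial0 + victim_idx
        lig_res.atoms = [a for a in lig_res.atoms if a.serial != victim_serial]
        conect = {p for p in conect if victim_serial not in p}
        expected["stage"] = "ligand_fix"
        expected["ligand_fix_status"] = "mismatch"

    if "corrupt_reference_all_single" in defects:
        ref_smiles = _all_single_smiles(ligand_smiles)
        expected["stage"] = "ligand_fix"
        expected["ligand_fix_status"] = "bad-reference"

    if "add_covalent_conect" in defects:
        lig_serial = lig_res.atoms[0].serial
        ca = chain.residues[spec.length // 2].atom("CA")
        conect.add(frozenset((lig_serial, ca.serial)))
        expected["stage"] = "filters"
        expected["filters_failed"].append("covalent-binder")

    if "tiny_ligand" in defects:
        expected["stage"] = "filters"
        expected["filters_failed"].append("small-ligand")

    if "create_clash" in defects and target < 2.0:
        expected["stage"] = "filters"
        expected["filters_failed"].append("steric-clash")
        expected["clash_distance"] = target

    if "delete_side_chain_atom" in defects:
        arg = defects["delete_side_chain_atom"]
        if arg:
            seq_s, atom_name = arg.split("/")
            seq = int(seq_s)
        else:
            seq = next((s for s, n in substitutions.items() if n not in
                        ("ALA", "GLY")), None)
            if seq is None:
                raise FixtureSpecError(
                    "delete_side_chain_atom needs a non-ALA substitution")
            atom_name = HEAVY_ATOMS[substitutions[seq]][-1]
        res = chain.residue(seq)
        res.atoms = [a for a in res.atoms if a.name != atom_name]
        expected["repairs"].append(
            {"kind": "missing-atom", "chain": "A", "seq": seq,
             "atoms": [atom_name]})

    full_length = spec.length
    deleted: List[int] = []
    if "delete_internal_segment" in defects:
        n = int(defects["delete_internal_segment"] or 4)
        start = max(2, spec.length // 2 - n // 2)
        if start + n >= spec.length:
            raise FixtureSpecError("internal segment does not fit")
        deleted = list(range(start, start + n))
        expected["repairs"].append(
            {"kind": "rebuild-segment" if n <= 10 else "skip-segment",
             "chain": "A", "start": start, "end": start + n - 1, "length": n})

    if "delete_terminal_segment" in defects:
        n = int(defects["delete_terminal_segment"] or 3)
        term = list(range(spec.length - n + 1, spec.length + 1))
        deleted += term
        expected["repairs"].append(
            {"kind": "skip-terminal", "chain": "A", "start": term[0],
             "end": term[-1], "length": n})

    if deleted:
        chain.residues = [r for r in chain.residues
                          if r.seq_number not in deleted]

    manifest["reference_smiles"] = ref_smiles
    structure.conect_pairs = conect
    pdb_text = write_pdb(structure)
    cif_text = _mmcif_header(structure.entry_id, chain_id="A",
                             full_length=full_length,
                             substitutions=substitutions,
                             modeled=[r.seq_number for r in chain.residues])
    return FixtureBundle(pdb_text=pdb_text, cif_text=cif_text,
                         ref_smiles=ref_smiles, manifest=manifest)


def _mmcif_header(entry_id: str, chain_id: str, full_length: int,
                  substitutions: Dict[int, str], modeled: List[int]) -> str:
    lines = [
        f"data_{entry_id}",
        f"_entry.id {entry_id}",
        "_refine.ls_d_res_high 1.80",
        "_exptl.method 'X-RAY DIFFRACTION'",
        "_pdbx_database_status.recvd_initial_deposition_date 2024-01-01",
        "loop_",
        "_pdbx_poly_seq_scheme.asym_id",
        "_pdbx_poly_seq_scheme.pdb_strand_id",
        "_pdbx_poly_seq_scheme.seq_id",
        "_pdbx_poly_seq_scheme.mon_id",
        "_pdbx_poly_seq_scheme.auth_seq_num",
    ]
    modeled_set = set(modeled)
    for i in range(1, full_length + 1):
        mon = substitutions.get(i, "ALA")
        auth = str(i) if i in modeled_set else "?"
        lines.append(f"{chain_id} {chain_id} {i} {mon} {auth}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the default verification suite: one fixture per pipeline outcome
# ---------------------------------------------------------------------------

def default_suite(seed: int = 0) -> List[Tuple[str, FixtureSpec]]:
    """Ten fixtures covering the clean path, every filter, both ligand-fix
    failure modes and the three protein-repair rules."""
    base = FixtureSpec(seed=seed, substitutions=((5, "LYS"), (9, "ASP"),
                                                 (12, "HIS"), (16, "SER")))
    return [
        ("clean", base),
        ("clash", base.with_defects("create_clash:1.5")),
        ("rare_element", base.with_defects("swap_element_to:Se")),
        ("tiny_ligand", base.with_defects("tiny_ligand")),
        ("covalent", base.with_defects("add_covalent_conect")),
        ("missing_ligand_atom", base.with_defects("delete_ligand_atom")),
        ("corrupt_reference", base.with_defects("corrupt_reference_all_single")),
        ("missing_side_chain", base.with_defects("delete_side_chain_atom")),
        ("internal_gap", base.with_defects("delete_internal_segment:4")),
        ("terminal_gap", base.with_defects("delete_terminal_segment:3")),
    ]
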