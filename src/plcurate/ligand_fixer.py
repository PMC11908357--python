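"""Ligand chemistry repair.

Crystallographic ligands carry coordinates but no chemistry: hydrogens are
absent and bond orders are at best inferred from geometry. This module
rebuilds a chemistry-complete molecule in four steps:

1. *perceive*: bond connectivity from interatomic distances against
   covalent-radius sums (the "inferred structure");
2. *reference*: a trusted SMILES for the ligand's identity, from an
   override table, a chemical-component-dictionary lookup, or — for short
   peptides of standard alpha-amino acids — generated from the sequence by
   amide-bond formation rules;
3. *transfer*: if the inferred and reference heavy-atom graphs are
   isomorphic under element labels (bond orders ignored, since inferred
   orders are untrusted), bond orders, aromaticity, hybridization and
   formal charges are copied through the atom mapping onto the crystal
   coordinates; a non-isomorphism means missing atoms or distorted
   geometry and the entry is excluded;
4. *protonate*: a fixed, ordered set of SMARTS rules for pH 7.4 — acids,
   nitro groups, thiophenols, azides and N-oxides are deprotonated;
   aliphatic amines and guanidines/amidines/imines are protonated; anilines
   and amines whose nitrogen touches a non-{H,C} atom are not; diamines and
   piperazines receive exactly one proton; enols in the O=C-C=C-OH motif
   are deprotonated. Explicit hydrogens are then added at standard
   geometry.

Heavy-atom coordinates are never moved: the crystal geometry is the ground
truth being curated. Stereochemistry is likewise taken from the 3D
coordinates, not from the reference SMILES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from ._residues import SIDECHAIN_SMILES
from .config import WorkflowConfig
from .splitter import LigandInstance

logger = logging.getLogger(__name__)

_PT = Chem.GetPeriodicTable()


class UnsupportedResidueError(ValueError):
    pass


class UnresolvableReferenceError(ValueError):
    pass


@dataclass
class MoleculeGraph:
    """Chemistry-complete (or inferred) molecular graph over 3D coordinates.

    Thin wrapper over an RDKit molecule with one conformer. ``src_serials``
    maps atom index -> source crystal-atom serial (or None for atoms added
    later, i.e. hydrogens).
    """

    rdmol: Chem.Mol
    inferred_only: bool = False     # True before bond orders are trusted

    def to_rdkit(self) -> Chem.Mol:
        return self.rdmol

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1)

    @property
    def atoms(self) -> List[tuple]:
        """(element, formal_charge, hybridization, aromatic, position, serial)"""
        conf = self.rdmol.GetConformer()
        out = []
        for a in self.rdmol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            hyb = {Chem.HybridizationType.SP: "sp",
                   Chem.HybridizationType.SP2: "sp2",
                   Chem.HybridizationType.SP3: "sp3"}.get(a.GetHybridization(),
                                                          "other")
            serial = (a.GetIntProp("src_serial")
                      if a.HasProp("src_serial") else None)
            out.append((a.GetSymbol(), a.GetFormalCharge(), hyb,
                        a.GetIsAromatic(), np.array([p.x, p.y, p.z]), serial))
        return out

    @property
    def bonds(self) -> List[Tuple[int, int, object]]:
        out = []
        for b in self.rdmol.GetBonds():
            if b.GetIsAromatic():
                order: object = "aromatic"
            else:
                order = int(b.GetBondTypeAsDouble())
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out

    @property
    def net_charge(self) -> int:
        return sum(a.GetFormalCharge() for a in self.rdmol.GetAtoms())

    def heavy_coordinates(self) -> np.ndarray:
        conf = self.rdmol.GetConformer()
        return np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                          conf.GetAtomPosition(i).z]
                         for i, a in enumerate(self.rdmol.GetAtoms())
                         if a.GetAtomicNum() > 1])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.rdmol.GetAtoms():
            if a.GetAtomicNum() > 1:
                g.add_node(a.GetIdx(), element=a.GetSymbol())
        for b in self.rdmol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if g.has_node(i) and g.has_node(j):
                g.add_edge(i, j)
        return g


@dataclass
class ReferenceChem:
    smiles: str
    source: str                     # ccd-lookup | bird-lookup | peptide-builder | override-table

    def mol(self) -> Chem.Mol:
        """Reference molecule: largest organic fragment, heavy atoms only."""
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise UnresolvableReferenceError(
                f"reference SMILES does not parse: {self.smiles!r}")
        frags = Chem.GetMolFrags(m, asMols=True, sanitizeFrags=True)
        if len(frags) > 1:
            frags = sorted(frags, key=lambda f: (
                sum(1 for a in f.GetAtoms() if a.GetAtomicNum() == 6),
                f.GetNumAtoms()), reverse=True)
            logger.debug("reference has %d fragments; keeping largest organic",
                         len(frags))
        return Chem.RemoveHs(frags[0])

    @property
    def net_charge(self) -> int:
        return sum(a.GetFormalCharge() for a in self.mol().GetAtoms())


@dataclass
class FixOutcome:
    status: str                     # fixed | mismatch | bad-reference
    mol: Optional[MoleculeGraph] = None
    diagnostic: str = ""
    stage: str = ""


# ---------------------------------------------------------------------------
# 1. geometry perception
# ---------------------------------------------------------------------------

def perceive_from_geometry(ligand: LigandInstance,
                           cfg: Optional[WorkflowConfig] = None) -> MoleculeGraph:
    """Infer heavy-atom connectivity from distances: atoms i,j are bonded
    when d(i,j) < (r_cov(i) + r_cov(j)) * tolerance. Orders are provisional
    (all single) — correcting them is the point of the transfer step."""
    cfg = cfg or WorkflowConfig()
    atoms = ligand.atoms
    if len(atoms) == 0:
        raise ValueError("ligand has no heavy atoms")
    rw = Chem.RWMol()
    conf = Chem.Conformer(len(atoms))
    radii = []
    for i, a in enumerate(atoms):
        at = Chem.Atom(a.element.capitalize())
        at.SetIntProp("src_serial", a.serial)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
        conf.SetAtomPosition(i, Point3D(*map(float, a.position)))
        radii.append(_PT.GetRcovalent(at.GetAtomicNum()) or 0.77)
    coords = np.array([a.position for a in atoms])
    n = len(atoms)
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] < (radii[i] + radii[j]) * cfg.bond_perception_tolerance:
                rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.AddConformer(conf, assignId=True)
    frag_count = len(Chem.GetMolFrags(mol))
    if frag_count > 1:
        logger.warning("ligand %s perceived as %d fragments (kept, flagged)",
                       ligand.key, frag_count)
        mol.SetProp("multi_fragment", str(frag_count))
    return MoleculeGraph(rdmol=mol, inferred_only=True)


# ---------------------------------------------------------------------------
# 2. reference resolution
# ---------------------------------------------------------------------------

def peptide_smiles(sequence: str) -> ReferenceChem:
    """Linear peptide SMILES from a one-letter sequence: free neutral N- and
    C-termini, amide bonds between consecutive residues, L stereocenters."""
    if len(sequence) < 2:
        raise UnsupportedResidueError("peptide builder needs length >= 2")
    parts = []
    for letter in sequence.upper():
        if letter == "G":
            parts.append("NCC(=O)")
        elif letter == "P":
            parts.append("N9[C@@H](CCC9)C(=O)")
        elif letter in SIDECHAIN_SMILES:
            parts.append(f"N[C@@H]({SIDECHAIN_SMILES[letter]})C(=O)")
        else:
            raise UnsupportedResidueError(
                f"non-standard residue letter {letter!r}: only simple "
                f"non-cyclic peptides of alpha-amino acids are supported")
    smiles = "".join(parts) + "O"
    if Chem.MolFromSmiles(smiles) is None:   # pragma: no cover - table guard
        raise UnsupportedResidueError(f"internal peptide SMILES invalid: {smiles}")
    return ReferenceChem(smiles=smiles, source="peptide-builder")


def table_fetcher(table: Dict[str, str]) -> Callable[[str], Optional[str]]:
    """Offline CCD/BIRD lookup backed by a code->SMILES table; drop-in
    interchangeable with the cached network fetcher."""
    def fetch(code: str) -> Optional[str]:
        return table.get(code)
    return fetch


def rcsb_fetcher(cache: Optional[Dict[str, str]] = None) -> Callable[[str], Optional[str]]:
    """CCD/BIRD -> SMILES lookup against the RCSB chemical component API
    (network required), with in-memory caching."""
    cache = {} if cache is None else cache

    def fetch(code: str) -> Optional[str]:
        if code in cache:
            return cache[code]
        import json
        import urllib.request
        url = f"https://data.rcsb.org/rest/v1/core/chemcomp/{code.upper()}"
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                data = json.load(resp)
        except Exception as exc:       # network failures -> not found
            logger.warning("RCSB chemcomp lookup failed for %s: %s", code, exc)
            return None
        smiles = (data.get("rcsb_chem_comp_descriptor", {}) or {}).get("smiles")
        cache[code] = smiles
        return smiles
    return fetch


def resolve_reference(ligand: LigandInstance,
                      overrides: Optional[Dict[str, str]] = None,
                      fetcher: Optional[Callable[[str], Optional[str]]] = None
                      ) -> ReferenceChem:
    """Reference SMILES with precedence override table > CCD/BIRD lookup >
    peptide builder."""
    overrides = overrides or {}
    code = ligand.spec.ccd_code
    if code and code in overrides:
        return ReferenceChem(smiles=overrides[code], source="override-table")
    if code and fetcher is not None:
        smiles = fetcher(code)
        if smiles:
            return ReferenceChem(smiles=smiles, source="ccd-lookup")
    if ligand.spec.kind == "polymer":
        key = ligand.key
        if key in overrides:
            return ReferenceChem(smiles=overrides[key], source="override-table")
        seq = ligand.sequence_one_letter()
        if seq is not None:
            try:
                return peptide_smiles(seq)
            except UnsupportedResidueError as exc:
                raise UnresolvableReferenceError(str(exc)) from exc
        raise UnresolvableReferenceError(
            f"polymer ligand {ligand.key} is not a standard alpha-amino-acid "
            f"peptide and no reference SMILES was supplied")
    raise UnresolvableReferenceError(
        f"no reference source available for ligand {ligand.key}")


# ---------------------------------------------------------------------------
# 3. geometric validation of the reference
# ---------------------------------------------------------------------------

def _improper_deg(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees) of the 4-point sequence p0-p1-p2-p3."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def _planarity_deviation(center: np.ndarray, nbrs: np.ndarray) -> float:
    """Out-of-plane angle of a 3-coordinate center: 0 for perfectly planar,
    ~35 degrees for ideal tetrahedral."""
    tors = _improper_deg(nbrs[0], nbrs[1], nbrs[2], center)
    return min(abs(tors), abs(180.0 - abs(tors)))


def validate_reference_geometry(reference: ReferenceChem,
                                inferred: MoleculeGraph,
                                cfg: Optional[WorkflowConfig] = None
                                ) -> Tuple[bool, str]:
    """Check the reference's carbon hybridizations against crystal geometry.

    Returns False (with a diagnostic naming the atoms) when e.g. the
    reference declares sp3 at a carbon whose three substituents are
    coplanar, or sp2/aromatic where the geometry is clearly pyramidal —
    the signature of corrupted all-single-bond reference SMILES. When the
    graphs are not isomorphic the check is inconclusive and returns True
    (the transfer step will fail with a proper mismatch diagnostic).
    """
    cfg = cfg or WorkflowConfig()
    ref_mol = reference.mol()
    mapping = _element_isomorphism(inferred.to_networkx(), _ref_graph(ref_mol))
    if mapping is None:
        return True, "inconclusive: inferred and reference graphs not isomorphic"

    conf = inferred.rdmol.GetConformer()
    pos = lambda i: np.array(conf.GetAtomPosition(i))
    adj = {i: list(inferred.rdmol.GetAtomWithIdx(i).GetNeighbors())
           for i in range(inferred.rdmol.GetNumAtoms())}

    bad: List[str] = []
    angle_suspects = 0
    for inf_idx, ref_idx in mapping.items():
        ref_atom = ref_mol.GetAtomWithIdx(ref_idx)
        if ref_atom.GetAtomicNum() != 6:
            continue
        hyb = ref_atom.GetHybridization()
        is_sp2 = (ref_atom.GetIsAromatic()
                  or hyb == Chem.HybridizationType.SP2)
        nbr_idx = [n.GetIdx() for n in adj[inf_idx]]
        if len(nbr_idx) == 3:
            dev = _planarity_deviation(pos(inf_idx),
                                       np.array([pos(j) for j in nbr_idx]))
            if hyb == Chem.HybridizationType.SP3 and dev < cfg.planarity_tolerance_deg:
                bad.append(f"atom {inf_idx}: reference sp3 but planar "
                           f"(out-of-plane {dev:.1f} deg)")
            elif is_sp2 and dev > 25.0:
                bad.append(f"atom {inf_idx}: reference sp2 but pyramidal "
                           f"(out-of-plane {dev:.1f} deg)")
        elif len(nbr_idx) == 2:
            v1 = pos(nbr_idx[0]) - pos(inf_idx)
            v2 = pos(nbr_idx[1]) - pos(inf_idx)
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if hyb == Chem.HybridizationType.SP3 and ang > 118.0:
                angle_suspects += 1
    # a single wide angle can be strain; several point at a flattened ring
    if angle_suspects >= 2:
        bad.append(f"{angle_suspects} two-neighbor carbons with sp2-like bond "
                   f"angles but sp3 reference")
    if bad:
        return False, "; ".join(bad)
    return True, "reference hybridizations consistent with crystal geometry"


# ---------------------------------------------------------------------------
# 4. bond-order transfer
# ---------------------------------------------------------------------------

def _ref_graph(ref_mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for a in ref_mol.GetAtoms():
        g.add_node(a.GetIdx(), element=a.GetSymbol())
    for b in ref_mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    return g


def _element_isomorphism(g1: nx.Graph, g2: nx.Graph) -> Optional[Dict[int, int]]:
    """One element-labelled graph isomorphism g1 -> g2, or None. Any one of
    multiple automorphic mappings is chemically equivalent."""
    if g1.number_of_nodes() != g2.number_of_nodes():
        return None
    gm = nx.isomorphism.GraphMatcher(
        g1, g2, node_match=lambda a, b: a["element"] == b["element"])
    if gm.is_isomorphic():
        return dict(gm.mapping)
    return None


def transfer_bond_orders(inferred: MoleculeGraph,
                         reference: ReferenceChem) -> FixOutcome:
    """Copy bond orders, aromaticity, hybridization and formal charges from
    the reference onto the crystal coordinates through an element-labelled
    isomorphism of the heavy-atom graphs (bond orders ignored in matching)."""
    try:
        ref_mol = reference.mol()
    except UnresolvableReferenceError as exc:
        return FixOutcome(status="bad-reference", diagnostic=str(exc),
                          stage="transfer")
    g_inf = inferred.to_networkx()
    g_ref = _ref_graph(ref_mol)
    if g_inf.number_of_nodes() != g_ref.number_of_nodes():
        return FixOutcome(
            status="mismatch", stage="transfer",
            diagnostic=f"atom count differs: inferred {g_inf.number_of_nodes()} "
                       f"vs reference {g_ref.number_of_nodes()} heavy atoms "
                       f"(missing atoms or wrong reference)")
    mapping = _element_isomorphism(g_inf, g_ref)
    if mapping is None:
        inf_elems = sorted(d["element"] for _, d in g_inf.nodes(data=True))
        ref_elems = sorted(d["element"] for _, d in g_ref.nodes(data=True))
        what = ("element composition differs" if inf_elems != ref_elems
                else "bond connectivity differs")
        return FixOutcome(status="mismatch", stage="transfer",
                          diagnostic=f"no isomorphism: {what}")

    # rebuild the reference molecule on the crystal coordinates
    new = Chem.RWMol(ref_mol)
    conf = Chem.Conformer(new.GetNumAtoms())
    src_conf = inferred.rdmol.GetConformer()
    for inf_idx, ref_idx in mapping.items():
        p = src_conf.GetAtomPosition(inf_idx)
        conf.SetAtomPosition(ref_idx, Point3D(p.x, p.y, p.z))
        src_atom = inferred.rdmol.GetAtomWithIdx(inf_idx)
        if src_atom.HasProp("src_serial"):
            new.GetAtomWithIdx(ref_idx).SetIntProp(
                "src_serial", src_atom.GetIntProp("src_serial"))
    mol = new.GetMol()
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)
    Chem.SanitizeMol(mol)
    # stereochemistry from the crystal geometry, not the reference string
    Chem.AssignStereochemistryFrom3D(mol)
    return FixOutcome(status="fixed", mol=MoleculeGraph(rdmol=mol),
                      stage="transfer",
                      diagnostic="bond orders transferred from reference")


# ---------------------------------------------------------------------------
# 5. protonation rules (pH 7.4)
# ---------------------------------------------------------------------------

# (rule name, SMARTS, charged-atom index within the match, new charge)
_DEPROTONATION_RULES = [
    ("carboxylic-acid", "[CX3](=O)[OX2H1]", 2, -1),
    ("sulfonic-acid", "[OX2H1][SX4](=O)=O", 0, -1),
    ("sulfinic-acid", "[OX2H1][SX3]=O", 0, -1),
    ("phosphonic-acid", "[OX2H1][PX4]=O", 0, -1),
    ("thiophenol", "[SX2H1][c]", 0, -1),
    ("azide", "[NX2H1]=[N+]=[N-]", 0, -1),
    ("tetrazole", "[nX3H1]1nnnc1", 0, -1),
    ("n-hydroxy", "[OX2H1][#7X3]", 0, -1),
]

_ENOL_RULE = ("enol", "[OX1]=[CX3]-[CX3]=[CX3]-[OX2H1]", 4, -1)

# protonation: amidines/guanidines first (their sp2 N), then plain aliphatic
# amines, then isolated aliphatic imines. Patterns require neutral nitrogen
# so a second application is a no-op.
_PROTONATION_RULES = [
    ("guanidine/amidine",
     "[NX2;+0;!$(N[!#6;!#1])]=[CX3;!$(C=N[!#6;!#1])]([#7X3;+0])", 0, +1),
    ("aliphatic-amine",
     "[NX3;+0;!$(N[a]);!$(N[!#6;!#1]);!$(N[CX3]=[O,N,S,P]);!$(N=*);$([N][#6]),$([NH3])]",
     0, +1),
    ("aliphatic-imine",
     "[NX2;+0;!$(N[a]);!$(N[!#6;!#1]);!$(N=C[N,n,O,o,S,s]);!$(N=C[a])]=[CX3]",
     0, +1),
]


def _apply_charge_rules(rw: Chem.RWMol) -> List[Tuple[str, int]]:
    hits: List[Tuple[str, int]] = []
    for name, smarts, pos, charge in _DEPROTONATION_RULES + [_ENOL_RULE]:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[pos])
            if atom.GetFormalCharge() == 0:
                atom.SetFormalCharge(charge)
                atom.SetNoImplicit(False)
                atom.SetNumExplicitHs(0)
                hits.append((name, match[pos]))
    Chem.SanitizeMol(rw)
    protonated: List[int] = []
    for name, smarts, pos, charge in _PROTONATION_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[pos])
            if atom.GetFormalCharge() == 0 and not any(
                    n.GetFormalCharge() > 0 for n in atom.GetNeighbors()):
                atom.SetFormalCharge(charge)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                protonated.append(match[pos])
                hits.append((name, match[pos]))
                logger.debug("protonation rule %s hit atom %d", name, match[pos])
    Chem.SanitizeMol(rw)

    # diamines / piperazines: two protonated amine nitrogens within three
    # bonds would put two cations side by side; keep exactly one. The
    # nitrogen with more heavy-atom substituents is returned to neutral
    # (ties: lower canonical rank goes neutral). The scan covers every
    # sp3 N-H cation, not just freshly protonated ones, so reapplying the
    # rules cannot re-create the second cation.
    cations = sorted({i for i in protonated} | {
        a.GetIdx() for a in rw.GetAtoms()
        if a.GetAtomicNum() == 7 and a.GetFormalCharge() == 1
        and a.GetTotalNumHs() >= 1 and not a.GetIsAromatic()
        and all(b.GetBondType() == Chem.BondType.SINGLE for b in a.GetBonds())})
    if len(cations) > 1:
        ranks = list(Chem.CanonicalRankAtoms(rw, breakTies=True))
        dmat = Chem.GetDistanceMatrix(rw)
        for i, ni in enumerate(cations):
            for nj in cations[i + 1:]:
                ai, aj = rw.GetAtomWithIdx(ni), rw.GetAtomWithIdx(nj)
                if ai.GetFormalCharge() <= 0 or aj.GetFormalCharge() <= 0:
                    continue
                if dmat[ni][nj] <= 3:
                    hi = sum(1 for n in ai.GetNeighbors() if n.GetAtomicNum() > 1)
                    hj = sum(1 for n in aj.GetNeighbors() if n.GetAtomicNum() > 1)
                    if (hi, -ranks[ni]) >= (hj, -ranks[nj]):
                        neutral = ai
                    else:
                        neutral = aj
                    neutral.SetFormalCharge(0)
                    neutral.SetNumExplicitHs(neutral.GetTotalNumHs() - 1)
                    hits.append(("diamine-single-protonation", neutral.GetIdx()))
        Chem.SanitizeMol(rw)
    return hits


def assign_protonation(mol: MoleculeGraph) -> MoleculeGraph:
    """Apply the pH-7.4 protonation rule set and add explicit hydrogens.

    Idempotent: every rule requires the pre-transformation charge state, so
    running it on already-protonated output changes nothing.
    """
    rdmol = mol.to_rdkit() if isinstance(mol, MoleculeGraph) else mol
    rw = Chem.RWMol(Chem.RemoveHs(rdmol))
    hits = _apply_charge_rules(rw)
    if hits:
        logger.info("protonation rules applied: %s", hits)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    out = Chem.AddHs(out, addCoords=out.GetNumConformers() > 0)
    return MoleculeGraph(rdmol=out)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def fix_ligand(ligand: LigandInstance,
               overrides: Optional[Dict[str, str]] = None,
               fetcher: Optional[Callable[[str], Optional[str]]] = None,
               cfg: Optional[WorkflowConfig] = None) -> FixOutcome:
    """Full ligand repair: perceive -> resolve reference -> validate
    geometry -> transfer bond orders -> protonate. Heavy-atom coordinates
    are preserved exactly; hydrogens are placed at standard geometry."""
    cfg = cfg or WorkflowConfig()
    try:
        inferred = perceive_from_geometry(ligand, cfg)
    except ValueError as exc:
        return FixOutcome(status="mismatch", stage="perceive", diagnostic=str(exc))
    try:
        reference = resolve_reference(ligand, overrides, fetcher)
    except UnresolvableReferenceError as exc:
        return FixOutcome(status="bad-reference", stage="reference",
                          diagnostic=str(exc))
    try:
        ok, diag = validate_reference_geometry(reference, inferred, cfg)
    except UnresolvableReferenceError as exc:
        return FixOutcome(status="bad-reference", stage="validate",
                          diagnostic=str(exc))
    if not ok:
        return FixOutcome(status="bad-reference", stage="validate",
                          diagnostic=diag)
    outcome = transfer_bond_orders(inferred, reference)
    if outcome.status != "fixed":
        return outcome
    fixed = assign_protonation(outcome.mol)
    # contract: crystal heavy atoms did not move
    before = inferred.heavy_coordinates()
    after = fixed.heavy_coordinates()
    # order may differ; compare as sorted point sets
    key = lambda arr: arr[np.lexsort(arr.T)]
    assert np.allclose(key(before), key(after), atol=1e-6), \
        "heavy atoms moved during ligand fixing"
    return FixOutcome(status="fixed", mol=fixed, stage="protonate",
                      diagnostic=f"reference source: {reference.source}")
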