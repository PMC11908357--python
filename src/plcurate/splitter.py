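"""Splitting deposited structures into ligand / protein / additive roles.

Two ligand classes are recognised: *small molecules*, HETATM residues whose
name matches a Chemical Component Dictionary (CCD) code named by a
reference-dataset row, and *polymers*, whole short chains (2..19 residues by
default) — typically polypeptides, oligosaccharides or oligonucleotides.

For every ligand occurrence, all biopolymer chains with any heavy atom
closer than the association cutoff (10 Å) are kept whole as the associated
protein; HETATM residues within the additive cutoff (4 Å) of that protein
become additives (ions, solvents, co-factors). Both cutoffs are strict
inequalities. Waters are kept as additives by default and can be dropped
via configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .config import WorkflowConfig
from .structure_io import (AtomRecord, ChainRecord, ResidueRecord, Structure,
                           STANDARD_AA)

logger = logging.getLogger(__name__)


class LigandNotFoundError(ValueError):
    pass


class PolymerClassViolation(ValueError):
    pass


class OrphanLigandError(ValueError):
    """No biopolymer chain lies within the association cutoff of the ligand."""


@dataclass(frozen=True)
class LigandSpec:
    kind: str                       # "ccd" | "polymer"
    ccd_code: Optional[str] = None
    chain_id: Optional[str] = None
    residue_span: Optional[Tuple[int, int]] = None   # inclusive, optional
    source: str = "user"

    def __post_init__(self):
        if self.kind == "ccd" and not self.ccd_code:
            raise ValueError("ccd spec requires ccd_code")
        if self.kind == "polymer" and not self.chain_id:
            raise ValueError("polymer spec requires chain_id")
        if self.kind not in ("ccd", "polymer"):
            raise ValueError(f"unknown ligand spec kind {self.kind!r}")


@dataclass
class LigandInstance:
    spec: LigandSpec
    chain_id: str
    residues: List[ResidueRecord]

    @property
    def atoms(self) -> List[AtomRecord]:
        return [a for r in self.residues for a in r.atoms if a.element != "H"]

    @property
    def residue_names(self) -> List[str]:
        return [r.name for r in self.residues]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def key(self) -> str:
        first = self.residues[0]
        name = self.spec.ccd_code or "-".join(self.residue_names[:1]) + f"x{self.n_residues}"
        icode = first.insertion_code
        return f"{name}_{self.chain_id}_{first.seq_number}{icode}"

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def sequence_one_letter(self) -> Optional[str]:
        from ._residues import THREE_TO_ONE, VARIANT_TO_STANDARD
        letters = []
        for name in self.residue_names:
            std = VARIANT_TO_STANDARD.get(name, name)
            if std not in THREE_TO_ONE:
                return None
            letters.append(THREE_TO_ONE[std])
        return "".join(letters)


@dataclass
class ComplexBundle:
    ligand: LigandInstance
    protein: Structure
    additives: List[ResidueRecord]
    entry_id: str
    conect_pairs: set = field(default_factory=set)
    provenance: List[str] = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.entry_id}_{self.ligand.key}"


def identify_ligands(structure: Structure,
                     specs: Sequence[LigandSpec],
                     cfg: Optional[WorkflowConfig] = None) -> List[LigandInstance]:
    """Find every occurrence of each ligand spec in the structure.

    A CCD spec yields one instance per matching residue (copies in
    different chains are separate instances); a polymer spec yields the
    whole named chain, which must respect the polymer residue-count bounds.
    Instances are sorted by (chain, residue key) for determinism.
    """
    cfg = cfg or WorkflowConfig()
    instances: List[LigandInstance] = []
    for spec in specs:
        found = False
        if spec.kind == "ccd":
            for chain in structure.chains:
                for res in chain.residues:
                    if res.name == spec.ccd_code:
                        instances.append(LigandInstance(
                            spec=spec, chain_id=chain.chain_id, residues=[res]))
                        found = True
        else:
            chain = structure.chain(spec.chain_id)
            if chain is not None:
                residues = chain.residues
                if spec.residue_span is not None:
                    lo, hi = spec.residue_span
                    residues = [r for r in residues if lo <= r.seq_number <= hi]
                if residues:
                    n = len(residues)
                    if n >= cfg.polymer_ligand_max_residues:
                        raise PolymerClassViolation(
                            f"polymer spec {spec} matches chain of {n} residues, "
                            f"limit is < {cfg.polymer_ligand_max_residues}")
                    if n < cfg.polymer_ligand_min_residues:
                        raise PolymerClassViolation(
                            f"polymer spec {spec} matches only {n} residue(s), "
                            f"need >= {cfg.polymer_ligand_min_residues}")
                    instances.append(LigandInstance(
                        spec=spec, chain_id=chain.chain_id, residues=list(residues)))
                    found = True
        if not found:
            raise LigandNotFoundError(f"no residue/chain matches ligand spec {spec}")
    instances.sort(key=lambda li: (li.chain_id, li.residues[0].key))
    return instances


def _chain_heavy_coords(chain: ChainRecord) -> np.ndarray:
    pts = [a.position for r in chain.residues for a in r.atoms
           if a.element != "H" and a.record_kind == "ATOM"]
    return np.array(pts) if pts else np.empty((0, 3))


def extract_complex(structure: Structure, ligand: LigandInstance,
                    cfg: Optional[WorkflowConfig] = None,
                    exclude_ligand_residues: Optional[set] = None) -> ComplexBundle:
    """Build one curated unit around a ligand occurrence.

    ``exclude_ligand_residues`` holds (chain_id, seq, icode) keys of residues
    serving as the ligand in *other* bundles of the same entry; they are
    never counted as additives, keeping roles disjoint.
    """
    cfg = cfg or WorkflowConfig()
    lig_coords = ligand.coordinates()
    if lig_coords.size == 0:
        raise ValueError("ligand instance carries no heavy atoms")
    lig_tree = cKDTree(lig_coords)
    lig_res_keys = {(ligand.chain_id, r.seq_number, r.insertion_code)
                    for r in ligand.residues}
    excluded = set(exclude_ligand_residues or ()) | lig_res_keys

    protein_chains: List[ChainRecord] = []
    for chain in structure.chains:
        if not chain.is_polymer:
            continue
        if chain.chain_id == ligand.chain_id and ligand.spec.kind == "polymer":
            continue
        coords = _chain_heavy_coords(chain)
        if coords.size == 0:
            continue
        dmin = lig_tree.query(coords)[0].min()
        if dmin < cfg.protein_assoc_cutoff:
            protein_chains.append(chain)
            logger.debug("chain %s associated (min dist %.2f)", chain.chain_id, dmin)

    if not protein_chains:
        raise OrphanLigandError(
            f"no biopolymer chain within {cfg.protein_assoc_cutoff} A of "
            f"ligand {ligand.key}")

    prot_coords = np.concatenate([
        _chain_heavy_coords(c) for c in protein_chains])
    prot_tree = cKDTree(prot_coords)

    additives: List[ResidueRecord] = []
    for chain in structure.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.seq_number, res.insertion_code)
            if key in excluded:
                continue
            if not all(a.record_kind == "HETATM" for a in res.atoms):
                continue
            if cfg.drop_waters and res.is_water:
                continue
            coords = np.array([a.position for a in res.heavy_atoms()])
            if coords.size == 0:
                continue
            if prot_tree.query(coords)[0].min() < cfg.additive_cutoff:
                additives.append(res)

    protein = Structure(entry_id=structure.entry_id,
                        chains=protein_chains,
                        conect_pairs=set(),
                        model_number=structure.model_number)
    return ComplexBundle(ligand=ligand, protein=protein, additives=additives,
                         entry_id=structure.entry_id,
                         conect_pairs=set(structure.conect_pairs),
                         provenance=[f"protein chains: "
                                     f"{[c.chain_id for c in protein_chains]}",
                                     f"additives: {len(additives)}"])


# ---------------------------------------------------------------------------
# reference-dataset dialect adapters
# ---------------------------------------------------------------------------

_POLYMER_TAGS = {"peptide", "dna", "rna"}


def specs_from_simple_csv(rows: Sequence[dict], entry_id: str) -> List[LigandSpec]:
    """Two-column dialect: entry_id, ccd_or_span. A span is CHAIN:LO-HI or a
    bare chain id; anything else is a CCD code."""
    specs = []
    for row in rows:
        if row.get("entry_id", "").lower() != entry_id.lower():
            continue
        token = row["ccd_or_span"].strip()
        if ":" in token:
            chain, span = token.split(":", 1)
            lo, hi = (int(x) for x in span.split("-"))
            specs.append(LigandSpec(kind="polymer", chain_id=chain,
                                    residue_span=(lo, hi), source="simple-csv"))
        elif len(token) == 1 and token.isalpha() and token.isupper():
            specs.append(LigandSpec(kind="polymer", chain_id=token,
                                    source="simple-csv"))
        else:
            specs.append(LigandSpec(kind="ccd", ccd_code=token, source="simple-csv"))
    return specs


def specs_from_biolip(rows: Sequence[dict], entry_id: str) -> List[LigandSpec]:
    """BioLiP-style rows: columns ``pdb_id``, ``ligand_ccd``, ``ligand_chain``.
    Polymer tags 'peptide'/'dna'/'rna' name the whole ligand chain."""
    specs = []
    for row in rows:
        if row.get("pdb_id", "").lower() != entry_id.lower():
            continue
        ccd = row["ligand_ccd"].strip()
        if ccd.lower() in _POLYMER_TAGS:
            specs.append(LigandSpec(kind="polymer", chain_id=row["ligand_chain"],
                                    source="biolip"))
        else:
            specs.append(LigandSpec(kind="ccd", ccd_code=ccd, source="biolip"))
    return specs


def specs_from_pdbbind(rows: Sequence[dict], entry_id: str) -> List[LigandSpec]:
    """PDBbind-style rows: a ``ligand_name`` column where patterns like
    '5-mer' or names joined by '&' or '+' indicate polymer ligands on the
    chain in ``ligand_chain``; otherwise the name is a CCD code in parens
    or bare."""
    specs = []
    for row in rows:
        if row.get("pdb_id", "").lower() != entry_id.lower():
            continue
        name = row["ligand_name"].strip().strip("()")
        if "-mer" in name.lower() or "&" in name or "+" in name:
            specs.append(LigandSpec(kind="polymer", chain_id=row["ligand_chain"],
                                    source="pdbbind"))
        else:
            specs.append(LigandSpec(kind="ccd", ccd_code=name, source="pdbbind"))
    return specs


def specs_from_moad(rows: Sequence[dict], entry_id: str) -> List[LigandSpec]:
    """MOAD-style rows: a ``ligand_name`` column that may hold several CCD
    codes separated by spaces or ':' (a multi-CCD name means a polymer built
    from those components, named by ``ligand_chain``)."""
    specs = []
    for row in rows:
        if row.get("pdb_id", "").lower() != entry_id.lower():
            continue
        names = row["ligand_name"].replace(":", " ").split()
        if len(names) > 1:
            specs.append(LigandSpec(kind="polymer", chain_id=row["ligand_chain"],
                                    source="moad"))
        else:
            specs.append(LigandSpec(kind="ccd", ccd_code=names[0], source="moad"))
    return specs
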