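"""Reading and writing of structure files.

PDB coordinate files are read through gemmi into a light internal model
(chains -> residues -> atoms plus CONECT pairs). mmCIF files are consulted
for header metadata only: resolution, deposit date, experimental method and
the full deposited polymer sequences with per-position modeled flags, which
drive missing-residue detection.

Conventions applied on input (both are logged):

* alternate locations are collapsed to the highest-occupancy conformer
  (ties broken by first label alphabetically);
* hydrogens present in deposited files are dropped — both fixers re-add
  them under a uniform protonation policy, so ``is_experimental`` refers to
  heavy atoms only;
* for multi-model (NMR) files only one model is kept, the first by default.

On output, atoms added by the fixers are written with occupancy 0.00 and
experimentally resolved atoms with their original occupancy, so a written
file re-parses to an equal model including the experimental flags.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np
from rdkit import Chem

from ._residues import THREE_TO_ONE, VARIANT_TO_STANDARD

logger = logging.getLogger(__name__)

STANDARD_AA = set(THREE_TO_ONE) | set(VARIANT_TO_STANDARD)
STANDARD_NUCLEOTIDES = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU"}
WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    pass


class EmptyStructureError(PDBParseError):
    pass


class MetadataError(ValueError):
    pass


class PDBCapacityError(ValueError):
    pass


class SDFWriteError(ValueError):
    pass


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    position: np.ndarray
    occupancy: float = 1.0
    record_kind: str = "ATOM"       # ATOM | HETATM
    is_experimental: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    def __eq__(self, other):
        # serial numbers are bookkeeping, not identity: writers may renumber
        if not isinstance(other, AtomRecord):
            return NotImplemented
        return (self.name == other.name
                and self.element == other.element
                and self.record_kind == other.record_kind
                and self.is_experimental == other.is_experimental
                and np.allclose(self.position, other.position, atol=1.5e-3))


@dataclass
class ResidueRecord:
    name: str
    seq_number: int
    insertion_code: str = ""
    atoms: List[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> Tuple[int, str]:
        return (self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def heavy_atoms(self) -> List[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class ChainRecord:
    chain_id: str
    residues: List[ResidueRecord] = field(default_factory=list)
    is_polymer: bool = False

    def residue(self, seq_number: int, insertion_code: str = "") -> Optional[ResidueRecord]:
        for r in self.residues:
            if r.key == (seq_number, insertion_code):
                return r
        return None


@dataclass
class Structure:
    entry_id: str
    chains: List[ChainRecord] = field(default_factory=list)
    conect_pairs: Set[frozenset] = field(default_factory=set)
    model_number: int = 1

    def chain(self, chain_id: str) -> Optional[ChainRecord]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def iter_atoms(self):
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def atom_by_serial(self, serial: int) -> Optional[AtomRecord]:
        for _, _, a in self.iter_atoms():
            if a.serial == serial:
                return a
        return None

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def conect_keys(self) -> Set[frozenset]:
        """CONECT pairs expressed by atom identity instead of serial number,
        for comparisons across renumbering."""
        ident = {}
        for c, r, a in self.iter_atoms():
            ident[a.serial] = (c.chain_id, r.seq_number, r.insertion_code, a.name)
        return {frozenset(ident[s] for s in pair) for pair in self.conect_pairs
                if all(s in ident for s in pair)}

    def coordinates(self, heavy_only: bool = True) -> np.ndarray:
        pts = [a.position for _, _, a in self.iter_atoms()
               if not (heavy_only and a.element == "H")]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class ChainSequence:
    """Full deposited sequence of one polymer chain."""
    sequence: str                      # one-letter codes, X for unknown
    modeled: List[bool]                # per position
    seq_ids: List[int]                 # label seq ids, 1-based

    def __post_init__(self):
        assert len(self.sequence) == len(self.modeled) == len(self.seq_ids)


@dataclass
class EntryMetadata:
    entry_id: str
    resolution: Optional[float]
    deposit_date: Optional[str]
    experimental_method: Optional[str]
    full_sequences: Dict[str, ChainSequence]


def _is_polymer_residue(res: ResidueRecord) -> bool:
    return res.name in STANDARD_AA or res.name in STANDARD_NUCLEOTIDES


def _collapse_altlocs(raw_atoms) -> list:
    """Keep one conformer per atom name: highest occupancy, ties by label."""
    by_name: Dict[str, list] = {}
    for a in raw_atoms:
        by_name.setdefault(a[1], []).append(a)
    kept = []
    for name, variants in by_name.items():
        if len(variants) > 1:
            variants.sort(key=lambda a: (-a[5], a[3]))
            logger.debug("alt-loc collapse for atom %s: kept %r", name, variants[0][3])
        kept.append(variants[0])
    kept.sort(key=lambda a: a[0])
    return kept


def parse_pdb(text: str, model_select: int = 1, entry_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the selected model is kept (1-based index into the models present).
    Hydrogens are dropped; alternate locations are collapsed.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"unparseable PDB document: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("document contains no coordinate records")
    idx = min(model_select, len(st)) - 1
    model = st[idx]

    chains: List[ChainRecord] = []
    kept_serials: Set[int] = set()
    for ch in model:
        chain = ChainRecord(chain_id=ch.name)
        for res in ch:
            rr = ResidueRecord(
                name=res.name,
                seq_number=res.seqid.num,
                insertion_code=res.seqid.icode.strip(),
            )
            raw = []
            for atom in res:
                elem = atom.element.name if atom.element else ""
                if not elem or elem == "X":
                    elem = "".join(c for c in atom.name if c.isalpha())[:1].upper()
                    logger.debug("element heuristic used for atom %s -> %s",
                                 atom.name, elem)
                raw.append((atom.serial, atom.name, elem, atom.altloc.strip(),
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            atom.occ))
            for serial, name, elem, alt, pos, occ in _collapse_altlocs(raw):
                if elem == "H" or elem == "D":
                    continue
                rr.atoms.append(AtomRecord(
                    serial=serial, name=name, element=elem, alt_loc="",
                    position=pos, occupancy=occ,
                    record_kind="HETATM" if res.het_flag == "H" else "ATOM",
                    is_experimental=occ > 0.0,
                ))
                kept_serials.add(serial)
            if rr.atoms:
                chain.residues.append(rr)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
            chain.is_polymer = any(
                r.name in STANDARD_AA or r.name in STANDARD_NUCLEOTIDES
                for r in chain.residues
                if any(a.record_kind == "ATOM" for a in r.atoms))
            chains.append(chain)

    if not chains:
        raise EmptyStructureError("document contains no coordinate records")

    conect: Set[frozenset] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("CONECT"):
            try:
                fields = [int(line[i:i + 5]) for i in range(6, min(len(line), 31), 5)
                          if line[i:i + 5].strip()]
            except ValueError as exc:
                raise PDBParseError(f"bad CONECT record at line {lineno}") from exc
            if fields:
                base = fields[0]
                for other in fields[1:]:
                    if base != other and base in kept_serials and other in kept_serials:
                        conect.add(frozenset((base, other)))

    eid = entry_id or (st.name.strip() if st.name else "")
    return Structure(entry_id=eid, chains=chains, conect_pairs=conect,
                     model_number=model.num if hasattr(model, "num") else idx + 1)


def parse_mmcif_header(text: str) -> EntryMetadata:
    """Extract metadata (resolution, date, method, full sequences) from an
    mmCIF document. Coordinates in the document are ignored."""
    doc = gemmi.cif.read_string(text)
    block = doc.sole_block()

    entry_id = block.find_value("_entry.id") or ""
    entry_id = entry_id.strip("'\"")

    resolution = None
    for tag in ("_refine.ls_d_res_high", "_em_3d_reconstruction.resolution"):
        val = block.find_value(tag)
        if val and val not in (".", "?"):
            resolution = float(val)
            break

    date = block.find_value("_pdbx_database_status.recvd_initial_deposition_date")
    if date in (".", "?"):
        date = None
    method = block.find_value("_exptl.method")
    if method:
        method = method.strip("'\"")

    table = block.find("_pdbx_poly_seq_scheme.",
                       ["pdb_strand_id", "mon_id", "seq_id", "auth_seq_num"])
    if len(table) == 0:
        raise MetadataError("mmCIF header lacks _pdbx_poly_seq_scheme; "
                            "cannot recover deposited sequences")
    per_chain: Dict[str, list] = {}
    for row in table:
        chain_id = row[0]
        mon = row[1]
        one = THREE_TO_ONE.get(mon) or THREE_TO_ONE.get(
            VARIANT_TO_STANDARD.get(mon, ""), "X")
        modeled = row[3] not in (".", "?")
        per_chain.setdefault(chain_id, []).append((int(row[2]), one, modeled))

    sequences = {}
    for chain_id, rows in per_chain.items():
        rows.sort()
        sequences[chain_id] = ChainSequence(
            sequence="".join(r[1] for r in rows),
            modeled=[r[2] for r in rows],
            seq_ids=[r[0] for r in rows],
        )
    return EntryMetadata(entry_id=entry_id, resolution=resolution,
                         deposit_date=date, experimental_method=method,
                         full_sequences=sequences)


def write_pdb(structure: Structure,
              fix_annotations: Optional[Sequence[str]] = None) -> str:
    """Serialize a Structure as PDB text.

    ``fix_annotations`` are free-text per-residue notes emitted as REMARK 99
    lines so that downstream users can distinguish deposited from rebuilt
    content.
    """
    if structure.n_atoms() > 99999:
        raise PDBCapacityError("PDB format supports at most 99,999 atoms")
    lines = [f"HEADER    CURATED COMPLEX                         {structure.entry_id:>4s}"]
    for note in (fix_annotations or []):
        lines.append(f"REMARK  99 FIX {note}")
    serial_map: Dict[int, int] = {}
    serial = 0
    for chain in structure.chains:
        last = None
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                serial_map[atom.serial] = serial
                if len(atom.name) < 4 and len(atom.element) < 2:
                    name_f = f" {atom.name:<3s}"
                else:
                    name_f = f"{atom.name:<4s}"
                x, y, z = atom.position
                occ = atom.occupancy if atom.is_experimental else 0.0
                icode = res.insertion_code or " "
                lines.append(
                    f"{atom.record_kind:<6s}{serial:>5d} {name_f} {res.name:>3s} "
                    f"{chain.chain_id:>1s}{res.seq_number:>4d}{icode:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}")
                last = (res, serial)
        if last is not None and chain.is_polymer:
            res, s = last
            icode = res.insertion_code or " "
            lines.append(f"TER   {s + 1:>5d}      {res.name:>3s} "
                         f"{chain.chain_id:>1s}{res.seq_number:>4d}{icode:1s}")
            serial += 1
    for pair in sorted(structure.conect_pairs, key=sorted):
        a, b = sorted(pair)
        if a in serial_map and b in serial_map:
            na, nb = serial_map[a], serial_map[b]
            lines.append(f"CONECT{na:>5d}{nb:>5d}")
            lines.append(f"CONECT{nb:>5d}{na:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_sdf(mol, name: str = "ligand") -> str:
    """Write a chemistry-complete molecule as V2000 SDF text.

    Formal charges go into ``M  CHG`` fields; aromatic rings are written
    kekulized, never via aromatic-atom tricks on equivalent oxygens.
    Accepts an RDKit Mol or any object with a ``to_rdkit`` method.
    """
    rdmol = mol.to_rdkit() if hasattr(mol, "to_rdkit") else mol
    if rdmol.GetNumConformers() == 0:
        raise SDFWriteError("molecule has no 3D coordinates")
    rdmol = Chem.Mol(rdmol)
    rdmol.SetProp("_Name", name)
    Chem.Kekulize(rdmol, clearAromaticFlags=False)
    block = Chem.MolToMolBlock(rdmol, kekulize=True)
    return block + "$$$$\n"


def parse_sdf(text: str, remove_hs: bool = False):
    """Parse the first molecule of an SDF document into an RDKit Mol."""
    mol = Chem.MolFromMolBlock(text.split("$$$$")[0], removeHs=remove_hs)
    if mol is None:
        raise ValueError("unparseable SDF document")
    return mol


RCSB_PDB_URL = "https://files.rcsb.org/download/{}.pdb"
RCSB_CIF_URL = "https://files.rcsb.org/download/{}.cif"


def fetch_entry(entry_id: str, cache_dir: Path) -> Tuple[Path, Path]:
    """Download PDB and mmCIF files for an accession from RCSB, caching them
    locally. Network use is opt-in; every other code path takes local files."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for url, suffix in ((RCSB_PDB_URL, ".pdb"), (RCSB_CIF_URL, ".cif")):
        dest = cache_dir / f"{entry_id.lower()}{suffix}"
        if not dest.exists():
            logger.info("fetching %s", url.format(entry_id.upper()))
            with urllib.request.urlopen(url.format(entry_id.upper()), timeout=60) as resp:
                dest.write_bytes(resp.read())
        paths.append(dest)
    return tuple(paths)
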