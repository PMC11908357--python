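"""Static chemistry tables for the 20 standard alpha-amino acids.

Heavy-atom name sets follow PDB v3 naming. Template SMILES are written so
that the i-th atom of the parsed molecule corresponds to the i-th PDB atom
name in ``TEMPLATE_NAMES`` — this lets an embedded 3D conformer of the
template be superposed onto a partially resolved residue to place missing
atoms.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# common non-standard residues mapped onto standard repair templates
VARIANT_TO_STANDARD = {"MSE": "MET", "SEC": "CYS", "HID": "HIS", "HIE": "HIS",
                       "HIP": "HIS", "CYX": "CYS", "ASH": "ASP", "GLH": "GLU",
                       "LYN": "LYS"}

BACKBONE = ("N", "CA", "C", "O")

SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

HEAVY_ATOMS = {res: list(BACKBONE) + sc for res, sc in SIDECHAIN_ATOMS.items()}

# (smiles, atom names in SMILES parse order); C=O stands in for the peptide
# carbonyl — only geometry is taken from these, never protonation.
TEMPLATES = {
    "ALA": ("NC(C=O)C", ["N", "CA", "C", "O", "CB"]),
    "ARG": ("NC(C=O)CCCNC(=N)N",
            ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"]),
    "ASN": ("NC(C=O)CC(=O)N", ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"]),
    "ASP": ("NC(C=O)CC(=O)O", ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"]),
    "CYS": ("NC(C=O)CS", ["N", "CA", "C", "O", "CB", "SG"]),
    "GLN": ("NC(C=O)CCC(=O)N",
            ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"]),
    "GLU": ("NC(C=O)CCC(=O)O",
            ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"]),
    "GLY": ("NCC=O", ["N", "CA", "C", "O"]),
    "HIS": ("NC(C=O)Cc1[nH]cnc1",
            ["N", "CA", "C", "O", "CB", "CG", "ND1", "CE1", "NE2", "CD2"]),
    "ILE": ("NC(C=O)C(C)CC",
            ["N", "CA", "C", "O", "CB", "CG2", "CG1", "CD1"]),
    "LEU": ("NC(C=O)CC(C)C",
            ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"]),
    "LYS": ("NC(C=O)CCCCN",
            ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"]),
    "MET": ("NC(C=O)CCSC", ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"]),
    "PHE": ("NC(C=O)Cc1ccccc1",
            ["N", "CA", "C", "O", "CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2"]),
    "PRO": ("N1C(C=O)CCC1", ["N", "CA", "C", "O", "CB", "CG", "CD"]),
    "SER": ("NC(C=O)CO", ["N", "CA", "C", "O", "CB", "OG"]),
    "THR": ("NC(C=O)C(O)C", ["N", "CA", "C", "O", "CB", "OG1", "CG2"]),
    "TRP": ("NC(C=O)Cc1c[nH]c2ccccc12",
            ["N", "CA", "C", "O", "CB", "CG", "CD1", "NE1", "CE2",
             "CZ2", "CH2", "CZ3", "CE3", "CD2"]),
    "TYR": ("NC(C=O)Cc1ccc(O)cc1",
            ["N", "CA", "C", "O", "CB", "CG", "CD1", "CE1", "CZ", "OH",
             "CE2", "CD2"]),
    "VAL": ("NC(C=O)C(C)C", ["N", "CA", "C", "O", "CB", "CG1", "CG2"]),
}

# L-amino-acid side-chain fragments for building linear peptide SMILES;
# each residue contributes "N[C@@H](<frag>)C(=O)" (GLY and PRO special).
SIDECHAIN_SMILES = {
    "A": "C", "R": "CCCNC(=[NH2+])N", "N": "CC(N)=O", "D": "CC(=O)O",
    "C": "CS", "Q": "CCC(N)=O", "E": "CCC(=O)O", "H": "Cc1c[nH]cn1",
    "I": "[C@@H](C)CC", "L": "CC(C)C", "K": "CCCCN", "M": "CCSC",
    "F": "Cc1ccccc1", "S": "CO", "T": "[C@H](O)C", "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1", "V": "C(C)C",
}

# side-chain torsion angle definitions (chi1..chi4); each entry is the
# atom-name quadruple. Terminal two-fold-symmetric torsions are listed in
# CHI_SYMMETRIC as (residue, chi index) and folded into (-90, 90].
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# torsions whose terminal atom pair is chemically equivalent; the periodic
# difference is additionally folded by 180 degrees for these.
CHI_SYMMETRIC = {("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2)}
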