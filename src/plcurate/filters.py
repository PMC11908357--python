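"""The four rejection filters.

A complex is rejected when the ligand is covalently bonded to the protein
(CONECT record joining a ligand atom to a protein atom), when it contains
elements outside the allowed organic set, when it has fewer than the
minimum number of heavy atoms, or when any protein-ligand heavy-atom pair
lies closer than the clash cutoff (such contacts arise from electron
density uncertainty, not physical non-covalent binding — and also catch
covalent binders whose bond was never recorded in CONECT).

All four rules are always evaluated — no short-circuiting — so a report
lists every reason a bundle fails. Additives are excluded from the clash
scan: the filter targets protein-ligand pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .config import WorkflowConfig
from .splitter import ComplexBundle, LigandInstance

logger = logging.getLogger(__name__)

RULE_COVALENT = "covalent-binder"
RULE_ELEMENTS = "rare-element"
RULE_SIZE = "small-ligand"
RULE_CLASH = "steric-clash"


class UnknownElementError(ValueError):
    """Element symbol not in the periodic table (data defect, not a filter hit)."""


@dataclass
class RuleVerdict:
    rule_id: str
    passed: bool
    evidence: str = ""


@dataclass
class FilterReport:
    verdicts: List[RuleVerdict] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    @property
    def failures(self) -> List[Tuple[str, str]]:
        return [(v.rule_id, v.evidence) for v in self.verdicts if not v.passed]


_PERIODIC = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR", "MN", "FE",
    "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR", "RB", "SR",
    "Y", "ZR", "NB", "MO", "TC", "RU", "RH", "PD", "AG", "CD", "IN", "SN",
    "SB", "TE", "I", "XE", "CS", "BA", "LA", "CE", "PR", "ND", "PM", "SM",
    "EU", "GD", "TB", "DY", "HO", "ER", "TM", "YB", "LU", "HF", "TA", "W",
    "RE", "OS", "IR", "PT", "AU", "HG", "TL", "PB", "BI", "PO", "AT", "RN",
    "FR", "RA", "AC", "TH", "PA", "U",
}


def check_covalent(bundle: ComplexBundle) -> RuleVerdict:
    """Fail iff a CONECT pair joins a ligand atom to a protein atom.

    A file without CONECT records vacuously passes.
    """
    lig_serials = {a.serial for a in bundle.ligand.atoms}
    prot_serials = {a.serial for _, _, a in bundle.protein.iter_atoms()}
    offending = []
    for pair in sorted(bundle.conect_pairs, key=sorted):
        s = set(pair)
        if s & lig_serials and s & prot_serials:
            offending.append(tuple(sorted(pair)))
    if offending:
        return RuleVerdict(RULE_COVALENT, False,
                           f"CONECT joins ligand to protein: {offending}")
    return RuleVerdict(RULE_COVALENT, True)


def check_elements(ligand: LigandInstance,
                   cfg: Optional[WorkflowConfig] = None) -> RuleVerdict:
    """Fail iff any ligand atom's element is outside the allowed set."""
    cfg = cfg or WorkflowConfig()
    allowed = {e.upper() for e in cfg.allowed_elements}
    bad = sorted({a.element for a in ligand.atoms
                  if a.element.upper() not in allowed})
    unknown = [e for a in ligand.atoms
               if (e := a.element).upper() not in _PERIODIC]
    if unknown:
        raise UnknownElementError(f"unknown element symbol(s): {sorted(set(unknown))}")
    if bad:
        return RuleVerdict(RULE_ELEMENTS, False,
                           f"disallowed element(s): {bad}")
    return RuleVerdict(RULE_ELEMENTS, True)


def check_size(ligand: LigandInstance,
               cfg: Optional[WorkflowConfig] = None) -> RuleVerdict:
    """Fail iff the ligand has fewer heavy atoms than the minimum (strict)."""
    cfg = cfg or WorkflowConfig()
    n = len(ligand.atoms)
    if n < cfg.min_heavy_atoms:
        return RuleVerdict(RULE_SIZE, False,
                           f"{n} heavy atoms < {cfg.min_heavy_atoms}")
    return RuleVerdict(RULE_SIZE, True)


def check_clash(bundle: ComplexBundle,
                cfg: Optional[WorkflowConfig] = None) -> RuleVerdict:
    """Fail iff the minimum protein-ligand heavy-atom distance is below the
    clash cutoff (strict: a pair exactly at the cutoff passes)."""
    cfg = cfg or WorkflowConfig()
    lig_atoms = bundle.ligand.atoms
    prot_atoms = [a for _, _, a in bundle.protein.iter_atoms() if a.element != "H"]
    if not prot_atoms:
        raise ValueError("bundle has an empty protein; cannot evaluate clash rule")
    lig_coords = np.array([a.position for a in lig_atoms])
    prot_coords = np.array([a.position for a in prot_atoms])
    dists, idx = cKDTree(prot_coords).query(lig_coords)
    i = int(np.argmin(dists))
    dmin = float(dists[i])
    if dmin < cfg.clash_cutoff:
        pa = prot_atoms[int(idx[i])]
        la = lig_atoms[i]
        return RuleVerdict(
            RULE_CLASH, False,
            f"ligand {la.name}(#{la.serial}) vs protein {pa.name}(#{pa.serial}) "
            f"at {dmin:.2f} A < {cfg.clash_cutoff} A")
    return RuleVerdict(RULE_CLASH, True, f"min distance {dmin:.2f} A")


def apply_filters(bundle: ComplexBundle,
                  cfg: Optional[WorkflowConfig] = None) -> FilterReport:
    """Evaluate all four rules (covalent, rare-element, small-ligand, clash)
    and aggregate the verdicts into a complete report."""
    cfg = cfg or WorkflowConfig()
    report = FilterReport(verdicts=[
        check_covalent(bundle),
        check_elements(bundle.ligand, cfg),
        check_size(bundle.ligand, cfg),
        check_clash(bundle, cfg),
    ])
    if not report.passed:
        logger.info("bundle %s rejected: %s", bundle.key, report.failures)
    return report


def report_rows(bundle: ComplexBundle, report: FilterReport) -> List[dict]:
    """CSV manifest rows (entry, ligand, rule, verdict, evidence)."""
    return [{"entry_id": bundle.entry_id, "ligand": bundle.ligand.key,
             "rule_id": v.rule_id, "passed": v.passed, "evidence": v.evidence}
            for v in report.verdicts]
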