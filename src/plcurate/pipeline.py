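"""Per-entry orchestration of the full curation workflow and batch driving.

For each entry the stages run in order: split (ligand identification and
complex extraction), the four filters, ligand fixing, protein fixing, and
constrained refinement. The first hard failure terminates that bundle with
a stage tag; other bundles of the same entry continue independently — one
deposited structure can legitimately yield several curated complexes
(copies of a ligand across chains, different ligands, different pockets).

Batch execution appends one row per entry to a ledger CSV and skips
entries that already reached a terminal status, so an interrupted batch
can simply be rerun. Individual entry failures never abort the batch.
"""

from __future__ import annotations

import csv
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import filters as filt
from .config import WorkflowConfig
from .ligand_fixer import fix_ligand, table_fetcher
from .protein_fixer import (MetadataError, RepairError, detect_missing,
                            protonate_protein, repair_protein)
from .refiner import RefinementError, minimize_complex
from .splitter import (ComplexBundle, LigandNotFoundError, OrphanLigandError,
                       extract_complex, identify_ligands, specs_from_simple_csv)
from .structure_io import (ChainRecord, Structure, parse_mmcif_header,
                           parse_pdb, write_pdb, write_sdf)

logger = logging.getLogger(__name__)

STATUS_SUCCEEDED = "succeeded"
STATUS_FILTER_REJECTED = "filter-rejected"
STATUS_FIX_FAILED = "fix-failed"
STATUS_ERRORED = "errored"


@dataclass
class BundleResult:
    bundle_key: str
    status: str
    stages: Dict[str, str] = field(default_factory=dict)
    output_dir: Optional[Path] = None
    filter_failures: List[tuple] = field(default_factory=list)


@dataclass
class CurationResult:
    entry_id: str
    status: str
    bundles: List[BundleResult] = field(default_factory=list)
    error: str = ""

    @property
    def n_succeeded(self) -> int:
        return sum(1 for b in self.bundles if b.status == STATUS_SUCCEEDED)


def _entry_status(bundles: List[BundleResult]) -> str:
    if any(b.status == STATUS_SUCCEEDED for b in bundles):
        return STATUS_SUCCEEDED
    if any(b.status == STATUS_FIX_FAILED for b in bundles):
        return STATUS_FIX_FAILED
    if any(b.status == STATUS_FILTER_REJECTED for b in bundles):
        return STATUS_FILTER_REJECTED
    return STATUS_ERRORED


def _load_csv_rows(path: Path) -> List[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def run_entry(entry_dir: Path, out_dir: Optional[Path] = None,
              cfg: Optional[WorkflowConfig] = None,
              overrides: Optional[Dict[str, str]] = None) -> CurationResult:
    """Curate one entry from a local directory holding ``structure.pdb``,
    ``header.cif``, ``ligands.csv`` (entry_id, ccd_or_span) and
    ``ref_smiles.csv`` (code, smiles), plus optional ``overrides.csv``."""
    cfg = cfg or WorkflowConfig()
    entry_dir = Path(entry_dir)
    entry_id = entry_dir.name
    try:
        pdb_path = entry_dir / "structure.pdb"
        structure = parse_pdb(pdb_path.read_text(), entry_id=entry_id)
        meta = parse_mmcif_header((entry_dir / "header.cif").read_text())
        lig_rows = _load_csv_rows(entry_dir / "ligands.csv")
        entry_key = lig_rows[0]["entry_id"] if lig_rows else entry_id
        specs = specs_from_simple_csv(lig_rows, entry_key)
        ref_table = {}
        ref_path = entry_dir / "ref_smiles.csv"
        if ref_path.exists():
            ref_table = {r["code"]: r["smiles"] for r in _load_csv_rows(ref_path)}
        ov_path = entry_dir / "overrides.csv"
        file_overrides = ({r["code"]: r["smiles"] for r in _load_csv_rows(ov_path)}
                          if ov_path.exists() else {})
        file_overrides.update(overrides or {})
        ligands = identify_ligands(structure, specs, cfg)
    except (FileNotFoundError, KeyError, ValueError, LigandNotFoundError) as exc:
        logger.error("entry %s unresolvable: %s", entry_id, exc)
        return CurationResult(entry_id=entry_id, status=STATUS_ERRORED,
                              error=str(exc))

    lig_res_keys = {(li.chain_id, r.seq_number, r.insertion_code)
                    for li in ligands for r in li.residues}
    fetcher = table_fetcher(ref_table)
    result = CurationResult(entry_id=entry_id, status="")
    for ligand in ligands:
        result.bundles.append(_run_bundle(
            structure, ligand, lig_res_keys, meta, fetcher, file_overrides,
            cfg, out_dir))
    result.status = _entry_status(result.bundles)
    return result


def _run_bundle(structure, ligand, lig_res_keys, meta, fetcher, overrides,
                cfg, out_dir) -> BundleResult:
    br = BundleResult(bundle_key=f"{structure.entry_id}_{ligand.key}",
                      status="", stages={})
    # --- split ---
    try:
        own = {(ligand.chain_id, r.seq_number, r.insertion_code)
               for r in ligand.residues}
        bundle = extract_complex(structure, ligand, cfg,
                                 exclude_ligand_residues=lig_res_keys - own)
        br.stages["split"] = "ok"
    except OrphanLigandError as exc:
        br.stages["split"] = f"orphan: {exc}"
        br.status = STATUS_ERRORED
        return br
    # --- filters ---
    report = filt.apply_filters(bundle, cfg)
    if not report.passed:
        br.stages["filter"] = "; ".join(f"{r}: {e}" for r, e in report.failures)
        br.filter_failures = report.failures
        br.status = STATUS_FILTER_REJECTED
        return br
    br.stages["filter"] = "ok"
    # --- ligand fixing ---
    outcome = fix_ligand(ligand, overrides, fetcher, cfg)
    if outcome.status != "fixed":
        br.stages["ligand_fix"] = f"{outcome.status}@{outcome.stage}: " \
                                  f"{outcome.diagnostic}"
        br.status = STATUS_FIX_FAILED
        return br
    br.stages["ligand_fix"] = "ok"
    # --- protein fixing ---
    try:
        missing = detect_missing(bundle.protein, meta, cfg)
        protein, annotations = repair_protein(
            bundle.protein, missing, cfg,
            ligand_coords=ligand.coordinates())
        protein = protonate_protein(protein, cfg)
        br.stages["protein_fix"] = (
            "ok" if not annotations else "; ".join(annotations))
    except (MetadataError, RepairError) as exc:
        br.stages["protein_fix"] = f"failed: {exc}"
        br.status = STATUS_FIX_FAILED
        return br
    # --- refinement ---
    try:
        refined = minimize_complex(protein, outcome.mol, cfg)
        br.stages["refine"] = (f"ok: E {refined.energy_initial:.1f} -> "
                               f"{refined.energy_final:.1f}")
    except RefinementError as exc:
        br.stages["refine"] = f"failed: {exc}"
        br.status = STATUS_FIX_FAILED
        return br
    br.status = STATUS_SUCCEEDED
    # --- outputs ---
    if out_dir is not None:
        bundle_dir = Path(out_dir) / br.bundle_key
        bundle_dir.mkdir(parents=True, exist_ok=True)
        (bundle_dir / "protein.pdb").write_text(
            write_pdb(refined.protein, annotations))
        (bundle_dir / "ligand.sdf").write_text(
            write_sdf(refined.ligand, name=br.bundle_key))
        additives = Structure(entry_id=structure.entry_id, chains=[])
        for res in bundle.additives:
            ch = ChainRecord(chain_id="X", residues=[res], is_polymer=False)
            additives.chains.append(ch)
        if additives.chains:
            (bundle_dir / "additives.pdb").write_text(write_pdb(additives))
        (bundle_dir / "stages.json").write_text(json.dumps(br.stages, indent=1))
        br.output_dir = bundle_dir
    return br


@dataclass
class BatchSummary:
    total: int = 0
    succeeded: int = 0
    filter_rejected: int = 0
    fix_failed: int = 0
    errored: int = 0
    skipped: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def run_batch(entry_dirs: Sequence[Path], out_dir: Path,
              cfg: Optional[WorkflowConfig] = None) -> BatchSummary:
    """Process entries sequentially with a resumable ledger.

    ``<out_dir>/ledger.csv`` records one terminal row per entry; entries
    already present are skipped on rerun. Per-rule rejection manifests for
    covalent binders and rare-element ligands are written separately (they
    are useful as their own curations).
    """
    cfg = cfg or WorkflowConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ledger_path = out_dir / "ledger.csv"
    done = set()
    if ledger_path.exists():
        done = {row["entry_id"] for row in _load_csv_rows(ledger_path)}

    summary = BatchSummary()
    new_rows: List[dict] = []
    covalent_rows: List[dict] = []
    rare_rows: List[dict] = []
    for entry_dir in entry_dirs:
        entry_dir = Path(entry_dir)
        summary.total += 1
        if entry_dir.name in done:
            summary.skipped += 1
            continue
        try:
            result = run_entry(entry_dir, out_dir=out_dir / "complexes", cfg=cfg)
        except Exception as exc:    # defensive: a bad entry must not kill the batch
            logger.error("entry %s crashed: %s\n%s", entry_dir.name, exc,
                         traceback.format_exc())
            result = CurationResult(entry_id=entry_dir.name,
                                    status=STATUS_ERRORED, error=str(exc))
        setattr(summary, result.status.replace("-", "_"),
                getattr(summary, result.status.replace("-", "_")) + 1)
        new_rows.append({
            "entry_id": result.entry_id, "status": result.status,
            "n_bundles": len(result.bundles),
            "n_succeeded": result.n_succeeded,
            "detail": result.error or "; ".join(
                f"{b.bundle_key}:{b.status}" for b in result.bundles),
        })
        for b in result.bundles:
            for rule, evidence in b.filter_failures:
                row = {"entry_id": result.entry_id, "bundle": b.bundle_key,
                       "rule": rule, "evidence": evidence}
                if rule == filt.RULE_COVALENT:
                    covalent_rows.append(row)
                elif rule == filt.RULE_ELEMENTS:
                    rare_rows.append(row)

    _append_csv(ledger_path, new_rows,
                ["entry_id", "status", "n_bundles", "n_succeeded", "detail"])
    _append_csv(out_dir / "rejected_covalent.csv", covalent_rows,
                ["entry_id", "bundle", "rule", "evidence"])
    _append_csv(out_dir / "rejected_rare_element.csv", rare_rows,
                ["entry_id", "bundle", "rule", "evidence"])
    return summary


def _append_csv(path: Path, rows: List[dict], fieldnames: List[str]) -> None:
    if not rows:
        return
    exists = path.exists()
    with open(path, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        if not exists:
            writer.writeheader()
        writer.writerows(rows)
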