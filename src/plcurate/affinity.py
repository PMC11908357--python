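"""Binding-affinity normalization.

Deposited affinity annotations are heterogeneous: four measurement types
(Kd, Ki, IC50, EC50), qualifiers for ranges and approximations, and units
from femtomolar to molar. Everything is parsed to molar; exact (qualifier
"=") dissociation and inhibition constants are additionally converted to a
binding free energy through dG = R T ln K. IC50/EC50 are carried through
with no dG — they depend on assay conditions and inhibition mechanism and
cannot be translated reliably — and range-qualified values are retained for
users who handle censored data. Records from multiple sources are merged
with de-duplication and an invalid-affinity rule discarding Ki/Kd above a
physically meaningless threshold (1e3 M by default).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .config import WorkflowConfig

logger = logging.getLogger(__name__)

MEASUREMENTS = ("Kd", "Ki", "IC50", "EC50")
QUALIFIERS = ("=", "~", ">=", "<=", ">", "<")
_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9,
                 "pM": 1e-12, "fM": 1e-15}

_PATTERN = re.compile(
    r"^\s*(?P<meas>Kd|Ki|IC50|IC_50_?|EC50|EC_50_?)\s*"
    r"(?P<qual>>=|<=|=|~|>|<)\s*"
    r"(?P<value>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*"
    r"(?P<unit>fM|pM|nM|uM|µM|mM|M)\s*$",
    re.IGNORECASE)

_MEAS_CANON = {"kd": "Kd", "ki": "Ki", "ic50": "IC50", "ic_50": "IC50",
               "ic_50_": "IC50", "ec50": "EC50", "ec_50": "EC50",
               "ec_50_": "EC50"}
_UNIT_CANON = {u.lower(): u for u in _UNIT_FACTORS}


class AffinityParseError(ValueError):
    """Unrecognized annotation; carries the raw text for quarantine."""

    def __init__(self, raw: str, why: str):
        super().__init__(f"cannot parse affinity annotation {raw!r}: {why}")
        self.raw = raw


@dataclass
class AffinityRecord:
    entry_id: str
    ligand: str
    measurement: str          # Kd | Ki | IC50 | EC50
    qualifier: str            # = ~ > < >= <=
    value_molar: float
    raw_text: str
    source: str = "other"     # biolip | moad | other
    delta_g: Optional[float] = None   # kJ/mol, exact Kd/Ki only

    def __post_init__(self):
        if self.value_molar <= 0:
            raise ValueError("affinity value must be positive")
        if self.measurement not in MEASUREMENTS:
            raise ValueError(f"unknown measurement {self.measurement}")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier}")

    @property
    def dedup_key(self) -> Tuple[str, str, str]:
        return (self.entry_id.lower(), self.ligand, self.measurement)

    def format(self) -> str:
        """Canonical annotation string; parse(format(r)) == r."""
        return f"{self.measurement}{self.qualifier}{self.value_molar:g}M"


def dg_from_constant(k: float, cfg: Optional[WorkflowConfig] = None) -> float:
    """Binding free energy dG = R T ln(K) in kJ/mol for a dissociation or
    inhibition constant in molar. dG(1 M) is exactly zero."""
    cfg = cfg or WorkflowConfig()
    if k <= 0:
        raise ValueError(f"equilibrium constant must be > 0, got {k}")
    return cfg.gas_constant * cfg.temperature * math.log(k)


def parse_affinity(raw: str, entry_id: str = "", ligand: str = "",
                   source: str = "other",
                   cfg: Optional[WorkflowConfig] = None) -> AffinityRecord:
    """Parse one annotation like ``Kd=2nM`` or ``IC50~5uM``.

    The qualifier is preserved verbatim; the unit is normalized to molar.
    dG is attached only for exact Kd/Ki.
    """
    if not raw or not raw.strip():
        raise AffinityParseError(raw, "empty annotation")
    m = _PATTERN.match(raw)
    if m is None:
        raise AffinityParseError(raw, "unrecognized measurement/qualifier/unit")
    meas = _MEAS_CANON[m.group("meas").lower().rstrip("_").replace("_", "")]
    unit = _UNIT_CANON[m.group("unit").lower()]
    value = float(m.group("value")) * _UNIT_FACTORS[unit]
    qual = m.group("qual")
    rec = AffinityRecord(entry_id=entry_id, ligand=ligand, measurement=meas,
                         qualifier=qual, value_molar=value, raw_text=raw,
                         source=source)
    if meas in ("Kd", "Ki") and qual == "=":
        rec.delta_g = dg_from_constant(value, cfg)
    return rec


_SOURCE_RANK = {"biolip": 0, "moad": 1, "other": 2}


def merge_sources(*record_lists: Sequence[AffinityRecord],
                  cfg: Optional[WorkflowConfig] = None
                  ) -> Tuple[List[AffinityRecord], List[dict]]:
    """Union records by (entry, ligand, measurement); de-duplicate with
    source precedence biolip > moad > other; drop Ki/Kd above the validity
    threshold. Returns (kept records, logged drop/conflict rows)."""
    cfg = cfg or WorkflowConfig()
    log: List[dict] = []
    merged: Dict[Tuple[str, str, str], AffinityRecord] = {}
    provenance: Dict[Tuple[str, str, str], List[str]] = {}
    for records in record_lists:
        for rec in records:
            if rec.measurement in ("Kd", "Ki") and rec.value_molar > cfg.max_valid_ki:
                log.append({"entry_id": rec.entry_id, "ligand": rec.ligand,
                            "reason": "invalid-affinity",
                            "detail": f"{rec.measurement}={rec.value_molar:g} M "
                                      f"> {cfg.max_valid_ki:g} M"})
                continue
            key = rec.dedup_key
            if key not in merged:
                merged[key] = rec
                provenance[key] = [rec.source]
            else:
                kept = merged[key]
                provenance[key].append(rec.source)
                if not math.isclose(kept.value_molar, rec.value_molar,
                                    rel_tol=1e-6):
                    log.append({"entry_id": rec.entry_id, "ligand": rec.ligand,
                                "reason": "source-conflict",
                                "detail": f"{kept.source}:{kept.value_molar:g} "
                                          f"vs {rec.source}:{rec.value_molar:g}"})
                if _SOURCE_RANK.get(rec.source, 2) < _SOURCE_RANK.get(kept.source, 2):
                    merged[key] = rec
    out = sorted(merged.values(), key=lambda r: r.dedup_key)
    for rec in out:
        rec.source = "+".join(dict.fromkeys(provenance[rec.dedup_key]))
    return out, log


def records_to_frame(records: Sequence[AffinityRecord]) -> pd.DataFrame:
    """The machine-readable output table."""
    return pd.DataFrame([{
        "entry_id": r.entry_id, "ligand": r.ligand,
        "measurement": r.measurement, "qualifier": r.qualifier,
        "value_molar": r.value_molar, "delta_g_kj_mol": r.delta_g,
        "source": r.source, "raw_text": r.raw_text,
    } for r in records])


# ---------------------------------------------------------------------------
# source dialect readers
# ---------------------------------------------------------------------------

def read_biolip(path_or_buf, cfg: Optional[WorkflowConfig] = None
                ) -> Tuple[List[AffinityRecord], List[dict]]:
    """BioLiP-style tab-separated rows: pdb_id, ligand_ccd, affinity."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    return _records_from_frame(df, "biolip", cfg)


def read_moad(path_or_buf, cfg: Optional[WorkflowConfig] = None
              ) -> Tuple[List[AffinityRecord], List[dict]]:
    """MOAD-style comma-separated rows: pdb_id, ligand_ccd, affinity."""
    df = pd.read_csv(path_or_buf, dtype=str)
    return _records_from_frame(df, "moad", cfg)


def _records_from_frame(df: pd.DataFrame, source: str,
                        cfg: Optional[WorkflowConfig]
                        ) -> Tuple[List[AffinityRecord], List[dict]]:
    records, quarantined = [], []
    for _, row in df.iterrows():
        raw = str(row.get("affinity", "")).strip()
        try:
            records.append(parse_affinity(
                raw, entry_id=str(row["pdb_id"]),
                ligand=str(row.get("ligand_ccd", "")), source=source, cfg=cfg))
        except AffinityParseError as exc:
            quarantined.append({"entry_id": row.get("pdb_id"),
                                "raw_text": raw, "error": str(exc)})
            logger.warning("quarantined affinity row: %s", exc)
    return records, quarantined
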