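"""Workflow configuration: every numeric threshold and rule constant in one
validated object.

The defaults encode the curation rules: ligand-associated protein chains are
labelled within 10 Å, additives within 4 Å, steric clashes are heavy-atom
pairs closer than 2 Å, ligands need at least 4 heavy atoms, polymer ligands
span 2..19 residues, allowed ligand elements are the common organic set,
internal missing segments up to 10 residues are rebuilt, protonation is
assigned for pH 7.4, rotamer changes use a 60 degree chi cutoff, and
inhibition constants above 1e3 M are treated as invalid.

Config files are flat YAML key-value documents; any key can also be
overridden per-call.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

logger = logging.getLogger(__name__)

DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"})


class ConfigError(ValueError):
    """Malformed configuration document or unknown key."""


class ConfigValidationError(ValueError):
    """A configuration value violates an invariant."""


@dataclass(frozen=True)
class WorkflowConfig:
    """All tunable thresholds of the curation workflow.

    Lengths are in angstroms, temperature in kelvin, the gas constant in
    kJ mol^-1 K^-1 so that ``gas_constant * temperature * ln(K)`` yields
    binding free energies in kJ/mol.
    """

    protein_assoc_cutoff: float = 10.0
    additive_cutoff: float = 4.0
    clash_cutoff: float = 2.0
    min_heavy_atoms: int = 4
    polymer_ligand_max_residues: int = 20   # exclusive
    polymer_ligand_min_residues: int = 2    # inclusive
    allowed_elements: frozenset = DEFAULT_ALLOWED_ELEMENTS
    missing_segment_max: int = 10
    ph: float = 7.4
    rotamer_angle_cutoff: float = 60.0
    max_valid_ki: float = 1.0e3
    temperature: float = 298.15
    gas_constant: float = 8.31446e-3
    # implementation constants (documented defaults, overridable)
    bond_perception_tolerance: float = 1.3
    planarity_tolerance_deg: float = 10.0
    disulfide_cutoff: float = 2.3
    minimize_max_iterations: int = 10000
    minimize_energy_tol: float = 10.0
    drop_waters: bool = False

    def __post_init__(self):
        for key in ("protein_assoc_cutoff", "additive_cutoff", "clash_cutoff"):
            if getattr(self, key) <= 0:
                raise ConfigValidationError(f"{key} must be > 0, got {getattr(self, key)}")
        if self.clash_cutoff >= self.protein_assoc_cutoff:
            raise ConfigValidationError(
                "clash_cutoff must be smaller than protein_assoc_cutoff")
        if self.polymer_ligand_min_residues < 2:
            raise ConfigValidationError("polymer_ligand_min_residues must be >= 2")
        if self.polymer_ligand_min_residues >= self.polymer_ligand_max_residues:
            raise ConfigValidationError(
                "polymer_ligand_min_residues must be < polymer_ligand_max_residues")
        elements = frozenset(self.allowed_elements)
        object.__setattr__(self, "allowed_elements", elements)
        if not {"C", "H"} <= elements:
            raise ConfigValidationError("allowed_elements must contain C and H")
        if self.min_heavy_atoms < 1:
            raise ConfigValidationError("min_heavy_atoms must be >= 1")
        if self.temperature <= 0 or self.gas_constant <= 0:
            raise ConfigValidationError("temperature and gas_constant must be > 0")

    def replace(self, **kwargs) -> "WorkflowConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allowed_elements"] = sorted(self.allowed_elements)
        return d


def serialize_config(cfg: WorkflowConfig) -> str:
    """Render a config as a flat YAML document."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> WorkflowConfig:
    """Load defaults, overlay a YAML file (if given), then keyword overrides.

    Raises :class:`ConfigError` for malformed documents or unknown keys and
    :class:`ConfigValidationError` when an invariant is violated.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} must be a flat key-value map")
        values.update(doc)
    values.update(overrides)

    known = {f.name for f in dataclasses.fields(WorkflowConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "allowed_elements" in values:
        values["allowed_elements"] = frozenset(values["allowed_elements"])
    for f in dataclasses.fields(WorkflowConfig):
        if f.name in values and f.type in ("float", "int"):
            v = values[f.name]
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ConfigError(f"config key {f.name} must be numeric, got {v!r}")
    cfg = WorkflowConfig(**values)
    logger.info("workflow configuration: %s", cfg.to_dict())
    return cfg
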