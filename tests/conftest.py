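import logging
from pathlib import Path

import pytest

from plcurate.config import WorkflowConfig
from plcurate.fixtures import FixtureSpec, default_suite, make_fixture
from plcurate.pipeline import run_entry
from plcurate.splitter import LigandSpec, extract_complex, identify_ligands
from plcurate.structure_io import parse_mmcif_header, parse_pdb

logging.getLogger("plcurate").setLevel(logging.ERROR)

BASE_SUBS = ((5, "LYS"), (9, "ASP"), (12, "HIS"), (16, "SER"))


@pytest.fixture(scope="session")
def cfg():
    return WorkflowConfig()


@pytest.fixture(scope="session")
def clean_bundle():
    """One defect-free synthetic complex, generated once per session."""
    return make_fixture(FixtureSpec(seed=42, substitutions=BASE_SUBS))


@pytest.fixture(scope="session")
def clean_structure(clean_bundle):
    return parse_pdb(clean_bundle.pdb_text, entry_id="FIX1")


@pytest.fixture(scope="session")
def clean_meta(clean_bundle):
    return parse_mmcif_header(clean_bundle.cif_text)


@pytest.fixture()
def clean_complex(clean_bundle, cfg):
    """Freshly extracted complex (mutable, so function-scoped)."""
    st = parse_pdb(clean_bundle.pdb_text, entry_id="FIX1")
    lig = identify_ligands(st, [LigandSpec(kind="ccd", ccd_code="LIG")], cfg)[0]
    return extract_complex(st, lig, cfg)


@pytest.fixture(scope="session")
def suite_results(tmp_path_factory):
    """The full default fixture suite run through the pipeline once."""
    root = tmp_path_factory.mktemp("suite")
    out = []
    for name, spec in default_suite(seed=7):
        fb = make_fixture(spec)
        entry_dir = fb.write(root / name)
        result = run_entry(entry_dir, out_dir=root / "curated", cfg=WorkflowConfig())
        out.append((name, fb, result))
    return out
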