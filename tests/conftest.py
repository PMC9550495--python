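from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"

TOY_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 20.00           C
HETATM    2  O   HOH W   1       4.000   5.000   6.000  1.00 30.00           O
HETATM    3  C1  LIG L   1       0.000   0.000   0.000  1.00 25.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path: Path) -> Path:
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture(scope="session")
def benchmark_combination_averages() -> pd.DataFrame:
    """Model-averaged metrics for the 63 feature combinations, as published
    for the full homolog-pair training corpus (fixture for internal-consistency
    and ranking-logic checks)."""
    return pd.read_csv(DATA_DIR / "combination_averages.tsv", sep="\t")


@pytest.fixture(scope="session")
def benchmark_model_metrics() -> pd.DataFrame:
    """Published per-family metrics on the full feature combination."""
    return pd.read_csv(DATA_DIR / "model_metrics.tsv", sep="\t")


@pytest.fixture(scope="session")
def homolog_pair():
    """One default planted homolog pair, shared across read-only tests."""
    from conswat.synthetic import StructureSimSpec, generate_homolog_pair

    return generate_homolog_pair(StructureSimSpec(seed=11))


@pytest.fixture(scope="session")
def small_feature_table() -> pd.DataFrame:
    from conswat.synthetic import FeatureSimSpec, generate_feature_table

    return generate_feature_table(FeatureSimSpec(n=400, seed=11))
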