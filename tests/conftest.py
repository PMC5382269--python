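"""Shared fixtures: annotation tables and small synthetic systems."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hydramem.io import ANNOTATION_COLUMNS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_annotation_table() -> pd.DataFrame:
    """Sidecar annotation rows for the synthetic HGL/SOL species."""
    rows = []
    for k in range(1, 9):
        rows.append(
            ("HGL", f"O{k}", "lipid", "by_z", "donor+acceptor", "", "-0.548", "0.310", "0.650")
        )
        rows.append(("HGL", f"HO{k}", "lipid", "by_z", "hydrogen", "-1", "0.408", "", ""))
    rows.append(
        ("SOL", "OW", "water", "", "donor+acceptor", "", "-0.8476", "0.3166", "0.650")
    )
    rows.append(("SOL", "HW1", "water", "", "hydrogen", "-1", "0.4238", "", ""))
    rows.append(("SOL", "HW2", "water", "", "hydrogen", "-2", "0.4238", "", ""))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


@pytest.fixture
def annotation_table() -> pd.DataFrame:
    return make_annotation_table()


@pytest.fixture
def annotation_file(tmp_path, annotation_table):
    path = tmp_path / "annotations.tsv"
    annotation_table.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
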