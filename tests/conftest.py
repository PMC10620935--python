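import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from midpipe.data_model import IsotopologueTable, MoleculeSpec, SampleMeta

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def molecules():
    return {
        "lac": MoleculeSpec("lac", 3),
        "pyr": MoleculeSpec("pyr", 3),
    }


def make_table(data: dict, samples: list[str], stage: str = "raw") -> IsotopologueTable:
    """Build a table from {(metabolite, shift): [values per sample]}."""
    idx = pd.MultiIndex.from_tuples(data.keys(), names=("metabolite", "shift"))
    values = pd.DataFrame(
        np.array(list(data.values()), dtype=float), index=idx, columns=samples
    ).sort_index()
    return IsotopologueTable(values=values, stage=stage)


def make_meta(rows: list[tuple]) -> SampleMeta:
    """rows: (sample_id, group, donor, batch, is_blank)."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "group", "donor", "batch", "is_blank"]
    ).set_index("sample_id")
    return SampleMeta(df)


@pytest.fixture
def simple_meta():
    return make_meta(
        [
            ("s1", "TN", "D1", "B1", False),
            ("s2", "TN", "D2", "B1", False),
            ("s3", "TSCM", "D1", "B1", False),
            ("s4", "TSCM", "D2", "B1", False),
            ("b1", "", "", "B1", True),
            ("b2", "", "", "B1", True),
            ("b3", "", "", "B1", True),
        ]
    )
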