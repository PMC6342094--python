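import numpy as np
import pandas as pd
import pytest

from cibias import IsolineDesign, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def small_design():
    """A fast 6-line assay used by most pipeline tests."""
    return IsolineDesign(n_lines=6, n_blocks=2, n_per_sex_per_block=4, seed=42)


@pytest.fixture
def small_records(small_design):
    return generate_dataset(small_design)


@pytest.fixture
def paper_like_design():
    """The standard 27-line x 3-block x 10-per-cell assay with two CI lines."""
    return IsolineDesign(ci_lines=("L26", "L27"), seed=7)


def make_records(values_by_cell):
    """Build a records frame from {(line, sex, block): [raw values]}."""
    rows = []
    for (line, sex, block), values in values_by_cell.items():
        for i, v in enumerate(values, start=1):
            rows.append(
                {
                    "line_id": line,
                    "sex": sex,
                    "block": block,
                    "individual": i,
                    "fitness_raw": float(v),
                }
            )
    return pd.DataFrame(rows)
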