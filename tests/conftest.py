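import numpy as np
import pytest

from combiscore import ResponseRecord, build_matrix


def matrix_from_grid(row_concs, col_concs, grid_pct, block_id="blk",
                     drug_row="d1", drug_col="d2", n_replicates=1):
    """DoseResponseMatrix from an explicit %-inhibition grid (rows x cols)."""
    records = []
    for i, cr in enumerate(row_concs):
        for j, cc in enumerate(col_concs):
            for rep in range(1, n_replicates + 1):
                records.append(ResponseRecord(
                    block_id=block_id, drug_row=drug_row, drug_col=drug_col,
                    conc_row=float(cr), conc_col=float(cc),
                    response=float(grid_pct[i][j]), replicate=rep))
    return build_matrix(records)


@pytest.fixture
def simple_grid_matrix():
    """3 doses + margins, additive-ish toy block."""
    concs = [0.0, 0.1, 1.0, 10.0]
    grid = np.array([
        [0.0, 10.0, 30.0, 50.0],
        [10.0, 20.0, 40.0, 60.0],
        [30.0, 40.0, 55.0, 70.0],
        [50.0, 60.0, 72.0, 85.0],
    ])
    return matrix_from_grid(concs, concs, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
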