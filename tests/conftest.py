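import numpy as np
import pytest
from scipy.spatial import cKDTree

from ctcquant import default_phenotypes


@pytest.fixture(scope="session")
def phenotypes():
    return default_phenotypes()


def match_by_centroid(truth, cells, max_dist=5.0):
    """Match truth cells to detected cells by nearest centroid.

    Returns (matched_truth_index, matched_cell_iloc, n_unmatched_truth,
    n_unmatched_cells).
    """
    if len(cells) == 0:
        return np.array([], int), np.array([], int), len(truth), 0
    tree = cKDTree(cells[["row", "col"]].to_numpy())
    d, idx = tree.query(truth[["row", "col"]].to_numpy())
    ok = d <= max_dist
    # guard against two truth cells claiming one detection
    used = set()
    t_idx, c_idx = [], []
    for ti in np.nonzero(ok)[0]:
        ci = int(idx[ti])
        if ci not in used:
            used.add(ci)
            t_idx.append(ti)
            c_idx.append(ci)
    n_missed = len(truth) - len(t_idx)
    n_extra = len(cells) - len(c_idx)
    return np.asarray(t_idx), np.asarray(c_idx), n_missed, n_extra
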