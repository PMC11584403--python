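"""TF motif deviation matrices with planted lineage shifts.

Emulates bias-corrected per-cell motif deviation scores: standard
Gaussian noise per (TF, cell), with planted TFs shifted by a stated
effect (in SD units) in stated cell groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_motif_matrix"]


def generate_motif_matrix(
    groups: dict[str, int],
    planted_shifts: dict[str, dict[str, float]],
    seed: int,
    n_tfs: int = 50,
) -> tuple[pd.DataFrame, pd.Series, dict[str, dict[str, float]]]:
    """Gaussian motif-score matrix with planted group shifts.

    Parameters
    ----------
    groups
        Cell group -> number of cells.
    planted_shifts
        TF name -> {group: shift}; TF names must be among the generated
        ``TF_###`` ids (the first ``n_tfs`` names).

    Returns ``(matrix, cell_groups, planted_shifts)`` where ``matrix`` is
    TFs x cells and ``cell_groups`` maps each cell to its group.
    """
    tf_names = [f"TF_{i + 1:03d}" for i in range(n_tfs)]
    unknown = set(planted_shifts) - set(tf_names)
    if unknown:
        raise ValueError(f"planted TFs not in the assay: {sorted(unknown)}")
    for tf, shifts in planted_shifts.items():
        bad = set(shifts) - set(groups)
        if bad:
            raise ValueError(f"planted shift for {tf!r} names unknown group(s) {sorted(bad)}")

    rng = np.random.default_rng(seed)
    cells: list[str] = []
    labels: list[str] = []
    for group, n in groups.items():
        for i in range(n):
            cells.append(f"{group}_c{i + 1:04d}")
            labels.append(group)
    matrix = pd.DataFrame(
        rng.normal(size=(n_tfs, len(cells))), index=tf_names, columns=cells
    )
    cell_groups = pd.Series(labels, index=cells, name="group")
    for tf, shifts in planted_shifts.items():
        for group, shift in shifts.items():
            matrix.loc[tf, cell_groups == group] += shift
    return matrix, cell_groups, planted_shifts
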