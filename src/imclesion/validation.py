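"""Ground-truth recovery metrics for synthetic scenes.

Matching convention: a segmented cell recovers a true cell when its
centroid lies within one nucleus radius of the true center; matches are
assigned greedily by increasing distance, one-to-one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_to_truth", "segmentation_scores", "classification_accuracy"]


def match_to_truth(
    truth_cells: pd.DataFrame,
    segmented_cells: pd.DataFrame,
    *,
    max_distance_px: float | None = None,
) -> pd.DataFrame:
    """One-to-one greedy matching of segmented to true cells.

    Returns the truth table with ``matched_cell_id`` (NaN when missed) and
    ``match_distance_px`` columns. ``max_distance_px`` defaults to each
    true cell's own nucleus radius.
    """
    ty = truth_cells["y_px"].to_numpy(float)
    tx = truth_cells["x_px"].to_numpy(float)
    sy = segmented_cells["y_px"].to_numpy(float)
    sx = segmented_cells["x_px"].to_numpy(float)
    if max_distance_px is None:
        limits = truth_cells["nucleus_radius_px"].to_numpy(float)
    else:
        limits = np.full(len(truth_cells), float(max_distance_px))

    d = np.hypot(ty[:, None] - sy[None, :], tx[:, None] - sx[None, :])
    pairs = [
        (d[i, j], i, j)
        for i in range(len(ty))
        for j in range(len(sy))
        if d[i, j] <= limits[i]
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_s: set[int] = set()
    match_id = np.full(len(ty), np.nan)
    match_d = np.full(len(ty), np.nan)
    seg_ids = segmented_cells["cell_id"].to_numpy()
    for dist, i, j in pairs:
        if i in used_t or j in used_s:
            continue
        used_t.add(i)
        used_s.add(j)
        match_id[i] = seg_ids[j]
        match_d[i] = dist
    out = truth_cells.copy()
    out["matched_cell_id"] = match_id
    out["match_distance_px"] = match_d
    return out


def segmentation_scores(
    truth_cells: pd.DataFrame, segmented_cells: pd.DataFrame
) -> tuple[float, float]:
    """(recall, precision) of nucleus detection against true centers."""
    matched = match_to_truth(truth_cells, segmented_cells)
    n_hit = int(matched["matched_cell_id"].notna().sum())
    recall = n_hit / len(truth_cells) if len(truth_cells) else 1.0
    precision = n_hit / len(segmented_cells) if len(segmented_cells) else 1.0
    return recall, precision


def classification_accuracy(
    truth_cells: pd.DataFrame, classified_cells: pd.DataFrame
) -> float:
    """Fraction of matched true cells whose assigned class is the true class."""
    matched = match_to_truth(truth_cells, classified_cells)
    matched = matched[matched["matched_cell_id"].notna()]
    if matched.empty:
        return 0.0
    lookup = classified_cells.set_index("cell_id")["cell_class"]
    assigned = lookup.loc[matched["matched_cell_id"].astype(int)].to_numpy()
    return float(np.mean(assigned == matched["true_class"].to_numpy()))
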