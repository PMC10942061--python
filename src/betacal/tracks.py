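"""Measure every cell at every frame by replicating the static mask.

With a single shared mask, cell linking degenerates to identity: each label
IS a track, so the track table is exactly one (mean intensity, area,
centroid) row per label per frame. Mean intensity is the unweighted mean
over the cell's ROI pixels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DimensionError, EmptyMaskError
from .io_stack import TRACK_COLUMNS, FrameStack
from .segment import LabelMask


def measure_tracks(stack: FrameStack, mask: LabelMask) -> pd.DataFrame:
    """Per-cell-per-frame measurements as a long-form table.

    Returns a DataFrame with columns TRACK_ID, FRAME, MEAN_INTENSITY, AREA,
    POSITION_X, POSITION_Y; exactly n_cells x n_frames rows, sorted by
    (TRACK_ID, FRAME). Area and centroid are frame-independent by
    construction (static mask); x is the column index, y the row index.
    """
    if stack.shape != mask.shape:
        raise DimensionError(
            f"stack frames {stack.shape} do not match mask {mask.shape}"
        )
    n = mask.n_cells
    if n == 0:
        raise EmptyMaskError("mask contains no cells")

    ids = np.arange(1, n + 1)
    areas = np.bincount(mask.labels.ravel(), minlength=n + 1)[1:]
    centroids = ndi.center_of_mass(np.ones(mask.shape), mask.labels, ids)
    ys = np.array([c[0] for c in centroids])
    xs = np.array([c[1] for c in centroids])

    rows = []
    for t in range(stack.n_frames):
        means = ndi.mean(stack.frames[t].astype(np.float64), mask.labels, ids)
        rows.append(
            pd.DataFrame(
                {
                    "TRACK_ID": ids,
                    "FRAME": t,
                    "MEAN_INTENSITY": means,
                    "AREA": areas,
                    "POSITION_X": xs,
                    "POSITION_Y": ys,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return (
        table[TRACK_COLUMNS]
        .sort_values(["TRACK_ID", "FRAME"], kind="stable")
        .reset_index(drop=True)
    )
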