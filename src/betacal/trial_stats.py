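"""Trial-level statistics: pooled-Z outlier removal, mean spiking activity,
paired pre/post testing, and spatial spike maps.

Outliers are whole tracks: the mean and standard deviation of ALL normalized
intensity values pooled across the trial are computed once, and any track
containing a value with |Z| above the cutoff (default 3.0) is removed. Mean
spiking activity is total spikes / (cells x imaging minutes), making trials
of different cell counts comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calcium_dynamics import NormalizedTrace, SpikeCall
from .errors import DegenerateDataError, InsufficientPairsError

@dataclass
class TrialSummary:
    """Per-trial results; ``condition`` (e.g. field strength in V/cm) is
    pass-through metadata only."""

    trial_id: str
    condition: str
    period: str  # "pre" or "post"
    n_cells_segmented: int
    n_cells_after_outliers: int
    n_spikes: int
    duration_min: float
    mean_activity: float
    active_track_ids: list[int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def remove_outliers(
    traces: list[NormalizedTrace], z_max: float = 3.0
) -> tuple[list[NormalizedTrace], list[int]]:
    """Drop whole tracks containing any pooled-Z outlier value.

    Z is computed per value against the mean and SD of all normalized values
    pooled across the given (valid) traces, once, before any removal — so a
    second application removes nothing. Zero pooled SD removes nothing.
    Invalid traces are excluded from pooling and from the output.
    """
    valid = [t for t in traces if t.valid]
    if not valid:
        return [], []
    pooled = np.concatenate([t.values for t in valid])
    mean, sd = pooled.mean(), pooled.std()
    if sd == 0:
        return valid, []
    kept, removed = [], []
    for t in valid:
        if np.any(np.abs((t.values - mean) / sd) > z_max):
            removed.append(t.track_id)
        else:
            kept.append(t)
    return kept, removed


def mean_activity(n_spikes: int, n_cells: int, duration_min: float) -> float:
    """Spikes per cell per minute for one trial."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    return n_spikes / (n_cells * duration_min)


def paired_ttest(pre, post) -> tuple[float, float, int]:
    """Two-tailed paired t-test on per-trial activities.

    Returns (t, two-sided p, df = m - 1) with t = mean(d) / (sd(d)/sqrt(m)),
    d = post - pre, sample SD (m - 1 denominator).
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape:
        raise InsufficientPairsError(
            f"pre has {pre.size} trials, post has {post.size}; must be paired"
        )
    m = pre.size
    if m < 2:
        raise InsufficientPairsError(f"need >= 2 pairs, got {m}")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, m - 1
        raise DegenerateDataError("zero-variance differences with nonzero mean")
    t = d.mean() / (sd / np.sqrt(m))
    p = 2.0 * stats.t.sf(abs(t), df=m - 1)
    return float(t), float(p), m - 1


def spike_map(
    table: pd.DataFrame, calls: list[SpikeCall], frame: int
) -> list[tuple[int, float, float]]:
    """(track_id, x, y) of every cell whose spike peaks at ``frame``.

    Drives the spatial visualization: only cells currently spiking appear.
    """
    n_frames = int(table["FRAME"].max()) + 1
    if not 0 <= frame < n_frames:
        raise IndexError(f"frame {frame} outside 0..{n_frames - 1}")
    centroids = (
        table.drop_duplicates("TRACK_ID")
        .set_index("TRACK_ID")[["POSITION_X", "POSITION_Y"]]
    )
    out = []
    for c in calls:
        if c.peak_frame == frame:
            x, y = centroids.loc[c.track_id]
            out.append((c.track_id, float(x), float(y)))
    return out
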