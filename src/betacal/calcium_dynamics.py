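"""Numerical core: background subtraction, baseline normalization, spike calls.

Background
    100 pixel locations (configurable) are drawn uniformly without
    replacement from outside every ROI; their per-frame mean is subtracted
    from each cell's mean intensity in that frame.

Normalization
    Dye loading varies between cells, so each background-subtracted trace is
    divided by a per-cell baseline: the mean of the first *n* points recorded
    before the trace first changes by >= 10% (relative, either direction)
    from its first value. A trace that never crosses uses its whole-trace
    mean. Normalized traces are unitless and hover around 1.

Spike determination
    A spike is a peak in the normalized trace reached either by a single
    frame-to-frame rise >= the threshold (rule ``single_step``) or by a
    cumulative rise >= the threshold summed from the preceding trough
    (rule ``cumulative``). Default threshold: 10%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, NoBackgroundError
from .io_stack import FrameStack
from .segment import LabelMask

logger = logging.getLogger(__name__)


@dataclass
class BackgroundSample:
    """Fixed set of background pixel coordinates and their per-frame mean."""

    pixel_coords: np.ndarray  # (n, 2) array of (row, col)
    per_frame_mean: np.ndarray  # length-T


@dataclass
class NormalizedTrace:
    """One cell's background-subtracted trace and its normalized form.

    ``values[t] * baseline == raw[t]`` when valid; ``valid`` is False iff the
    baseline is non-positive (background overwhelms signal), in which case
    the trace is excluded from spike analysis.
    """

    track_id: int
    raw: np.ndarray
    baseline: float
    baseline_n: int
    values: np.ndarray
    valid: bool


@dataclass
class SpikeCall:
    """One detected calcium spike."""

    track_id: int
    peak_frame: int
    rule: str  # "single_step" or "cumulative"
    magnitude_pct: float


def sample_background(
    stack: FrameStack, mask: LabelMask, n: int = 100, seed: int = 0
) -> BackgroundSample:
    """Draw ``n`` unique background coordinates and average them per frame.

    Coordinates are drawn uniformly without replacement from pixels whose
    mask label is 0, using a generator seeded with ``seed`` (deterministic).
    If fewer than ``n`` background pixels exist, all of them are used and a
    warning is logged.
    """
    bg_rows, bg_cols = np.nonzero(mask.labels == 0)
    n_avail = bg_rows.size
    if n_avail == 0:
        raise NoBackgroundError("mask has no background pixels to sample")
    if n_avail < n:
        logger.warning(
            "only %d background pixels available (requested %d); using all", n_avail, n
        )
        n = n_avail
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_avail, size=n, replace=False)
    coords = np.column_stack([bg_rows[idx], bg_cols[idx]])
    per_frame = stack.frames[:, coords[:, 0], coords[:, 1]].mean(axis=1)
    return BackgroundSample(coords, per_frame.astype(np.float64))


def subtract_background(table: pd.DataFrame, bg: BackgroundSample) -> pd.DataFrame:
    """Subtract the per-frame background mean from every cell's mean intensity.

    Returns a new table; other columns untouched. Results may be negative.
    """
    frames = table["FRAME"].to_numpy()
    if frames.min() < 0 or frames.max() >= bg.per_frame_mean.size:
        raise AlignmentError(
            f"background sample covers frames 0..{bg.per_frame_mean.size - 1}, "
            f"table has frames {frames.min()}..{frames.max()}"
        )
    out = table.copy()
    out["MEAN_INTENSITY"] = out["MEAN_INTENSITY"] - bg.per_frame_mean[frames]
    return out


def _baseline(raw: np.ndarray, threshold_pct: float) -> tuple[float, int]:
    """Baseline = mean of points before the first >=threshold relative change
    from the first point; whole-trace mean if no crossing (or first point 0)."""
    first = raw[0]
    if first != 0:
        rel = np.abs(raw[1:] - first) / abs(first)
        crossing = np.flatnonzero(rel >= threshold_pct / 100.0)
        if crossing.size:
            n = int(crossing[0]) + 1  # points strictly before the crossing
            return float(raw[:n].mean()), n
    return float(raw.mean()), raw.size


def normalize_traces(table: pd.DataFrame, threshold_pct: float = 10.0) -> list[NormalizedTrace]:
    """Per-cell baseline normalization of a background-subtracted track table."""
    traces = []
    for track_id, group in table.sort_values("FRAME").groupby("TRACK_ID"):
        raw = group["MEAN_INTENSITY"].to_numpy(dtype=np.float64)
        baseline, n = _baseline(raw, threshold_pct)
        valid = baseline > 0
        values = raw / baseline if valid else np.full_like(raw, np.nan)
        traces.append(NormalizedTrace(int(track_id), raw, baseline, n, values, valid))
    return traces


def _plateau_runs(v: np.ndarray):
    """Yield (start, end) of maximal runs of equal value (end inclusive)."""
    start = 0
    for i in range(1, v.size):
        if v[i] != v[start]:
            yield start, i - 1
            start = i
    yield start, v.size - 1


def find_peaks(v: np.ndarray) -> list[int]:
    """Peak indices: interior strict local maxima (plateaus report their first
    index), plus the final index when the trace ends rising."""
    peaks = []
    runs = list(_plateau_runs(v))
    for start, end in runs:
        if start > 0 and end < v.size - 1 and v[start] > v[start - 1] and v[end] > v[end + 1]:
            peaks.append(start)
    if v.size >= 2 and v[-1] > v[-2]:
        peaks.append(v.size - 1)
    return peaks


def find_minima(v: np.ndarray) -> list[int]:
    """Interior strict local minima, plateau-first-index (mirror of peaks)."""
    minima = []
    for start, end in _plateau_runs(v):
        if start > 0 and end < v.size - 1 and v[start] < v[start - 1] and v[end] < v[end + 1]:
            minima.append(start)
    return minima


def _pct_changes(v: np.ndarray) -> np.ndarray:
    """p[t] = 100 * (v[t] - v[t-1]) / v[t-1]; p[0] = 0 by convention."""
    p = np.zeros_like(v, dtype=np.float64)
    prev = v[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        p[1:] = 100.0 * (v[1:] - prev) / prev
    p[1:][prev == 0] = np.where(v[1:][prev == 0] > 0, np.inf, 0.0)
    return p


def detect_spikes(trace: NormalizedTrace, threshold_pct: float = 10.0) -> list[SpikeCall]:
    """Call spikes on one normalized trace.

    Each peak yields at most one call: the single-step rule is checked first;
    otherwise the cumulative rise from the preceding trough (or the trace
    start) must reach the threshold. Invalid traces are skipped with a log.
    """
    if not trace.valid:
        logger.info("track %d skipped: non-positive baseline", trace.track_id)
        return []
    v = trace.values
    if v.size < 2:
        return []
    p = _pct_changes(v)
    minima = find_minima(v)
    calls = []
    for t in find_peaks(v):
        if p[t] >= threshold_pct:
            calls.append(SpikeCall(trace.track_id, t, "single_step", float(p[t])))
            continue
        m = max((i for i in minima if i < t), default=0)
        cum = float(p[m + 1 : t + 1].sum())
        if cum >= threshold_pct:
            calls.append(SpikeCall(trace.track_id, t, "cumulative", cum))
    return calls


def active_cells(calls: list[SpikeCall]) -> set[int]:
    """Track ids with at least one spike during the imaging period."""
    return {c.track_id for c in calls}
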