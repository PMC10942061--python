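"""Produce one label mask from the composite image.

A single static mask serves every frame: the pipeline targets clustered,
non-migratory cells imaged over short spans with minimal movement, so the
mask is segmented once from the composite and replicated across the stack.

Two routes produce the mask:

* :func:`segment_fallback` — a deterministic, dependency-free algorithm
  (Gaussian smooth -> Otsu -> optional nuclear-seeded watershed -> area
  filter -> consecutive relabel);
* :func:`segment_external` — a thin adapter around a generalist model such
  as Cellpose, whose raw output is sanitized into the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import AdapterContractError, BackendUnavailableError, NoForegroundError
from .preprocess import CompositeImage


@dataclass
class LabelMask:
    """H x W integer image; 0 = background, cells labeled 1..n_cells consecutively."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if np.any(self.labels < 0):
            raise ValueError("negative labels")
        present = np.unique(self.labels)
        expected = np.arange(present.max(initial=0) + 1)
        if present.size and not np.array_equal(np.union1d(present, [0]), expected):
            raise ValueError("labels must be consecutive 0..n_cells")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class FallbackSegParams:
    """Parameters of the built-in deterministic segmenter."""

    smooth_sigma: float = 2.0
    min_cell_area_px: int = 50
    use_nuclear_seeds: bool = True

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.min_cell_area_px < 1:
            raise ValueError("min_cell_area_px must be >= 1")


def _relabel_row_major(labels: np.ndarray) -> np.ndarray:
    """Relabel consecutively 1..n in order of first-encountered pixel (row-major)."""
    flat = labels.ravel()
    # pd.unique preserves first-encounter order
    old = [int(v) for v in pd.unique(flat) if v != 0]
    lut = np.zeros(int(flat.max(initial=0)) + 1, dtype=np.int64)
    for new, o in enumerate(old, start=1):
        lut[o] = new
    return lut[labels]


def sanitize_labels(labels: np.ndarray, min_cell_area_px: int = 1) -> LabelMask:
    """Enforce the mask contract on an arbitrary non-negative integer image.

    Objects smaller than ``min_cell_area_px`` are zeroed; remaining labels are
    renumbered consecutively in row-major first-pixel order (deterministic).
    """
    labels = np.asarray(labels).astype(np.int64).copy()
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_cell_area_px)
    if small.size:
        labels[np.isin(labels, small[small > 0])] = 0
    return LabelMask(_relabel_row_major(labels))


def segment_fallback(
    composite: CompositeImage, params: FallbackSegParams | None = None
) -> LabelMask:
    """Deterministic built-in segmentation of the composite.

    Gaussian-smooths the cell channel, takes a global Otsu threshold for
    foreground, then either labels connected components (8-connectivity) or —
    when nuclear seeds are enabled and a nuclear channel is present — splits
    the foreground by watershed on the inverted smoothed image seeded at
    Otsu-thresholded nuclei. Objects below the minimum area are removed and
    survivors relabeled consecutively.
    """
    params = params or FallbackSegParams()
    img = composite.cell_channel.astype(np.float64)
    if np.ptp(img) == 0:
        raise NoForegroundError("constant cell channel: Otsu threshold undefined")
    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    foreground = smoothed > threshold_otsu(smoothed)
    if not foreground.any():
        raise NoForegroundError("no pixels above the Otsu threshold")

    if params.use_nuclear_seeds and composite.nuclear_channel is not None:
        nuc = composite.nuclear_channel.astype(np.float64)
        if np.ptp(nuc) == 0:
            raise NoForegroundError("constant nuclear channel: cannot derive seeds")
        seeds = cc_label(nuc > threshold_otsu(nuc), connectivity=2)
        labels = watershed(-smoothed, markers=seeds, mask=foreground)
    else:
        labels = cc_label(foreground, connectivity=2)
    return sanitize_labels(labels, params.min_cell_area_px)


def segment_external(
    composite: CompositeImage,
    backend: Callable[[CompositeImage], np.ndarray],
    min_cell_area_px: int = 50,
) -> LabelMask:
    """Run a pluggable segmentation backend and sanitize its output.

    ``backend`` receives the composite and must return an H x W integer array.
    Anything else is an adapter-contract violation.
    """
    raw = backend(composite)
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape != composite.shape:
        raise AdapterContractError(
            f"backend returned shape {raw.shape}, expected {composite.shape}"
        )
    if not np.issubdtype(raw.dtype, np.integer):
        if not np.allclose(raw, np.round(raw)):
            raise AdapterContractError("backend returned non-integer labels")
        raw = np.round(raw).astype(np.int64)
    if np.any(raw < 0):
        raise AdapterContractError("backend returned negative labels")
    return sanitize_labels(raw, min_cell_area_px)


def cellpose_backend(**cellpose_kwargs) -> Callable[[CompositeImage], np.ndarray]:
    """Adapter factory for the optional Cellpose backend.

    Model choice, diameter and thresholds are passed through unchanged; this
    package claims no defaults for them. Raises an actionable error when the
    optional dependency is absent.
    """
    try:
        from cellpose import models  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise BackendUnavailableError(
            "the 'cellpose' backend requires the optional dependency cellpose; "
            "install it with `pip install cellpose` or use --backend fallback"
        ) from exc

    model = models.Cellpose(model_type=cellpose_kwargs.pop("model_type", "cyto"))

    def _run(composite: CompositeImage) -> np.ndarray:  # pragma: no cover
        if composite.nuclear_channel is not None:
            img = np.stack([composite.cell_channel, composite.nuclear_channel])
            channels = [1, 2]
        else:
            img = composite.cell_channel
            channels = [0, 0]
        masks = model.eval(img, channels=channels, **cellpose_kwargs)[0]
        return np.asarray(masks)

    return _run
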