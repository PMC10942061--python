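"""Reading/writing the formats the pipeline touches, and run configuration.

Stacks and masks are plain grayscale TIFF (8/16-bit or float, single- or
multi-page); track tables are CSV with TrackMate-style column names. Native
microscope formats (ND2 etc.) are out of scope: convert to TIFF upstream.

Conventions fixed here and used everywhere else:

* coordinates are pixel units, ``x`` = column index, ``y`` = row index, 0-based;
* a centroid is the unweighted mean of member-pixel coordinates;
* ``FRAME`` is 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DepthOverflowError, UnsupportedFormatError

#: Column order of the track-table CSV.
TRACK_COLUMNS = ["TRACK_ID", "FRAME", "MEAN_INTENSITY", "AREA", "POSITION_X", "POSITION_Y"]


@dataclass
class FrameStack:
    """A T x H x W fluorescence movie.

    Intensities are arbitrary fluorescence units, non-negative, typically
    integer-valued as acquired. ``frame_interval_s`` is the acquisition
    interval (default 5 s, i.e. 25 frames span 2 minutes).
    """

    frames: np.ndarray
    frame_interval_s: float = 5.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.size == 0:
            raise ValueError("empty stack")
        if np.any(self.frames < 0):
            raise ValueError("negative intensities in stack")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape of one frame."""
        return self.frames.shape[1:]

    @property
    def duration_min(self) -> float:
        """Imaging span in minutes: (T - 1) intervals."""
        return (self.n_frames - 1) * self.frame_interval_s / 60.0


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Defaults follow the analysis procedure this package implements: a 10%
    relative-change spike threshold, 100 randomly sampled background pixels,
    and |Z| > 3 outlier removal on pooled normalized intensities.
    """

    spike_threshold_pct: float = 10.0
    n_background_pixels: int = 100
    z_max: float = 3.0
    rng_seed: int = 0
    min_cell_area_px: int = 50
    segmentation_backend: str = "fallback"
    frame_interval_s: float = 5.0
    smooth_sigma: float = 2.0
    use_nuclear_seeds: bool = True

    def __post_init__(self) -> None:
        if self.spike_threshold_pct <= 0:
            raise ValueError("spike_threshold_pct must be > 0")
        if self.n_background_pixels < 1:
            raise ValueError("n_background_pixels must be >= 1")
        if self.z_max <= 0:
            raise ValueError("z_max must be > 0")
        if self.min_cell_area_px < 1:
            raise ValueError("min_cell_area_px must be >= 1")
        if self.segmentation_backend not in ("fallback", "external"):
            raise ValueError("segmentation_backend must be 'fallback' or 'external'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_stack(path: str | Path, frame_interval_s: float = 5.0) -> FrameStack:
    """Read a single- or multi-page grayscale TIFF as a :class:`FrameStack`.

    Pixel values are preserved bit-exactly. RGB / multi-sample pages are
    rejected with an error naming the offending page.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                if page.samplesperpixel != 1:
                    raise UnsupportedFormatError(
                        f"{path}: page {i} has {page.samplesperpixel} samples per "
                        "pixel; only grayscale TIFF is supported"
                    )
            frames = tif.asarray()
    except UnsupportedFormatError:
        raise
    except (tifffile.TiffFileError, ValueError) as exc:
        raise UnsupportedFormatError(f"{path}: not a readable TIFF ({exc})") from exc
    return FrameStack(frames, frame_interval_s=frame_interval_s)


def write_stack(stack: FrameStack | np.ndarray, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF, one page per frame."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    tifffile.imwrite(path, frames, photometric="minisblack")


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask as a 16-bit single-page TIFF, values exact."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise DepthOverflowError(
            f"max label {labels.max()} exceeds 16-bit depth ({np.iinfo(np.uint16).max})"
        )
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a label mask written by :func:`write_label_mask`."""
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise UnsupportedFormatError(f"{path}: mask must be a single 2-D page")
    return labels.astype(np.int64)


def write_track_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as CSV, one row per (track, frame).

    Rows are sorted by (TRACK_ID, FRAME). Refuses to write an empty table.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty track table")
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    out = table[TRACK_COLUMNS].sort_values(["TRACK_ID", "FRAME"], kind="stable")
    out.to_csv(path, index=False)


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read a track-table CSV back into a DataFrame."""
    table = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table
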