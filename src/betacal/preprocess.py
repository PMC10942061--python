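"""Build the segmentation input: a maximum-value composite of the movie,
optionally merged with a nuclear-stain channel.

Calcium indicators oscillate, so any single frame can miss dark cells; the
pixelwise maximum over time shows every cell at its brightest and is what the
segmenter sees. A DAPI/NucBlue nuclear image (a single user-supplied frame)
can be carried as a second channel to help split touching cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError
from .io_stack import FrameStack


@dataclass
class CompositeImage:
    """Segmentation input: cell channel (max over frames) + optional nuclei."""

    cell_channel: np.ndarray
    nuclear_channel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_channel = np.asarray(self.cell_channel)
        if self.cell_channel.ndim != 2:
            raise DimensionError(f"cell channel must be 2-D, got {self.cell_channel.shape}")
        if self.nuclear_channel is not None:
            self.nuclear_channel = np.asarray(self.nuclear_channel)
            if self.nuclear_channel.shape != self.cell_channel.shape:
                raise DimensionError(
                    f"channel shapes differ: cell {self.cell_channel.shape} vs "
                    f"nuclear {self.nuclear_channel.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_channel.shape


def max_composite(stack: FrameStack) -> CompositeImage:
    """Pixelwise maximum over frames; same dtype and shape as one frame."""
    return CompositeImage(stack.frames.max(axis=0))


def merge_channels(cell_img: np.ndarray, nuclear_img: np.ndarray) -> CompositeImage:
    """Attach a nuclear channel to a cell-channel image; values untouched."""
    cell_img = np.asarray(cell_img)
    nuclear_img = np.asarray(nuclear_img)
    if cell_img.shape != nuclear_img.shape:
        raise DimensionError(
            f"cannot merge shapes {cell_img.shape} and {nuclear_img.shape}"
        )
    return CompositeImage(cell_img, nuclear_img)
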