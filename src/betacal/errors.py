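"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`BetacalError` so the CLI can report
the failing stage with a remediation hint instead of a bare traceback.
"""


class BetacalError(Exception):
    """Base class for all pipeline errors."""


class UnsupportedFormatError(BetacalError):
    """Input file is not a grayscale single/multi-page TIFF."""


class DepthOverflowError(BetacalError):
    """Label values do not fit the 16-bit mask pixel depth."""


class DimensionError(BetacalError):
    """Array shapes that must agree do not."""


class NoForegroundError(BetacalError):
    """Segmentation input has no detectable foreground (e.g. constant image)."""


class AdapterContractError(BetacalError):
    """An external segmentation backend violated the adapter contract."""


class BackendUnavailableError(BetacalError):
    """The requested optional segmentation backend is not installed."""


class EmptyMaskError(BetacalError):
    """A label mask with zero cells was passed where cells are required."""


class NoBackgroundError(BetacalError):
    """The mask leaves no background pixels to sample."""


class AlignmentError(BetacalError):
    """Background sample does not cover every frame of the track table."""


class InsufficientPairsError(BetacalError):
    """Fewer than two paired trials; a paired t-test is undefined."""


class DegenerateDataError(BetacalError):
    """Zero-variance differences with nonzero mean; t statistic undefined."""


class PlacementError(BetacalError):
    """Synthetic cell placement infeasible; use fewer or smaller cells."""


class PairingError(BetacalError):
    """Pre/post trial summaries cannot be paired one-to-one."""
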