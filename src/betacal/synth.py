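"""Ground-truthed synthetic calcium movies.

The generator emulates the statistical structure the pipeline assumes: static
clustered disk-like cells on a jittered grid, a per-cell lognormal dye-loading
factor L_c, transient multiplicative calcium spikes, a constant additive
background offset with optional Gaussian read noise and Poisson shot noise,
and a nuclear channel of smaller concentric disks.

The noise-free value of a pixel belonging to cell c at frame t is

    L_c * B * (1 + A * g(t)) + b

where B is the baseline intensity, b the background offset, A the spike
amplitude as a fraction of the loaded baseline, and g the spike kernel:
g = 1 at the peak frame, exponential decay over the following k frames
(time constant k/3), and 0 elsewhere. Background pixels have expectation b.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PlacementError
from .io_stack import FrameStack
from .segment import LabelMask, segment_fallback


@dataclass(frozen=True)
class SpikeEvent:
    """One scheduled spike: which cell (1-based label), when, how big."""

    cell: int
    peak_frame: int
    amplitude: float  # fraction of the loaded baseline, > 0
    decay_frames: int = 3


@dataclass
class SynthParams:
    """Knobs of the synthetic movie; defaults mirror the acquisition geometry
    the pipeline targets (25 frames at 5 s) at desk-scale image size."""

    image_size: tuple[int, int] = (256, 256)
    n_cells: int = 20
    cell_radius_px: tuple[float, float] = (6.0, 9.0)
    nucleus_radius_px: tuple[float, float] = (2.0, 4.0)
    dye_factor_sd: float = 0.3  # lognormal sigma of L_c
    baseline_intensity: float = 500.0  # B
    background_offset: float = 100.0  # b
    read_noise_sd: float = 0.0  # Gaussian sigma, fluorescence units
    shot_noise: bool = False
    n_frames: int = 25
    frame_interval_s: float = 5.0
    spike_schedule: tuple[SpikeEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_px[1] >= self.cell_radius_px[0]:
            raise ValueError("nucleus radius range must sit below cell radius range")
        for ev in self.spike_schedule:
            if ev.amplitude <= 0:
                raise ValueError(f"spike amplitude must be > 0: {ev}")
            if not 0 <= ev.peak_frame < self.n_frames:
                raise ValueError(f"peak frame out of range: {ev}")
            if not 1 <= ev.cell <= self.n_cells:
                raise ValueError(f"cell label out of range: {ev}")


@dataclass
class SynthGroundTruth:
    """Everything a recovery test needs to score the pipeline."""

    true_mask: LabelMask
    centers: np.ndarray  # (n, 2) row, col
    radii: np.ndarray  # (n,)
    dye_factors: np.ndarray  # (n,) L_c
    noise_free_traces: np.ndarray  # (n, T) analytic cell-pixel value
    spike_schedule: tuple[SpikeEvent, ...]
    background_offset: float


def _place_cells(params: SynthParams, rng: np.random.Generator):
    """Jittered-grid placement; no two centers closer than the radius sum."""
    h, w = params.image_size
    rmin, rmax = params.cell_radius_px
    g = int(np.ceil(np.sqrt(params.n_cells)))
    if g == 0:
        raise PlacementError("n_cells must be >= 1")
    sy, sx = h / g, w / g
    slots = [(i, j) for i in range(g) for j in range(g)][: params.n_cells]
    centers, radii = [], []
    for i, j in slots:
        for _ in range(200):
            r = rng.uniform(rmin, rmax)
            cy = (i + 0.5) * sy + rng.uniform(-sy / 4, sy / 4)
            cx = (j + 0.5) * sx + rng.uniform(-sx / 4, sx / 4)
            if not (r + 1 <= cy <= h - r - 1 and r + 1 <= cx <= w - r - 1):
                continue
            if all(np.hypot(cy - oy, cx - ox) > r + orr for (oy, ox), orr in zip(centers, radii)):
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers) + 1} of {params.n_cells}; "
                "use fewer or smaller cells or a larger image"
            )
    return np.array(centers), np.array(radii)


def _render_disks(shape, centers, radii) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int64)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = k
    return labels


def _spike_kernel(params: SynthParams) -> np.ndarray:
    """(n_cells, T) array of A * g(t) summed contributions per cell."""
    amp = np.zeros((params.n_cells, params.n_frames))
    for ev in params.spike_schedule:
        g = np.zeros(params.n_frames)
        g[ev.peak_frame] = 1.0
        if ev.decay_frames > 0:
            tau = ev.decay_frames / 3.0
            for j in range(1, ev.decay_frames + 1):
                if ev.peak_frame + j < params.n_frames:
                    g[ev.peak_frame + j] = np.exp(-j / tau)
        amp[ev.cell - 1] = np.maximum(amp[ev.cell - 1], ev.amplitude * g)
    return amp


def generate_movie(params: SynthParams) -> tuple[FrameStack, np.ndarray, SynthGroundTruth]:
    """Render one movie: cell-channel stack, nuclear image, ground truth."""
    rng = np.random.default_rng(params.seed)
    centers, radii = _place_cells(params, rng)
    labels = _render_disks(params.image_size, centers, radii)

    # nucleus radius scales with its cell's radius within the stated range
    nr_min, nr_max = params.nucleus_radius_px
    r_min, r_max = params.cell_radius_px
    frac = (radii - r_min) / (r_max - r_min) if r_max > r_min else np.zeros_like(radii)
    nuc_radii = nr_min + frac * (nr_max - nr_min)
    nuclear = np.where(_render_disks(params.image_size, centers, nuc_radii) > 0, 200.0, 10.0)

    L = np.exp(rng.normal(0.0, params.dye_factor_sd, size=params.n_cells))
    amp = _spike_kernel(params)  # (n, T)
    # analytic cell-pixel value per cell per frame
    traces = L[:, None] * params.baseline_intensity * (1.0 + amp) + params.background_offset

    b = params.background_offset
    lut = np.zeros((params.n_frames, params.n_cells + 1))
    lut[:, 1:] = (traces - b).T  # cell contribution above background
    frames = b + lut[:, labels]  # (T, H, W) via label lookup

    if params.shot_noise:
        frames = rng.poisson(frames).astype(np.float64)
    if params.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, params.read_noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    truth = SynthGroundTruth(
        true_mask=LabelMask(labels),
        centers=centers,
        radii=radii,
        dye_factors=L,
        noise_free_traces=traces,
        spike_schedule=params.spike_schedule,
        background_offset=b,
    )
    return FrameStack(frames, frame_interval_s=params.frame_interval_s), nuclear, truth


# --- benchmark suite -------------------------------------------------------

BENCHMARK_AMPLITUDES = (0.05, 0.10, 0.15, 0.20, 0.50)
BENCHMARK_NOISE_FRACTIONS = (0.0, 0.01, 0.02)  # read-noise sigma / baseline B


@dataclass
class BenchmarkCase:
    amplitude: float
    noise_fraction: float
    params: SynthParams
    stack: FrameStack
    nuclear: np.ndarray
    truth: SynthGroundTruth


def benchmark_suite(seed: int = 0) -> list[BenchmarkCase]:
    """Fixed 5 x 3 grid of movies: spike amplitudes {5,10,15,20,50}% crossed
    with read-noise levels {0,1,2}% of baseline; 20 cells each, 12 of them
    scheduled to spike once, deterministic per seed."""
    cases = []
    for i, a in enumerate(BENCHMARK_AMPLITUDES):
        for j, nf in enumerate(BENCHMARK_NOISE_FRACTIONS):
            sub = (seed * 97 + i * 13 + j) % (2**31)
            sched_rng = np.random.default_rng(sub + 1)
            spikers = sched_rng.choice(20, size=12, replace=False) + 1
            frames = sched_rng.integers(5, 20, size=12)
            schedule = tuple(
                SpikeEvent(int(c), int(f), a) for c, f in zip(spikers, frames)
            )
            params = SynthParams(
                read_noise_sd=nf * 500.0,
                spike_schedule=schedule,
                seed=sub,
            )
            stack, nuclear, truth = generate_movie(params)
            cases.append(BenchmarkCase(a, nf, params, stack, nuclear, truth))
    return cases


# --- scoring helpers -------------------------------------------------------

def evaluate_case(
    case: BenchmarkCase, threshold_pct: float = 10.0, n_bg: int = 100, bg_seed: int = 0
) -> tuple[float, float, int, int]:
    """Run the trace-analysis pipeline on one benchmark movie and score it.

    Composite -> nuclear-seeded fallback segmentation -> track measurement ->
    background subtraction -> normalization -> spike detection, then greedy
    matching of detections against the scheduled spikes (cells matched to
    ground truth by mask overlap). Returns (recall, precision, n_matched,
    n_detected).
    """
    from . import calcium_dynamics as cad
    from . import preprocess, tracks

    composite = preprocess.merge_channels(
        preprocess.max_composite(case.stack).cell_channel, case.nuclear
    )
    mask = segment_fallback(composite)
    table = tracks.measure_tracks(case.stack, mask)
    bg = cad.sample_background(case.stack, mask, n_bg, bg_seed)
    traces = cad.normalize_traces(cad.subtract_background(table, bg), threshold_pct)
    calls = [s for t in traces for s in cad.detect_spikes(t, threshold_pct)]
    mapping = match_labels(mask, case.truth.true_mask)
    return score_spike_recovery(calls, mapping, case.truth.spike_schedule)


def match_labels(pred: LabelMask, true: LabelMask) -> dict[int, int]:
    """Map each predicted label to the true label it overlaps most (IoU > 0.5
    required); unmatched predictions are absent from the mapping."""
    mapping: dict[int, int] = {}
    for p in range(1, pred.n_cells + 1):
        sel = pred.labels == p
        overlap = np.bincount(true.labels[sel], minlength=true.n_cells + 1)
        overlap[0] = 0
        t = int(overlap.argmax())
        if t == 0:
            continue
        inter = overlap[t]
        union = sel.sum() + (true.labels == t).sum() - inter
        if inter / union > 0.5:
            mapping[p] = t
    return mapping


def score_spike_recovery(
    calls, mapping: dict[int, int], schedule, frame_tol: int = 1
) -> tuple[float, float, int, int]:
    """Greedy one-to-one matching of detected vs scheduled spikes.

    A detection matches a scheduled event when its track maps to the event's
    cell and its peak frame is within ``frame_tol``. Returns
    (recall, precision, n_matched, n_detected); recall/precision are 1.0
    when their denominator is zero.
    """
    remaining = list(schedule)
    matched = 0
    for c in calls:
        cell = mapping.get(c.track_id)
        hit = next(
            (ev for ev in remaining if ev.cell == cell and abs(ev.peak_frame - c.peak_frame) <= frame_tol),
            None,
        )
        if hit is not None:
            remaining.remove(hit)
            matched += 1
    n_sched, n_det = len(schedule), len(calls)
    recall = matched / n_sched if n_sched else 1.0
    precision = matched / n_det if n_det else 1.0
    return recall, precision, matched, n_det
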