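# Methods

## Data model and conventions

A trial period is a T×H×W movie (default 25 frames at 5 s, i.e. a 2 min
span = (T−1)·Δt) in arbitrary fluorescence units. All coordinates are pixel
units, x = column, y = row, 0-based; centroids are unweighted means of
member-pixel coordinates; the `FRAME` column is 0-based. These conventions
are fixed so that CSV artifacts are byte-reproducible.

## Static-mask tracking

The pipeline assumes clustered, non-migratory cells with minimal stage
drift. Segmentation therefore runs once, on the maximum-value composite of
the movie, and the resulting label mask is replicated over every frame.
Under a shared mask, track linking is the identity — each label is a track —
so no motion model, gap closing or split/merge handling exists anywhere in
the pipeline. Movies with visible cell movement are outside the model.

## Built-in segmentation

The fallback segmenter is deliberately simple and fully deterministic:
Gaussian smoothing (σ = 2 px default) → global Otsu threshold → either
8-connected component labeling or, when a nuclear channel is supplied,
watershed on the inverted smoothed image seeded at Otsu-thresholded
nuclear components → removal of objects below `min_cell_area_px`
(default 50) → consecutive relabeling in row-major first-pixel order (the
tie-break that makes golden tests possible). An external generalist model
(Cellpose) can replace it behind an adapter that sanitizes arbitrary label
images into the same contract; model, diameter and thresholds are passed
through without claimed defaults.

Known limitation: a *global* Otsu threshold erodes dim cells when per-cell
brightness varies strongly. With a lognormal dye spread of σ = 0.3 the
per-cell IoU against ground truth can fall to ~0.7 for the dimmest cells
while cell counts stay exact. The geometry-recovery tests therefore use
uniform-intensity noiseless disks (where IoU ≥ 0.93 across seeds); trace
and spike recovery, which are insensitive to moderate boundary erosion,
are tested under full dye heterogeneity.

## Background subtraction

`n = 100` pixel locations (default) are drawn uniformly without replacement
from mask-background pixels with a seeded generator; one fixed coordinate
set serves all frames. The per-frame mean over those pixels is subtracted
from every cell's mean intensity in that frame. Subtracted intensities may
be negative; a cell whose resulting baseline is ≤ 0 is flagged invalid and
excluded from spike analysis rather than silently clamped. With constant
offset b and read noise σ the estimator error is O(σ/√n); tests assert a
4σ/√n per-frame bound and exactness at σ = 0.

## Baseline normalization

For each cell the first index t* ≥ 2 (1-based) with
|raw(t*) − raw(1)| / |raw(1)| ≥ 10 % defines the baseline window: the mean
of the first t* − 1 points. The crossing test counts changes in either
direction, and the crossing point itself is excluded from the window (t* = 2
means the first point alone is the baseline). A trace that never crosses —
or whose first value is 0, making the relative test undefined — uses its
whole-trace mean. Normalized values are raw/baseline, hence unitless and
scale-invariant: multiplying a trace by any c > 0 changes neither its
normalized values nor its spike calls (property-tested).

## Spike determination

Percent change p(t) = 100·(v(t) − v(t−1))/v(t−1) on the normalized trace.
A *peak* is an interior index strictly above both neighbours, with plateaus
reporting their first index, plus the final index when the trace ends
rising (the minimal definition consistent with marked example peaks; the
final-frame case is a judgment call documented here). Each peak yields at
most one spike:

* **single_step** — p(t) ≥ θ (checked first);
* **cumulative** — Σ p(s) ≥ θ, summed from just after the preceding strict
  local minimum (or the trace start) to the peak. Summing from the trough
  rather than literally "between two peaks" avoids cancelling the
  intervening descent and captures slow multi-frame rises; the window
  resets at every local minimum.

θ defaults to 10 %. Raising θ never increases the call count
(property-tested), and the implementation is checked for exact agreement
with an independent brute-force enumerator over 1000 random traces. Exactly
at-threshold steps (e.g. a synthetic amplitude of precisely 10 %) sit on a
floating-point knife edge and are not relied on by any test.

## Outlier removal and trial statistics

Z-scores are computed per value against the mean and population SD of all
normalized values pooled across the trial, once, before any removal; any
track containing |Z| > 3 is removed whole. Zero pooled SD removes nothing.
The choice to pool *normalized* values (rather than raw or
background-subtracted) follows the pipeline ordering: normalization
precedes statistics.

An interaction worth knowing: on synthetic movies whose only variance is
the spikes themselves, a solitary spike is always ≈ 4.3 pooled SD
regardless of amplitude, so sparse clean spikers are removed wholesale.
Real recordings (and the end-to-end fixtures here) have oscillating cells —
several transients per trace — which keeps spiking values within the
|Z| ≤ 3 band. The default synthetic trial therefore schedules three
well-separated transients per cell.

Mean spiking activity = spikes / (cells × minutes), with duration
(T−1)·Δt/60 — 25 frames at 5 s span exactly 2 min — making units
spikes·cell⁻¹·min⁻¹ and trials of different sizes comparable. Pre/post
trials are paired by trial id; the two-tailed paired t-test uses the
textbook statistic t = mean(d)/(sd(d)/√m) with sample SD and m−1 degrees of
freedom (cross-checked against `scipy.stats.ttest_rel`). Identical pairs
return t = 0, p = 1; zero-variance nonzero differences are an error rather
than ±∞. No multiple-testing correction is applied: conditions are reported
per-condition, as collected.

## Synthetic movies

The generator renders disk-shaped cells on a jittered grid (no two centers
closer than the sum of radii; bounded retries, then a placement error),
each with a concentric nuclear disk and a lognormal dye factor L_c
(σ = 0.3 default — roughly a 2-fold loading spread, a realistic dye-uptake
variation for clustered cells). A cell pixel at frame t is

    L_c · B · (1 + A · g(t)) + b

with baseline B = 500, background offset b = 100, spike amplitude A as a
fraction of the loaded baseline, and kernel g = 1 at the peak, exponential
decay (time constant k/3) over k = 3 following frames, 0 elsewhere. Spikes
are multiplicative on the loaded baseline, matching the fractional-change
detection logic; an additive mode is deliberately omitted. Read noise is
Gaussian (truncated at 0), shot noise optionally Poisson with the
noise-free mean — the standard fluorescence-camera model with minimal
parameters. Frames are float64 in memory so noise-free fixtures are exact
to machine precision; the CLI writer rounds to uint16.

What the generator does **not** emulate: cell migration or division, focus
drift, photobleaching, spatially structured background, irregular cell
shapes. Passing recovery tests therefore demonstrate correctness of the
measurement and detection logic under the stated model, not robustness to
those real-data effects.

### Benchmark

`benchmark_suite(seed)` builds a 5×3 grid — amplitudes {5, 10, 15, 20, 50} %
× read-noise {0, 1, 2} % of B — of 256×256×25 movies with 20 cells, 12 of
which spike once at seeded frames. The image is 1/64 the pixel area of the
original 2048² acquisitions so the whole grid runs in seconds on one CPU.
Scoring maps predicted to true cells by mask overlap (IoU > 0.5) and
matches detections to scheduled spikes greedily within ±1 frame. Measured
at default settings: recall and precision ≥ 0.97 pooled over the
amplitude ≥ 20 %, noise ≤ 2 % slice, and zero detections at 5 % amplitude
without noise (below threshold by construction).

## Numerical choices

* Division-by-zero in percent change (previous value 0) maps to +∞ for a
  rise and 0 otherwise; such traces are pathological after normalization
  and effectively only arise in hand-built inputs.
* Thresholds use ≥ comparisons exactly as stated; no epsilon is added.
* All randomness (background sampling, synthetic rendering) flows from
  explicit integer seeds via `numpy.random.default_rng`; a run's seed is
  echoed in `summary.json`, and two runs with the same inputs and seed
  produce byte-identical CSV artifacts.
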