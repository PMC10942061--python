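"""End-to-end orchestration: read -> composite -> (merge) -> segment ->
measure -> background -> normalize -> outliers -> spikes -> summary.

Pre- and post-stimulation periods are separate runs joined afterwards by
:func:`compare_periods`. Every run writes a self-describing ``summary.json``
(full effective config including the seed) so it can be reproduced from the
summary alone given the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium_dynamics as cad
from . import io_stack, preprocess, segment, tracks, trial_stats
from .errors import PairingError

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory artifacts of one run."""

    composite: preprocess.CompositeImage
    mask: segment.LabelMask
    table: pd.DataFrame  # raw measurements
    bg: cad.BackgroundSample
    bg_table: pd.DataFrame  # background-subtracted
    traces: list[cad.NormalizedTrace]
    kept: list[cad.NormalizedTrace]
    removed_track_ids: list[int]
    calls: list[cad.SpikeCall]
    summary: trial_stats.TrialSummary


def run_on_arrays(
    stack: io_stack.FrameStack,
    config: io_stack.RunConfig,
    nuclear: np.ndarray | None = None,
    mask: segment.LabelMask | None = None,
    trial_id: str = "trial",
    condition: str = "",
    period: str = "pre",
    backend=None,
) -> PipelineResult:
    """Run the full analysis on in-memory arrays; library entry point."""
    composite = preprocess.max_composite(stack)
    if nuclear is not None:
        composite = preprocess.merge_channels(composite.cell_channel, nuclear)

    if mask is None:
        if config.segmentation_backend == "external":
            if backend is None:
                backend = segment.cellpose_backend()
            mask = segment.segment_external(composite, backend, config.min_cell_area_px)
        else:
            mask = segment.segment_fallback(
                composite,
                segment.FallbackSegParams(
                    smooth_sigma=config.smooth_sigma,
                    min_cell_area_px=config.min_cell_area_px,
                    use_nuclear_seeds=config.use_nuclear_seeds,
                ),
            )
    logger.info("segmented %d cells", mask.n_cells)

    table = tracks.measure_tracks(stack, mask)
    bg = cad.sample_background(stack, mask, config.n_background_pixels, config.rng_seed)
    bg_table = cad.subtract_background(table, bg)
    traces = cad.normalize_traces(bg_table, config.spike_threshold_pct)
    n_invalid = sum(not t.valid for t in traces)
    if n_invalid:
        logger.info("%d traces invalid (non-positive baseline)", n_invalid)
    kept, removed = trial_stats.remove_outliers(traces, config.z_max)
    logger.info("outlier removal: kept %d, removed %d tracks", len(kept), len(removed))

    calls = [c for t in kept for c in cad.detect_spikes(t, config.spike_threshold_pct)]
    active = sorted(cad.active_cells(calls))
    duration = stack.duration_min
    activity = (
        trial_stats.mean_activity(len(calls), len(kept), duration) if kept and duration > 0 else 0.0
    )
    summary = trial_stats.TrialSummary(
        trial_id=trial_id,
        condition=condition,
        period=period,
        n_cells_segmented=mask.n_cells,
        n_cells_after_outliers=len(kept),
        n_spikes=len(calls),
        duration_min=duration,
        mean_activity=activity,
        active_track_ids=active,
    )
    return PipelineResult(
        composite, mask, table, bg, bg_table, traces, kept, removed, calls, summary
    )


def _traces_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    raw_by_track = {
        tid: g["MEAN_INTENSITY"].to_numpy()
        for tid, g in result.table.sort_values("FRAME").groupby("TRACK_ID")
    }
    for tr in result.traces:
        raw = raw_by_track[tr.track_id]
        for t in range(raw.size):
            rows.append(
                (tr.track_id, t, raw[t], tr.raw[t], tr.values[t] if tr.valid else np.nan)
            )
    return pd.DataFrame(rows, columns=["TRACK_ID", "FRAME", "RAW", "BG_SUB", "NORMALIZED"])


def _spikes_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.track_id, c.peak_frame, c.rule, c.magnitude_pct) for c in calls],
        columns=["TRACK_ID", "PEAK_FRAME", "RULE", "MAGNITUDE_PCT"],
    )


def run_pipeline(
    config: io_stack.RunConfig,
    cell_stack_path: str | Path,
    outdir: str | Path,
    nuclear_path: str | Path | None = None,
    mask_path: str | Path | None = None,
    trial_id: str | None = None,
    condition: str = "",
    period: str = "pre",
) -> dict:
    """File-to-file run; writes all artifacts into ``outdir`` and returns the
    summary dict. Partial artifacts are retained on stage failure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("betacal")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        stack = io_stack.read_stack(cell_stack_path, config.frame_interval_s)
        nuclear = (
            io_stack.read_stack(nuclear_path).frames[0] if nuclear_path else None
        )
        mask = (
            segment.LabelMask(io_stack.read_label_mask(mask_path)) if mask_path else None
        )
        trial_id = trial_id or Path(cell_stack_path).stem
        result = run_on_arrays(
            stack, config, nuclear=nuclear, mask=mask,
            trial_id=trial_id, condition=condition, period=period,
        )
        io_stack.write_stack(result.composite.cell_channel[None], outdir / "composite.tif")
        io_stack.write_label_mask(result.mask.labels, outdir / "mask.tif")
        io_stack.write_track_table(result.table, outdir / "tracks.csv")
        _traces_frame(result).to_csv(outdir / "traces.csv", index=False, float_format="%.12g")
        _spikes_frame(result.calls).to_csv(outdir / "spikes.csv", index=False, float_format="%.12g")
        summary = result.summary.to_dict()
        summary["removed_track_ids"] = result.removed_track_ids
        summary["config"] = config.to_dict()
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def compare_periods(pre_summaries: list[dict], post_summaries: list[dict]) -> dict:
    """Paired pre/post comparison across trials, grouped by condition.

    Summaries are paired by ``trial_id``; a mismatch raises
    :class:`PairingError` listing the offending ids.
    """
    pre_by_id = {s["trial_id"]: s for s in pre_summaries}
    post_by_id = {s["trial_id"]: s for s in post_summaries}
    if len(pre_by_id) != len(pre_summaries) or len(post_by_id) != len(post_summaries):
        raise PairingError("duplicate trial_id among summaries")
    only_pre = sorted(set(pre_by_id) - set(post_by_id))
    only_post = sorted(set(post_by_id) - set(pre_by_id))
    if only_pre or only_post:
        raise PairingError(
            f"unpaired trials: pre-only {only_pre}, post-only {only_post}"
        )
    ids = sorted(pre_by_id)
    conditions: dict[str, list[str]] = {}
    for tid in ids:
        conditions.setdefault(pre_by_id[tid].get("condition", ""), []).append(tid)

    report: dict = {"n_pairs": len(ids), "conditions": {}}
    for cond, tids in conditions.items():
        pre_act = [pre_by_id[t]["mean_activity"] for t in tids]
        post_act = [post_by_id[t]["mean_activity"] for t in tids]
        deltas = [b - a for a, b in zip(pre_act, post_act)]
        entry = {
            "trials": tids,
            "pre_activity": pre_act,
            "post_activity": post_act,
            "activity_delta": deltas,
            "mean_delta": float(np.mean(deltas)),
        }
        if len(tids) >= 2:
            t, p, df = trial_stats.paired_ttest(pre_act, post_act)
            entry.update({"t": t, "p": p, "df": df})
        report["conditions"][cond] = entry
    return report
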