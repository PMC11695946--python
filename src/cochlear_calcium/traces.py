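"""ROI trace extraction, dF/F0, interpolation, detrending and stitching."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import FluorescenceTrace, RoiMap, TimelapseStack
from .preprocess import FrameQCReport

log = logging.getLogger("cochlear_calcium")


def erode_rois(rois: RoiMap, radius: int = 2) -> RoiMap:
    """Morphologically erode every label to reduce cross-contamination.

    Labels that vanish under erosion are dropped (and logged); the usual
    radius is 1–3 px.
    """
    if radius < 1:
        raise ValueError(f"erosion radius must be ≥ 1, got {radius}")
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    selem = (yy ** 2 + xx ** 2) <= radius ** 2
    out = np.zeros_like(rois.labels)
    dropped = []
    for lab in rois.label_ids:
        eroded = ndimage.binary_erosion(rois.labels == lab, structure=selem)
        if eroded.any():
            out[eroded] = lab
        else:
            dropped.append(lab)
    if dropped:
        log.info("erode_rois: dropped labels that vanished at radius %d: %s",
                 radius, dropped)
    if not out.any():
        raise ValueError("all labels vanished under erosion")
    return RoiMap(out,
                  {k: v for k, v in rois.class_of.items() if k not in dropped},
                  {k: v for k, v in rois.identity_of.items() if k not in dropped})


def _interpolate_removed(raw: np.ndarray, removed: np.ndarray) -> np.ndarray:
    """Linear interpolation across removed samples (edges: nearest value)."""
    if not removed.any():
        return raw
    x = np.arange(len(raw))
    good = ~removed
    return np.interp(x, x[good], raw[good])


def extract_traces(stack: TimelapseStack, rois: RoiMap,
                   report: FrameQCReport | None = None,
                   f0_rule: str = "percentile", f0_percentile: float = 10.0,
                   ) -> list[FluorescenceTrace]:
    """Per-ROI pixel-average traces normalized to dF/F0.

    Samples inside removed frame intervals are replaced by linear
    interpolation between flanking in-focus samples and flagged in
    ``interpolated_mask``.  F0 defaults to the 10th percentile of the raw
    trace (robust to active periods); ``f0_rule="median"`` is available.
    """
    label_ids = rois.label_ids
    if not label_ids:
        raise ValueError("ROI map has no labels")
    removed = (report.removed_mask(stack.n_frames) if report is not None
               else np.zeros(stack.n_frames, dtype=bool))
    # per-frame labelled means via bincount
    flat_labels = rois.labels.ravel()
    counts = np.bincount(flat_labels, minlength=max(label_ids) + 1)
    traces = []
    sums = np.empty((stack.n_frames, max(label_ids) + 1))
    for k in range(stack.n_frames):
        sums[k] = np.bincount(flat_labels, weights=stack.frames[k].ravel(),
                              minlength=max(label_ids) + 1)
    for lab in label_ids:
        f = sums[:, lab] / counts[lab]
        f = _interpolate_removed(f, removed)
        if f0_rule == "median":
            f0 = float(np.median(f))
        else:
            f0 = float(np.percentile(f, f0_percentile))
        if f0 <= 0:
            raise ValueError(f"ROI {rois.identity(lab)}: baseline F0 ≤ 0")
        traces.append(FluorescenceTrace(
            identity=rois.identity(lab),
            samples=(f - f0) / f0,
            interpolated_mask=removed.copy(),
            frame_rate=stack.frame_rate,
        ))
    log.info("extract_traces: %d ROIs, %d frames (%d interpolated)",
             len(traces), stack.n_frames, int(removed.sum()))
    return traces


def detrend(trace: FluorescenceTrace | np.ndarray, window_s: float = 30.0,
            frame_rate: float | None = None) -> FluorescenceTrace | np.ndarray:
    """Subtract a centered rolling median (edges: shrinking window)."""
    if isinstance(trace, FluorescenceTrace):
        rate = trace.frame_rate
        samples = trace.samples
    else:
        if frame_rate is None:
            raise ValueError("frame_rate required for array input")
        rate = frame_rate
        samples = np.asarray(trace, dtype=float)
    win = max(3, int(round(window_s * rate)) | 1)   # odd
    med = pd.Series(samples).rolling(win, center=True, min_periods=1).median().to_numpy()
    out = samples - med
    if isinstance(trace, FluorescenceTrace):
        return FluorescenceTrace(trace.identity, out, trace.interpolated_mask,
                                 trace.frame_rate, trace.start_time)
    return out


def stitch_recordings(trace_sets: list[list[FluorescenceTrace]],
                      durations: list[float] | None = None,
                      gap_s: float | None = None,
                      ) -> dict[str, list[FluorescenceTrace]]:
    """Combine repeated recordings of the same field per cell identity.

    Each cell's traces stay separate segments (no peak detection may cross a
    recording boundary); segments get consecutive ``start_time`` offsets.
    Returns identity -> list of segments; total observed duration per cell is
    the sum of its segments' durations.
    """
    per_cell: dict[str, list[FluorescenceTrace]] = {}
    offset = 0.0
    for k, traces in enumerate(trace_sets):
        seen = set()
        dur = durations[k] if durations else max((t.duration for t in traces), default=0.0)
        for tr in traces:
            if tr.identity in seen:
                raise ValueError(f"identity collision within one recording: {tr.identity}")
            seen.add(tr.identity)
            seg = FluorescenceTrace(tr.identity, tr.samples, tr.interpolated_mask,
                                    tr.frame_rate, start_time=offset)
            per_cell.setdefault(tr.identity, []).append(seg)
        offset += dur + (gap_s if gap_s is not None else 1.0)
    return per_cell


def total_duration(segments: list[FluorescenceTrace]) -> float:
    """Total observed time of one cell across stitched recordings, seconds."""
    return float(sum(seg.duration for seg in segments))
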