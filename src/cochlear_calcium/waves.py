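"""Supporting-cell Ca²⁺ wave segmentation, geometry/kinetics, and kymographs.

Waves are segmented as 3D-connected voxel objects in (t, y, x) after spatial
binning and Voronoi–Otsu labelling of the ΔF/F₀ stack.  Their geometry is
quantified in the cochlear coordinate frame (longitudinal arc length s,
radial distance d from the IHC row); expansion/contraction speeds come from
a linear fit of the equivalent radius √(area/π) against time.  Kymographs
along the IHC row and the GER read longitudinal propagation speed as a ridge
slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import WaveConfig
from .events import CellEvent
from .geometry import CochlearAxis
from .io_core import TimelapseStack
from .segmentation import voronoi_otsu_label

log = logging.getLogger("cochlear_calcium")


@dataclass
class WaveObject:
    """A 3D-connected Ca²⁺-wave voxel set (binned grid) with derived properties."""

    wave_id: int
    voxels: np.ndarray              # (n, 3) int indices (t, y, x) on the binned grid
    bin_factor: int
    pixel_size: float               # µm of the ORIGINAL grid
    frame_rate: float
    boundary_truncated: bool = False
    manual_2d: bool = False         # imported 2D ROI; no kinetics
    # filled by quantify_wave
    per_frame_area: dict[int, float] = field(default_factory=dict)   # µm²
    max_area: float = np.nan
    frame_of_max: int = -1
    centroid_um: tuple[float, float] = (np.nan, np.nan)
    centroid_distance: float = np.nan
    longitudinal_extent: float = np.nan
    radial_extent: float = np.nan
    fdhm: float | None = None
    expansion_speed: float | None = None
    contraction_speed: float | None = None

    @property
    def binned_px_um(self) -> float:
        return self.bin_factor * self.pixel_size

    @property
    def onset_frame(self) -> int:
        return int(self.voxels[:, 0].min())

    @property
    def offset_frame(self) -> int:
        return int(self.voxels[:, 0].max())

    @property
    def onset_time(self) -> float:
        return self.onset_frame / self.frame_rate

    @property
    def offset_time(self) -> float:
        return (self.offset_frame + 1) / self.frame_rate


def _bin_stack(frames: np.ndarray, b: int) -> np.ndarray:
    if b <= 1:
        return frames.astype(np.float64)
    t, h, w = frames.shape
    h2, w2 = (h // b) * b, (w // b) * b
    f = frames[:, :h2, :w2].astype(np.float64)
    return f.reshape(t, h2 // b, b, w2 // b, b).mean(axis=(2, 4))


def dff_stack(frames: np.ndarray, percentile: float = 10.0) -> np.ndarray:
    """Per-pixel ΔF/F₀ using a low temporal percentile as F₀."""
    f0 = np.percentile(frames, percentile, axis=0)
    f0 = np.clip(f0, 1e-6, None)
    return (frames - f0) / f0


def dff_timelapse(stack: TimelapseStack, percentile: float = 10.0) -> TimelapseStack:
    """Per-pixel ΔF/F₀ version of a stack (for kymographs and display)."""
    return stack.copy_with(dff_stack(stack.frames.astype(np.float64), percentile))


def segment_waves(stack: TimelapseStack, cfg: WaveConfig | None = None,
                  cell_labels: np.ndarray | None = None,
                  ) -> tuple[list[WaveObject], np.ndarray]:
    """Segment Ca²⁺ waves as 3D objects; returns (waves, binned ΔF/F₀ stack).

    Objects smaller than ``min_volume`` voxels or spatially confined within a
    single cell-sized footprint are discarded — those are single-cell
    transients, not intercellular waves.  When a cell label image (original
    pixel grid) is supplied, an object whose footprint lies ≥80% within the
    dilated union of the cell masks is likewise excluded — that also removes
    coordinated activity of the labelled row itself.
    """
    from skimage.filters import threshold_otsu

    from .preprocess import robust_sd

    cfg = cfg or WaveConfig()
    if cfg.bin_factor < 1:
        raise ValueError("bin_factor must be ≥ 1")
    binned = _bin_stack(stack.frames, cfg.bin_factor)
    dff = dff_stack(binned)
    threshold = cfg.threshold
    if threshold is None:
        # Otsu on a noise-dominated ΔF/F₀ volume can split the noise mode in
        # half; guard it with a floor of 6 robust SDs of the smoothed volume
        smoothed = ndimage.gaussian_filter(dff, cfg.outline_sigma)
        sub = smoothed[::max(1, smoothed.shape[0] // 600)]
        threshold = max(float(threshold_otsu(sub)), 6.0 * robust_sd(sub.ravel()))
    labels = voronoi_otsu_label(dff, cfg.spot_sigma, cfg.outline_sigma,
                                threshold=threshold)
    if labels.max() == 0:
        log.warning("segment_waves: threshold left no foreground")
        return [], dff
    bpx = cfg.bin_factor * stack.pixel_size
    cells_binned = None
    if cell_labels is not None:
        b = cfg.bin_factor
        cells_binned = np.asarray(cell_labels)[b // 2::b, b // 2::b]
    waves = []
    wid = 0
    n_dropped_small, n_dropped_confined = 0, 0
    # single pass voxel collection (argwhere per label is quadratic)
    coords = np.argwhere(labels > 0)
    labs_flat = labels[labels > 0]
    order = np.argsort(labs_flat, kind="stable")
    coords = coords[order]
    labs_sorted = labs_flat[order]
    bounds = np.searchsorted(labs_sorted, np.arange(1, labels.max() + 2))
    for lab in range(1, labels.max() + 1):
        vox = coords[bounds[lab - 1]:bounds[lab]]
        if len(vox) == 0:
            continue
        if len(vox) < cfg.min_volume:
            n_dropped_small += 1
            continue
        foot = np.unique(vox[:, 1:], axis=0)
        if len(foot) * bpx ** 2 < cfg.min_footprint_area_um2:
            n_dropped_confined += 1
            continue
        if cells_binned is not None and _confined_to_cells(foot, cells_binned):
            n_dropped_confined += 1
            continue
        truncated = vox[:, 0].min() == 0 or vox[:, 0].max() == stack.n_frames - 1
        waves.append(WaveObject(wid, vox, cfg.bin_factor, stack.pixel_size,
                                stack.frame_rate, boundary_truncated=bool(truncated)))
        wid += 1
    log.info("segment_waves: %d waves kept, %d below min_volume, %d single-cell confined",
             len(waves), n_dropped_small, n_dropped_confined)
    return waves, dff


def _confined_to_cells(foot: np.ndarray, cells_binned: np.ndarray,
                       dilate: int = 2, frac: float = 0.8) -> bool:
    """True when ≥``frac`` of the footprint lies within the dilated union of
    the labelled cell bodies.

    Catches both single-cell transients and coordinated multi-cell activity
    along the labelled row — neither is an intercellular wave of the
    surrounding epithelium.  A genuine wave keeps a substantial footprint
    outside the cell masks.
    """
    h, w = cells_binned.shape
    rows = np.clip(foot[:, 0], 0, h - 1)
    cols = np.clip(foot[:, 1], 0, w - 1)
    mask = ndimage.binary_dilation(cells_binned > 0, iterations=dilate)
    inside = mask[rows, cols].sum()
    return inside / len(foot) >= frac


def quantify_wave(wave: WaveObject, axis: CochlearAxis, dff: np.ndarray | None = None,
                  speed_estimator: str = "equivalent_radius") -> WaveObject:
    """Populate geometric and kinetic properties of a segmented wave.

    Extents and centroid are measured on the footprint at maximal expansion
    in (s, d) coordinates; FDHM from the pixel-average ΔF/F₀ trace over the
    union footprint (skipped when the wave is boundary-truncated); speeds by
    a linear fit of the equivalent radius against time (onset→max for
    expansion, max→offset for contraction).
    """
    if len(wave.voxels) == 0:
        raise ValueError("empty wave")
    bpx = wave.binned_px_um
    frames, counts = np.unique(wave.voxels[:, 0], return_counts=True)
    areas = counts * bpx ** 2
    wave.per_frame_area = {int(f): float(a) for f, a in zip(frames, areas)}
    k_max = int(np.argmax(areas))
    wave.frame_of_max = int(frames[k_max])
    wave.max_area = float(areas[k_max])

    foot_max = wave.voxels[wave.voxels[:, 0] == wave.frame_of_max][:, 1:]
    pts_um = np.stack([(foot_max[:, 1] + 0.5) * bpx, (foot_max[:, 0] + 0.5) * bpx], axis=1)
    s, d = axis.project(pts_um)
    wave.longitudinal_extent = float(s.max() - s.min() + bpx)
    wave.radial_extent = float(d.max() - d.min() + bpx)
    cx, cy = float(pts_um[:, 0].mean()), float(pts_um[:, 1].mean())
    wave.centroid_um = (cx, cy)
    _, dc = axis.project(np.array([[cx, cy]]))
    wave.centroid_distance = float(abs(dc[0]))

    if dff is not None and not wave.boundary_truncated and not wave.manual_2d:
        union_foot = np.unique(wave.voxels[:, 1:], axis=0)
        trace = dff[:, union_foot[:, 0], union_foot[:, 1]].mean(axis=1)
        wave.fdhm = _trace_fdhm(trace, wave.frame_of_max, wave.frame_rate)

    if not wave.manual_2d:
        r_eq = np.sqrt(areas / np.pi)
        t_s = frames / wave.frame_rate
        wave.expansion_speed = _fit_speed(t_s[:k_max + 1], r_eq[:k_max + 1])
        contraction = _fit_speed(t_s[k_max:], r_eq[k_max:])
        wave.contraction_speed = abs(contraction) if contraction is not None else None
        if speed_estimator == "boundary":
            wave.expansion_speed = _boundary_speed(wave, axis, expanding=True)
            wave.contraction_speed = _boundary_speed(wave, axis, expanding=False)
        if wave.expansion_speed is None or wave.contraction_speed is None:
            log.info("quantify_wave %d: speed undefined (max at wave %s)",
                     wave.wave_id,
                     "onset" if wave.expansion_speed is None else "offset")
    return wave


def _fit_speed(t_s: np.ndarray, r_um: np.ndarray) -> float | None:
    if len(t_s) < 2:
        return None
    return float(np.polyfit(t_s, r_um, 1)[0])


def _boundary_speed(wave: WaveObject, axis: CochlearAxis, expanding: bool) -> float | None:
    """Alternative estimator: maximal boundary displacement from the centroid."""
    bpx = wave.binned_px_um
    frames = np.unique(wave.voxels[:, 0])
    k_max = wave.frame_of_max
    sel = frames[frames <= k_max] if expanding else frames[frames >= k_max]
    if len(sel) < 2:
        return None
    radii = []
    for f in sel:
        foot = wave.voxels[wave.voxels[:, 0] == f][:, 1:]
        pts = np.stack([(foot[:, 1] + 0.5) * bpx, (foot[:, 0] + 0.5) * bpx], axis=1)
        radii.append(np.hypot(pts[:, 0] - wave.centroid_um[0],
                              pts[:, 1] - wave.centroid_um[1]).max())
    v = np.polyfit(sel / wave.frame_rate, radii, 1)[0]
    return float(abs(v))


def _trace_fdhm(trace: np.ndarray, peak_frame: int, frame_rate: float) -> float | None:
    """FDHM of a wave trace relative to zero baseline (ΔF/F₀ units)."""
    # the object's max-area frame may not be the trace's max; search nearby
    lo = max(0, peak_frame - int(2 * frame_rate))
    hi = min(len(trace), peak_frame + int(2 * frame_rate) + 1)
    p = lo + int(np.argmax(trace[lo:hi]))
    half = trace[p] / 2.0
    if trace[p] <= 0:
        return None
    i = p
    while i > 0 and trace[i - 1] >= half:
        i -= 1
    left = i - (trace[i] - half) / (trace[i] - trace[i - 1]) if i > 0 else 0.0
    j = p
    while j < len(trace) - 1 and trace[j + 1] >= half:
        j += 1
    right = (j + (trace[j] - half) / (trace[j] - trace[j + 1])
             if j < len(trace) - 1 else float(len(trace) - 1))
    return (right - left) / frame_rate


def wave_frequency(waves: list[WaveObject], total_duration_s: float) -> float:
    """Waves/min; boundary-truncated waves count (only durations exclude them)."""
    if total_duration_s <= 0:
        raise ValueError("total duration must be positive")
    return len(waves) / (total_duration_s / 60.0)


def waves_to_table(waves: list[WaveObject]) -> pd.DataFrame:
    rows = []
    for w in waves:
        rows.append({
            "wave_id": w.wave_id,
            "onset_s": w.onset_time, "offset_s": w.offset_time,
            "boundary_truncated": int(w.boundary_truncated),
            "manual_2d": int(w.manual_2d),
            "max_area_um2": w.max_area, "frame_of_max": w.frame_of_max,
            "centroid_x_um": w.centroid_um[0], "centroid_y_um": w.centroid_um[1],
            "centroid_distance_um": w.centroid_distance,
            "longitudinal_extent_um": w.longitudinal_extent,
            "radial_extent_um": w.radial_extent,
            "fdhm_s": np.nan if w.fdhm is None else w.fdhm,
            "expansion_speed_um_s": np.nan if w.expansion_speed is None else w.expansion_speed,
            "contraction_speed_um_s": np.nan if w.contraction_speed is None else w.contraction_speed,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# kymographs
# --------------------------------------------------------------------------

@dataclass
class Kymograph:
    data: np.ndarray            # (t, arc-length sample)
    step_um: float
    half_width_px: int
    frame_rate: float
    s_start: float = 0.0        # arc-length of column 0, µm

    @property
    def arc_positions(self) -> np.ndarray:
        return self.s_start + np.arange(self.data.shape[1]) * self.step_um


def build_kymograph(stack: TimelapseStack, polyline: CochlearAxis,
                    half_width_px: int = 3, step_um: float = 1.0) -> Kymograph:
    """Distance–time image: each column is the mean intensity over a transect
    of ±``half_width_px`` perpendicular to the polyline, sampled every
    ``step_um`` of arc length."""
    if step_um <= 0:
        raise ValueError("step must be positive")
    n_cols = int(np.floor(polyline.arc_length / step_um)) + 1
    s_samples = np.arange(n_cols) * step_um
    pts = polyline.point_at(s_samples)          # (n, 2) µm
    normals = polyline.normal_at(s_samples)
    offsets = np.arange(-half_width_px, half_width_px + 1) * stack.pixel_size
    # (n_cols, n_off, 2) µm -> px coordinates (row, col)
    sample_um = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    rows = sample_um[..., 1] / stack.pixel_size
    cols = sample_um[..., 0] / stack.pixel_size
    h, w = stack.frames.shape[1:]
    if rows.min() < 0 or rows.max() > h - 1 or cols.min() < 0 or cols.max() > w - 1:
        log.warning("build_kymograph: polyline transects exit the field; clipped")
        rows = np.clip(rows, 0, h - 1)
        cols = np.clip(cols, 0, w - 1)
    coords = np.stack([rows.ravel(), cols.ravel()])
    data = np.empty((stack.n_frames, n_cols))
    for k in range(stack.n_frames):
        vals = ndimage.map_coordinates(stack.frames[k].astype(np.float64), coords,
                                       order=1, mode="nearest")
        data[k] = vals.reshape(n_cols, len(offsets)).mean(axis=1)
    return Kymograph(data, step_um, half_width_px, stack.frame_rate)


def measure_kymo_speed(kymo: Kymograph, t_range: tuple[float, float],
                       s_range: tuple[float, float]) -> float | None:
    """Propagation speed within a time × arc-length box, µm/s.

    Origin = earliest suprathreshold sample (threshold: half-max within the
    box); maximal expansion = suprathreshold sample farthest in |Δs| from the
    origin; speed = |Δs|/Δt.  Returns 0 for a stationary blob and ``None``
    (logged) when the extremal sample is simultaneous with the origin.
    """
    r0 = max(0, int(np.floor(t_range[0] * kymo.frame_rate)))
    r1 = min(kymo.data.shape[0], int(np.ceil(t_range[1] * kymo.frame_rate)))
    c0 = max(0, int(np.floor((s_range[0] - kymo.s_start) / kymo.step_um)))
    c1 = min(kymo.data.shape[1], int(np.ceil((s_range[1] - kymo.s_start) / kymo.step_um)) + 1)
    sub = kymo.data[r0:r1, c0:c1]
    if sub.size == 0 or r1 - r0 < 1 or c1 - c0 < 1:
        raise ValueError("degenerate kymograph box")
    thr = sub.min() + 0.5 * (sub.max() - sub.min())
    supra = sub >= thr
    if not supra.any():
        return None
    t_idx, s_idx = np.nonzero(supra)
    t_first = t_idx.min()
    s_origin = float(s_idx[t_idx == t_first].mean())
    ds = np.abs(s_idx - s_origin) * kymo.step_um
    k = int(np.argmax(ds))
    if ds[k] == 0:
        return 0.0
    dt = (t_idx[k] - t_first) / kymo.frame_rate
    if dt <= 0:
        log.info("measure_kymo_speed: maximal expansion simultaneous with origin; undefined")
        return None
    return float(ds[k] / dt)


# --------------------------------------------------------------------------
# wave ↔ IHC event matching
# --------------------------------------------------------------------------

def match_wave_to_ihc_events(waves: list[WaveObject], events: list[CellEvent],
                             cell_arc_positions: dict[str, float],
                             origin_window_um: float = 35.0,
                             lag_s: float = 2.0) -> pd.DataFrame:
    """Pair each near-row wave with the IHC event overlapping it in time.

    Only waves whose centroid lies within ``origin_window_um`` of the IHC row
    enter; a wave matches the event whose time span overlaps
    [wave onset, wave offset + lag].  Ambiguity resolves to the nearest event
    in time (flagged).  Returns one record per eligible wave with the wave's
    longitudinal extent and the matched event's IHC activity span.
    """
    rows = []
    for w in waves:
        if not np.isfinite(w.centroid_distance) or w.centroid_distance > origin_window_um:
            continue
        t0, t1 = w.onset_time, w.offset_time + lag_s
        cands = [ev for ev in events
                 if ev.t_start <= t1 and ev.t_end >= t0]
        ambiguous = len(cands) > 1
        match = None
        if cands:
            match = min(cands, key=lambda ev: abs(ev.t_start - t0))
        row = {
            "wave_id": w.wave_id,
            "wave_onset_s": t0,
            "wave_extent_um": w.longitudinal_extent,
            "matched": int(match is not None),
            "ambiguous": int(ambiguous),
            "event_class": match.event_class if match else "",
            "n_cells": len(match.cells) if match else 0,
            "coordinated_3plus": int(match is not None and len(match.cells) >= 3),
        }
        if match:
            ss = [cell_arc_positions[c] for c in match.cells]
            row["ihc_span_um"] = float(max(ss) - min(ss))
        else:
            row["ihc_span_um"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
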