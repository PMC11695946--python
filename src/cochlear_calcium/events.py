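"""Ca²⁺ transient detection and multicell event analysis.

A transient is a prominence-selected peak of the detrended dF/F0 trace that
passes two inclusion rules: amplitude above twice the trace SD and full
duration at half maximum (FDHM) above 200 ms.  Transients across the IHC row
are grouped into events by single-linkage chaining in time (2 s window) and
split wherever more than four consecutive non-participating cells separate
participants; events are classed single (1 cell), pair (2) or multiple (≥3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .io_core import FluorescenceTrace
from .preprocess import robust_sd

log = logging.getLogger("cochlear_calcium")


@dataclass
class Transient:
    cell: str
    peak_time: float        # s
    amplitude: float        # dF/F0 of the detrended trace at the peak
    prominence: float
    fdhm: float             # s

    def __post_init__(self):
        if not self.fdhm > 0:
            raise ValueError("transient FDHM must be positive")


@dataclass
class CellEvent:
    transients: list[Transient]
    cells: set[str]
    event_class: str                 # single / pair / multiple
    skipped_cells: list[str] = field(default_factory=list)

    @property
    def t_start(self) -> float:
        return min(tr.peak_time for tr in self.transients)

    @property
    def t_end(self) -> float:
        return max(tr.peak_time for tr in self.transients)


def classify(n_cells: int) -> str:
    return "single" if n_cells == 1 else "pair" if n_cells == 2 else "multiple"


# --------------------------------------------------------------------------
# transient detection
# --------------------------------------------------------------------------

def _fdhm_at_peak(samples: np.ndarray, peak: int, prominence: float,
                  frame_rate: float, dwell: int = 1,
                  peak_height: float | None = None,
                  band: float = 0.0) -> float:
    """FDHM at half of the peak's height above its local baseline.

    The local baseline is the prominence base, but never below the detrended
    trace's zero level — a deep saddle elsewhere must not widen the peak.
    Noise robustness is tunable two ways: ``dwell`` > 1 requires that many
    consecutive below-half samples before a crossing counts, and ``band`` > 0
    terminates the walk only once the trace falls that far below half
    (Schmitt trigger).  The reported width is always interpolated at the half
    level itself.
    """
    height = samples[peak] if peak_height is None else peak_height
    baseline = max(height - prominence, 0.0)
    half = baseline + 0.5 * (height - baseline)
    stop = half - band
    n = len(samples)

    def _crossed(idx_range) -> int | None:
        """First index of a run of ≥dwell consecutive below-threshold samples."""
        run = 0
        for i in idx_range:
            if samples[i] < stop:
                run += 1
                if run >= dwell:
                    return i - (dwell - 1) * (1 if idx_range.step > 0 else -1)
            else:
                run = 0
        return None

    def _half_cross(c: int, step: int) -> float:
        # walk back toward the peak to the last sample ≥ half, then
        # interpolate the half-level crossing
        j = c
        while samples[j] < half and j != peak:
            j -= step
        k = j + step
        if samples[j] == samples[k]:
            return float(j)
        frac = (samples[j] - half) / (samples[j] - samples[k])
        return j + step * frac

    c = _crossed(range(peak - 1, -1, -1))
    left = 0.0 if c is None else _half_cross(c, -1)
    c = _crossed(range(peak + 1, n))
    right = float(n - 1) if c is None else _half_cross(c, +1)
    return (right - left) / frame_rate


def detect_transients(trace: FluorescenceTrace, min_fdhm: float = 0.2,
                      amp_k: float = 2.0, prominence_k: float = 2.0,
                      ) -> list[Transient]:
    """Detect genuine Ca²⁺ transients on a detrended trace.

    Peaks are found by prominence (``prominence_k`` × robust SD), then kept
    only if amplitude > ``amp_k`` × SD(trace) and FDHM > ``min_fdhm``.
    Peaks whose half-max span lies entirely in interpolated samples are
    rejected.
    """
    samples = trace.samples
    if trace.duration < 4 * min_fdhm:
        raise ValueError("trace too short to detect transients")
    sd = float(samples.std())
    rsd = robust_sd(samples)
    prom_thr = prominence_k * max(rsd, 1e-12)
    peaks, props = find_peaks(samples, prominence=prom_thr)
    # amplitude is height above the local pre-peak minimum so that a noise
    # wiggle riding the decay tail of a preceding transient is measured
    # against the tail, not against the distant zero baseline
    w_loc = max(1, int(round(2.0 * trace.frame_rate)))
    out = []
    for p, prom in zip(peaks, props["prominences"]):
        local_base = max(float(samples[max(0, p - w_loc):p + 1].min()), 0.0)
        amp = float(samples[p]) - local_base
        if amp <= amp_k * sd:
            continue
        # Schmitt-trigger width gates inclusion: the walk from the peak stops
        # once the trace falls a fifth of the peak height (capped at one
        # robust SD) below half-max.  A marginal-SNR noise peak terminates
        # within a sample or two, while a genuine ≥4σ transient (half ≈ 2σ)
        # survives isolated noise dips near the crossing.
        peak_h = float(samples[p]) - max(float(samples[p]) - float(prom), 0.0)
        fdhm_gate = _fdhm_at_peak(samples, p, float(prom), trace.frame_rate,
                                  band=min(rsd, 0.2 * peak_h))
        if fdhm_gate <= min_fdhm:
            continue
        # measurement pass: dwell hysteresis + noise-robust peak height from
        # a 50 ms-smoothed copy, both of which de-bias the width of genuine
        # transients without loosening the inclusion gate above
        smooth_h = float(gaussian_filter1d(
            samples[max(0, p - 5):p + 6], max(0.05 * trace.frame_rate, 0.5)).max())
        fdhm = _fdhm_at_peak(samples, p, float(prom), trace.frame_rate,
                             dwell=max(1, int(round(0.05 * trace.frame_rate))),
                             peak_height=min(smooth_h, float(samples[p])))
        half_w = max(1, int(round(fdhm * trace.frame_rate / 2)))
        span = trace.interpolated_mask[max(0, p - half_w):p + half_w + 1]
        if span.size and span.all():
            continue
        out.append(Transient(trace.identity,
                             float(trace.start_time + p / trace.frame_rate),
                             amp, float(prom), fdhm))
    return out


def detect_transients_stitched(segments: list[FluorescenceTrace], **kw) -> list[Transient]:
    """Detect per segment and pool; peaks never chain across a boundary gap."""
    out: list[Transient] = []
    for seg in segments:
        out.extend(detect_transients(seg, **kw))
    return out


# --------------------------------------------------------------------------
# frequencies
# --------------------------------------------------------------------------

def compute_frequency(transients: list[Transient],
                      total_duration_s: dict[str, float],
                      min_duration_s: float = 300.0) -> dict[str, float]:
    """Events/min per cell; cells observed under ``min_duration_s`` are excluded."""
    counts: dict[str, int] = {}
    for tr in transients:
        counts[tr.cell] = counts.get(tr.cell, 0) + 1
    freq = {}
    for cell, dur in total_duration_s.items():
        if dur <= 0:
            raise ValueError(f"cell {cell}: non-positive total duration")
        if dur < min_duration_s:
            log.info("compute_frequency: cell %s excluded (%.1f s < %.0f s)",
                     cell, dur, min_duration_s)
            continue
        freq[cell] = counts.get(cell, 0) / (dur / 60.0)
    return freq


# --------------------------------------------------------------------------
# event grouping
# --------------------------------------------------------------------------

def group_events(transients: list[Transient], cell_positions: dict[str, int],
                 window: float = 2.0, gap_limit: int = 4,
                 linkage: str = "single") -> list[CellEvent]:
    """Group transients into multicell events.

    Time linkage: transients belong to the same cluster if connected by a
    chain of pairwise gaps ≤ ``window`` (single linkage; the complete-linkage
    alternative requires all pairwise gaps ≤ window).  Clusters are then
    split positionally wherever a run of strictly more than ``gap_limit``
    consecutive non-participating cells separates participants.
    """
    if not transients:
        return []
    trs = sorted(transients, key=lambda tr: (tr.peak_time, cell_positions[tr.cell]))
    clusters: list[list[Transient]] = []
    if linkage == "single":
        cur = [trs[0]]
        for tr in trs[1:]:
            if tr.peak_time - cur[-1].peak_time <= window:
                cur.append(tr)
            else:
                clusters.append(cur)
                cur = [tr]
        clusters.append(cur)
    elif linkage == "complete":
        cur = [trs[0]]
        for tr in trs[1:]:
            if tr.peak_time - cur[0].peak_time <= window:
                cur.append(tr)
            else:
                clusters.append(cur)
                cur = [tr]
        clusters.append(cur)
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    events: list[CellEvent] = []
    for cluster in clusters:
        events.extend(_split_by_position_gap(cluster, cell_positions, gap_limit))
    return events


def _split_by_position_gap(cluster: list[Transient], cell_positions: dict[str, int],
                           gap_limit: int) -> list[CellEvent]:
    pos_of = {tr.cell: cell_positions[tr.cell] for tr in cluster}
    positions = sorted(set(pos_of.values()))
    # group participant positions separated by ≤ gap_limit empty cells
    groups: list[set[int]] = [{positions[0]}]
    for prev, cur in zip(positions, positions[1:]):
        if cur - prev - 1 > gap_limit:
            groups.append(set())
        groups[-1].add(cur)
    out = []
    for grp in groups:
        members = [tr for tr in cluster if pos_of[tr.cell] in grp]
        cells = {tr.cell for tr in members}
        out.append(CellEvent(members, cells, classify(len(cells))))
    return out


def group_events_bruteforce(transients: list[Transient],
                            cell_positions: dict[str, int],
                            window: float = 2.0, gap_limit: int = 4,
                            ) -> list[CellEvent]:
    """Independent oracle: exhaustive pairwise transitive closure in time,
    then exhaustive positional gap splitting.  O(n²); for testing."""
    n = len(transients)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            if abs(transients[i].peak_time - transients[j].peak_time) <= window:
                union(i, j)
    comps: dict[int, list[Transient]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(transients[i])

    events = []
    for cluster in comps.values():
        positions = sorted({cell_positions[tr.cell] for tr in cluster})
        # exhaustive split: cut at every internal gap of > gap_limit cells
        cuts = [k + 1 for k in range(len(positions) - 1)
                if positions[k + 1] - positions[k] - 1 > gap_limit]
        bounds = [0] + cuts + [len(positions)]
        for a, b in zip(bounds, bounds[1:]):
            grp = set(positions[a:b])
            members = [tr for tr in cluster if cell_positions[tr.cell] in grp]
            cells = {tr.cell for tr in members}
            events.append(CellEvent(members, cells, classify(len(cells))))
    return events


# --------------------------------------------------------------------------
# skipped cells
# --------------------------------------------------------------------------

def find_skipped_cells(event: CellEvent, all_transients: list[Transient],
                       cell_positions: dict[str, int],
                       amplitude_fraction: float = 0.25,
                       window: float = 2.0) -> list[str]:
    """Cells positionally inside a multiple event's cohort that failed to respond.

    A skipped cell either has no transient in the event window, or responded
    with amplitude below ``amplitude_fraction`` × the cohort's median; in
    both cases it must be active elsewhere in the recording ("not silent").
    """
    positions = {cell_positions[c] for c in event.cells}
    lo, hi = min(positions), max(positions)
    if hi - lo < 2:
        return []
    inv = {v: k for k, v in cell_positions.items()}
    t0, t1 = event.t_start - window, event.t_end + window
    amps = [tr.amplitude for tr in event.transients]
    med = float(np.median(amps)) if amps else 0.0
    skipped = []
    for pos in range(lo + 1, hi):
        cell = inv.get(pos)
        if cell is None:
            continue
        cell_trs = [tr for tr in all_transients if tr.cell == cell]
        in_win = [tr for tr in cell_trs if t0 <= tr.peak_time <= t1]
        reduced = bool(in_win) and max(tr.amplitude for tr in in_win) < amplitude_fraction * med
        absent = not in_win
        if not (absent or reduced):
            continue
        elsewhere = [tr for tr in cell_trs if not (t0 <= tr.peak_time <= t1)]
        if elsewhere:
            skipped.append(cell)
    event.skipped_cells = skipped
    return skipped


# --------------------------------------------------------------------------
# amplitudes by class
# --------------------------------------------------------------------------

def event_amplitude_by_class(events: list[CellEvent]) -> pd.DataFrame:
    """Pool member transient amplitudes by parent-event class (mean ± SD, n)."""
    rows = []
    for cls in ("single", "pair", "multiple"):
        amps = [tr.amplitude for ev in events if ev.event_class == cls
                for tr in ev.transients]
        rows.append({"event_class": cls, "n_transients": len(amps),
                     "amplitude_mean": float(np.mean(amps)) if amps else np.nan,
                     "amplitude_sd": float(np.std(amps, ddof=1)) if len(amps) > 1 else np.nan})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# correlation analysis
# --------------------------------------------------------------------------

def fisher_mean(rs: np.ndarray) -> float:
    """Fisher-z average of correlation coefficients: tanh(mean(arctanh r))."""
    rs = np.clip(np.asarray(rs, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def fisher_sd(rs: np.ndarray) -> float:
    """tanh(SD(arctanh r)), the printed companion to the Fisher average."""
    rs = np.clip(np.asarray(rs, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.std(np.arctanh(rs), ddof=1)))


def correlation_analysis(trace_df: pd.DataFrame, positions: dict[str, float],
                         frame_rate: float, min_overlap_s: float = 300.0,
                         detrend_window_s: float = 30.0,
                         distance_bin_um: float = 10.0,
                         fit_decay: bool = True) -> dict:
    """Pairwise Pearson correlations with Fisher-z summaries and distance decay.

    ``trace_df``: columns = cell identities, rows = aligned samples, NaN
    where a cell is absent; ``positions``: cell -> longitudinal coordinate
    (µm).  Pairs with less than ``min_overlap_s`` of simultaneous recording
    are left undefined (NaN), not zero.  The r-vs-distance curve is the
    Fisher-averaged r in distance bins; optionally an exponential decay
    r(d) = r0·exp(−d/d0) is fitted.
    """
    from .traces import detrend as _detrend

    cells = list(trace_df.columns)
    if len(cells) < 2:
        raise ValueError("correlation analysis needs ≥2 cells")
    det = {}
    for c in cells:
        v = trace_df[c].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        dv = np.full_like(v, np.nan)
        if ok.sum() >= 3:
            dv[ok] = _detrend(v[ok], detrend_window_s, frame_rate)
        det[c] = dv
    min_n = int(round(min_overlap_s * frame_rate))
    n = len(cells)
    r = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = det[cells[i]], det[cells[j]]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < min_n:
                continue
            aa, bb = a[ok], b[ok]
            if aa.std() == 0 or bb.std() == 0:
                continue
            rij = float(np.corrcoef(aa, bb)[0, 1])
            if abs(rij) >= 1.0:
                log.info("correlation_analysis: |r|=1 for (%s, %s), clamped",
                         cells[i], cells[j])
                rij = np.clip(rij, -1 + 1e-12, 1 - 1e-12)
            r[i, j] = r[j, i] = rij
            pairs.append((abs(positions[cells[i]] - positions[cells[j]]), rij))

    rs = np.array([p[1] for p in pairs])
    result = {
        "cells": cells,
        "r_matrix": pd.DataFrame(r, index=cells, columns=cells),
        "r_fisher_mean": fisher_mean(rs) if len(rs) else np.nan,
        "r_fisher_sd": fisher_sd(rs) if len(rs) > 1 else np.nan,
        "n_pairs": len(pairs),
    }
    if pairs:
        d_arr = np.array([p[0] for p in pairs])
        bins = np.arange(0, d_arr.max() + distance_bin_um, distance_bin_um)
        curve = []
        for lo, hi in zip(bins, bins[1:]):
            sel = (d_arr >= lo) & (d_arr < hi)
            if sel.any():
                curve.append({"distance_um": (lo + hi) / 2,
                              "r_mean": fisher_mean(rs[sel]),
                              "n_pairs": int(sel.sum())})
        result["r_vs_distance"] = pd.DataFrame(curve)
        if fit_decay and len(curve) >= 3:
            try:
                cd = result["r_vs_distance"]
                popt, _ = curve_fit(lambda d, r0, d0: r0 * np.exp(-d / d0),
                                    cd["distance_um"], cd["r_mean"],
                                    p0=[max(cd["r_mean"].iloc[0], 0.1), 40.0],
                                    maxfev=10000)
                result["decay_r0"], result["decay_d0_um"] = float(popt[0]), float(popt[1])
            except RuntimeError:
                result["decay_r0"] = result["decay_d0_um"] = np.nan
    return result
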