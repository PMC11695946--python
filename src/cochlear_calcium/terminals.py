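"""SGN afferent-terminal segmentation, IHC assignment, and recruitment stats.

Terminal puncta are segmented from the time-average image (white tophat then
Voronoi–Otsu), assigned to their parent IHC by proximity — falling back to
trace correlation when two IHCs are nearly equidistant — and annotated as
modiolar, pillar or middle from their signed radial coordinate relative to
the IHC row.  Per-IHC terminal traces, merged peaks, recruitment fractions
during single vs multiple IHC events, and the pillar/modiolar side asymmetry
follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import wilcoxon
from skimage.morphology import disk, white_tophat

from .config import TerminalConfig
from .events import CellEvent, Transient
from .geometry import CochlearAxis
from .io_core import FluorescenceTrace, RoiMap
from .segmentation import voronoi_otsu_label

log = logging.getLogger("cochlear_calcium")


@dataclass
class TerminalAssignment:
    terminal: str
    parent_ihc: str
    side: str               # modiolar / pillar / middle
    method: str             # proximity / correlation
    centroid_um: tuple[float, float]


# --------------------------------------------------------------------------

def segment_terminals(mean_image: np.ndarray, tophat_radius: int = 15,
                      spot_sigma: float = 1.5, outline_sigma: float = 1.0,
                      min_area_px: int = 4) -> RoiMap:
    """Segment terminal puncta on a time-average image.

    White-tophat filtering (disc of ``tophat_radius`` px) removes the smooth
    background including cell bodies larger than the structuring element;
    Voronoi–Otsu labelling then separates the remaining bright puncta.
    """
    if not 1 <= tophat_radius:
        raise ValueError("tophat_radius must be positive")
    img = np.asarray(mean_image, dtype=np.float64)
    filtered = white_tophat(img, footprint=disk(tophat_radius))
    labels = voronoi_otsu_label(filtered, spot_sigma, outline_sigma)
    # drop specks
    out = np.zeros_like(labels)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if m.sum() >= min_area_px:
            out[m] = next_id
            next_id += 1
    if next_id == 1:
        log.warning("segment_terminals: no puncta found")
    return RoiMap(out.astype(np.int64),
                  {i: "terminal" for i in range(1, next_id)},
                  {i: f"T{i - 1}" for i in range(1, next_id)})


def roi_centroids_um(rois: RoiMap, pixel_size: float) -> dict[int, tuple[float, float]]:
    cents = ndimage.center_of_mass(np.ones_like(rois.labels), rois.labels, rois.label_ids)
    return {lab: ((c[1] + 0.5) * pixel_size, (c[0] + 0.5) * pixel_size)
            for lab, c in zip(rois.label_ids, cents)}


# --------------------------------------------------------------------------

def assign_terminals(terminal_centroids: dict[str, tuple[float, float]],
                     ihc_centroids: dict[str, tuple[float, float]],
                     terminal_traces: dict[str, np.ndarray] | None = None,
                     ihc_traces: dict[str, np.ndarray] | None = None,
                     ambiguity_margin_um: float = 3.0) -> list[TerminalAssignment]:
    """Assign every terminal to exactly one IHC.

    If the nearest IHC beats the second nearest by more than the ambiguity
    margin the assignment is by proximity; otherwise the terminal goes to
    whichever of the two closest IHCs its trace correlates with best.
    """
    if not ihc_centroids:
        raise ValueError("no IHCs to assign to")
    ihc_ids = sorted(ihc_centroids)
    ihc_xy = np.array([ihc_centroids[i] for i in ihc_ids])
    out = []
    for term, xy in sorted(terminal_centroids.items()):
        d = np.hypot(ihc_xy[:, 0] - xy[0], ihc_xy[:, 1] - xy[1])
        order = np.argsort(d, kind="stable")
        best, second = order[0], (order[1] if len(order) > 1 else order[0])
        if len(order) == 1 or d[second] - d[best] > ambiguity_margin_um:
            out.append(TerminalAssignment(term, ihc_ids[best], "", "proximity", tuple(xy)))
            continue
        # correlation fallback with the two nearest
        if terminal_traces is None or ihc_traces is None:
            out.append(TerminalAssignment(term, ihc_ids[min(best, second)],
                                          "", "proximity", tuple(xy)))
            continue
        tt = terminal_traces[term]
        rs = []
        for cand in (best, second):
            ct = ihc_traces[ihc_ids[cand]]
            n = min(len(tt), len(ct))
            if n < 3 or tt[:n].std() == 0 or ct[:n].std() == 0:
                rs.append(-np.inf)
            else:
                rs.append(float(np.corrcoef(tt[:n], ct[:n])[0, 1]))
        if rs[0] == rs[1]:
            pick = min(best, second)
            log.info("assign_terminals: tie for %s; lower-index IHC chosen", term)
        else:
            pick = (best, second)[int(np.argmax(rs))]
        out.append(TerminalAssignment(term, ihc_ids[pick], "", "correlation", tuple(xy)))
    return out


def classify_side(assignment: TerminalAssignment, axis: CochlearAxis,
                  middle_half_width_um: float = 2.0) -> str:
    """Annotate the terminal's side around the IHC body from its radial coordinate."""
    _, d = axis.project(np.array([assignment.centroid_um]))
    if d[0] > middle_half_width_um:
        side = "modiolar"
    elif d[0] < -middle_half_width_um:
        side = "pillar"
    else:
        side = "middle"
    assignment.side = side
    return side


def assignments_to_table(assignments: list[TerminalAssignment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "terminal": a.terminal, "parent_ihc": a.parent_ihc, "side": a.side,
        "method": a.method, "x_um": a.centroid_um[0], "y_um": a.centroid_um[1],
    } for a in assignments])


# --------------------------------------------------------------------------

def merge_peaks(peak_times: list[float], merge_window_s: float = 1.0) -> list[float]:
    """Single-linkage merge of peaks within the window; returns merged times."""
    if not peak_times:
        return []
    ts = sorted(peak_times)
    merged = [[ts[0]]]
    for t in ts[1:]:
        if t - merged[-1][-1] <= merge_window_s:
            merged[-1].append(t)
        else:
            merged.append([t])
    return [float(np.mean(grp)) for grp in merged]


def per_ihc_terminal_activity(assignments: list[TerminalAssignment],
                              terminal_traces: dict[str, FluorescenceTrace],
                              terminal_transients: dict[str, list[Transient]],
                              merge_window_s: float = 1.0,
                              ) -> dict[str, dict]:
    """Average terminal trace, merged peak list and frequency per IHC.

    Peaks in different terminals of one IHC within 1 s count as the same
    hair-cell peak (single-linkage chaining).
    """
    by_ihc: dict[str, list[str]] = {}
    for a in assignments:
        by_ihc.setdefault(a.parent_ihc, []).append(a.terminal)
    out = {}
    for ihc, terms in sorted(by_ihc.items()):
        traces = [terminal_traces[t] for t in terms if t in terminal_traces]
        if not traces:
            continue
        n = min(len(tr.samples) for tr in traces)
        avg = np.mean([tr.samples[:n] for tr in traces], axis=0)
        peaks = [tr.peak_time for t in terms for tr in terminal_transients.get(t, [])]
        merged = merge_peaks(peaks, merge_window_s)
        dur_min = n / traces[0].frame_rate / 60.0
        out[ihc] = {
            "average_trace": avg,
            "merged_peaks": merged,
            "frequency_per_min": len(merged) / dur_min if dur_min > 0 else np.nan,
            "terminals": sorted(terms),
        }
    return out


# --------------------------------------------------------------------------

def recruitment_analysis(ihc_events: list[CellEvent],
                         terminal_transients: dict[str, list[Transient]],
                         assignments: list[TerminalAssignment],
                         merge_window_s: float = 1.0) -> pd.DataFrame:
    """Fraction of terminals active per IHC event, by event class and side.

    A terminal counts active in an event if it has a transient within the
    event span ± the merge window.  Per event and per participating IHC the
    fractions of total / pillar / modiolar terminals active are computed, as
    well as whether the entire visible pool was recruited.
    """
    by_ihc: dict[str, list[TerminalAssignment]] = {}
    for a in assignments:
        by_ihc.setdefault(a.parent_ihc, []).append(a)
    rows = []
    for k, ev in enumerate(ihc_events):
        t0, t1 = ev.t_start - merge_window_s, ev.t_end + merge_window_s
        for ihc in sorted(ev.cells):
            terms = by_ihc.get(ihc, [])
            if not terms:
                log.info("recruitment_analysis: IHC %s has no visible terminals", ihc)
                continue
            def active(a):
                return any(t0 <= tr.peak_time <= t1
                           for tr in terminal_transients.get(a.terminal, []))
            n_tot = len(terms)
            n_act = sum(active(a) for a in terms)
            pil = [a for a in terms if a.side == "pillar"]
            mod = [a for a in terms if a.side == "modiolar"]
            rows.append({
                "event_id": k, "event_class": ev.event_class, "ihc": ihc,
                "n_terminals": n_tot, "n_active": n_act,
                "frac_total": n_act / n_tot,
                "frac_pillar": (sum(active(a) for a in pil) / len(pil)) if pil else np.nan,
                "frac_modiolar": (sum(active(a) for a in mod) / len(mod)) if mod else np.nan,
                "full_pool": int(n_act == n_tot),
            })
    return pd.DataFrame(rows)


def recruitment_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Class-level means of recruitment fractions and full-pool percentages."""
    if df.empty:
        return pd.DataFrame()
    g = df.groupby("event_class")
    return pd.DataFrame({
        "frac_total_mean": g["frac_total"].mean(),
        "frac_pillar_mean": g["frac_pillar"].mean(),
        "frac_modiolar_mean": g["frac_modiolar"].mean(),
        "pct_full_pool": g["full_pool"].mean() * 100.0,
        "n_event_cells": g.size(),
    }).reset_index()


# --------------------------------------------------------------------------

def side_statistics(per_terminal_freq: dict[str, float],
                    per_terminal_amp: dict[str, float],
                    assignments: list[TerminalAssignment],
                    min_pairs: int = 6) -> dict:
    """Paired pillar-vs-modiolar comparison per IHC (Wilcoxon signed rank).

    Only IHCs possessing terminals on both sides enter; middle terminals are
    excluded from the contrast.  Reports per-IHC side means, the median
    paired difference, and the Wilcoxon p-value when enough pairs exist.
    """
    by_ihc: dict[str, dict[str, list[str]]] = {}
    for a in assignments:
        if a.side in ("pillar", "modiolar"):
            by_ihc.setdefault(a.parent_ihc, {}).setdefault(a.side, []).append(a.terminal)
    freq_pairs, amp_pairs = [], []
    for ihc, sides in sorted(by_ihc.items()):
        if "pillar" not in sides or "modiolar" not in sides:
            continue
        fp = [per_terminal_freq[t] for t in sides["pillar"] if t in per_terminal_freq]
        fm = [per_terminal_freq[t] for t in sides["modiolar"] if t in per_terminal_freq]
        if fp and fm:
            freq_pairs.append((np.mean(fp), np.mean(fm)))
        ap = [per_terminal_amp[t] for t in sides["pillar"] if t in per_terminal_amp]
        am = [per_terminal_amp[t] for t in sides["modiolar"] if t in per_terminal_amp]
        if ap and am:
            amp_pairs.append((np.mean(ap), np.mean(am)))

    def paired_report(pairs):
        if len(pairs) < min_pairs:
            return {"n_pairs": len(pairs), "insufficient_n": True,
                    "median_difference": (float(np.median([p - m for p, m in pairs]))
                                          if pairs else np.nan),
                    "p_value": np.nan}
        diffs = np.array([p - m for p, m in pairs])
        if np.all(diffs == 0):
            return {"n_pairs": len(pairs), "insufficient_n": False,
                    "median_difference": 0.0, "p_value": 1.0}
        stat = wilcoxon(diffs)
        return {"n_pairs": len(pairs), "insufficient_n": False,
                "median_difference": float(np.median(diffs)),
                "p_value": float(stat.pvalue)}

    return {"frequency": paired_report(freq_pairs),
            "amplitude": paired_report(amp_pairs)}
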