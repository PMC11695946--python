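"""Frame quality control and motion handling.

In vivo recordings suffer brief whole-frame artifacts from the animal's
breathing (dimming/defocus, sometimes a small lateral jump) and slow lateral
drift.  The pipeline smooths the stack, finds artifact frame intervals on a
global-mean quality-control trace, substitutes them with the last in-focus
frame (preserving the recording's timing), and removes drift with per-frame
rigid translation by phase correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.registration import phase_cross_correlation

from .config import QCConfig
from .io_core import TimelapseStack

log = logging.getLogger("cochlear_calcium")


@dataclass
class FrameQCReport:
    """Removed frame intervals, how each was found, and its substitution source."""

    removed_intervals: list[tuple[int, int]] = field(default_factory=list)  # half-open
    method_of: dict[tuple[int, int], str] = field(default_factory=dict)     # prominence/template/manual
    substitution_source: dict[tuple[int, int], int] = field(default_factory=dict)

    def validate(self, n_frames: int) -> None:
        prev_end = 0
        for (a, b) in self.removed_intervals:
            if not (0 <= a < b <= n_frames):
                raise ValueError(f"interval [{a},{b}) outside stack range 0..{n_frames}")
            if a < prev_end:
                raise ValueError("removed intervals must be disjoint and sorted")
            prev_end = b

    @property
    def n_removed(self) -> int:
        return sum(b - a for a, b in self.removed_intervals)

    def removed_mask(self, n_frames: int) -> np.ndarray:
        m = np.zeros(n_frames, dtype=bool)
        for a, b in self.removed_intervals:
            m[a:b] = True
        return m

    def to_dict(self) -> dict:
        return {
            "removed_intervals": [list(iv) for iv in self.removed_intervals],
            "method_of": {f"{a},{b}": m for (a, b), m in self.method_of.items()},
            "substitution_source": {f"{a},{b}": s for (a, b), s in
                                    self.substitution_source.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameQCReport":
        ivs = [tuple(iv) for iv in d.get("removed_intervals", [])]
        return cls(
            removed_intervals=ivs,
            method_of={tuple(int(x) for x in k.split(",")): v
                       for k, v in d.get("method_of", {}).items()},
            substitution_source={tuple(int(x) for x in k.split(",")): int(v)
                                 for k, v in d.get("substitution_source", {}).items()},
        )


# --------------------------------------------------------------------------

def smooth_stack(stack: TimelapseStack, sigma: float = 1.0,
                 sigma_t: float = 0.0) -> TimelapseStack:
    """Gaussian smoothing of the stack: σ px spatially, σ_t frames temporally.

    Edge handling uses nearest-replication so the mean intensity is preserved.
    Temporal smoothing defaults to off: it correlates the shot noise into
    bumps wide enough to defeat the 200 ms transient-duration criterion.
    """
    if stack.n_frames < 3:
        raise ValueError("smoothing needs ≥3 frames")
    out = ndimage.gaussian_filter(stack.frames.astype(np.float32),
                                  sigma=(sigma_t, sigma, sigma), mode="nearest")
    log.info("smooth_stack: sigma=(%g,%g,%g) shape=%s", sigma_t, sigma, sigma,
             stack.frames.shape)
    return stack.copy_with(out)


def robust_sd(x: np.ndarray) -> float:
    """1.4826 × median absolute deviation; robust to sparse transients."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def qc_trace(stack: TimelapseStack, qc_roi: np.ndarray | None = None,
             roi_fraction: float = 0.8) -> np.ndarray:
    """Pixel-average trace over the qc ROI (default: central fraction of the field)."""
    if qc_roi is None:
        h, w = stack.frames.shape[1:]
        my, mx = int(h * (1 - roi_fraction) / 2), int(w * (1 - roi_fraction) / 2)
        qc_roi = np.zeros((h, w), dtype=bool)
        qc_roi[my:h - my or None, mx:w - mx or None] = True
    if not qc_roi.any():
        raise ValueError("qc ROI is empty")
    return stack.frames[:, qc_roi].mean(axis=1)


def _peak_intervals(trace: np.ndarray, sign: float, prominence: float) -> list[tuple[int, int]]:
    """Prominent excursions of ``sign*trace`` expanded to full width at base.

    A candidate peak must both be prominent and deviate from the trace median
    by more than the threshold — a dip is an excursion, not merely a ripple.
    """
    peaks, props = find_peaks(sign * trace, prominence=prominence)
    baseline = np.median(sign * trace)
    ivs = []
    for p, lb, rb, prom in zip(peaks, props["left_bases"], props["right_bases"],
                               props["prominences"]):
        if sign * trace[p] - baseline < prominence:
            continue
        # tighten the base to where the excursion exceeds half its prominence,
        # so broad baseline context is not swallowed into the interval
        level = sign * trace[p] - 0.5 * prom
        a = p
        while a > lb and sign * trace[a - 1] > level:
            a -= 1
        b = p
        while b < rb and sign * trace[b + 1] > level:
            b += 1
        ivs.append((int(a), int(b) + 1))
    return ivs


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(iv) for iv in out]


def detect_bad_frames(stack: TimelapseStack, qc_roi: np.ndarray | None = None,
                      prominence_k: float = 4.0,
                      template_bank: list[np.ndarray] | None = None,
                      template_threshold: float = 0.8,
                      manual_list: list[tuple[int, int]] | None = None,
                      detect_positive: bool = False,
                      roi_fraction: float = 0.8) -> FrameQCReport:
    """Find out-of-focus / breathing frame intervals on the qc trace.

    Negative excursions exceeding ``prominence_k`` × robust SD (of the
    first-differenced qc trace) are flagged; positive detection is optional
    because bright Ca²⁺ waves produce genuine positive global excursions.
    Template matches and manual intervals are merged in.
    """
    g = qc_trace(stack, qc_roi, roi_fraction)
    sd = robust_sd(np.diff(g)) / np.sqrt(2.0)
    prom = prominence_k * max(sd, 1e-12)

    found: list[tuple[tuple[int, int], str]] = []
    for iv in _peak_intervals(g, -1.0, prom):
        found.append((iv, "prominence"))
    if detect_positive:
        for iv in _peak_intervals(g, +1.0, prom):
            found.append((iv, "prominence"))

    if template_bank:
        gz = (g - g.mean()) / (g.std() or 1.0)
        for tpl in template_bank:
            tz = (tpl - tpl.mean()) / (tpl.std() or 1.0)
            n = len(tz)
            if n > len(gz):
                continue
            for start in range(len(gz) - n + 1):
                seg = gz[start:start + n]
                denom = np.sqrt((seg ** 2).sum() * (tz ** 2).sum())
                if denom > 0 and float(seg @ tz) / denom >= template_threshold:
                    found.append(((start, start + n), "template"))

    for iv in (manual_list or []):
        found.append(((int(iv[0]), int(iv[1])), "manual"))

    merged = _merge_intervals([iv for iv, _ in found])
    method_of = {}
    for miv in merged:
        methods = {m for iv, m in found if iv[0] < miv[1] and miv[0] < iv[1]}
        for pref in ("manual", "template", "prominence"):
            if pref in methods:
                method_of[miv] = pref
                break

    n = stack.n_frames
    if sum(b - a for a, b in merged) >= n:
        raise ValueError("no in-focus frames left after artifact removal")

    removed = np.zeros(n, dtype=bool)
    for a, b in merged:
        removed[a:b] = True
    report = FrameQCReport(removed_intervals=merged, method_of=method_of)
    for a, b in merged:
        src = a - 1
        while src >= 0 and removed[src]:
            src -= 1
        if src < 0:
            # a leading interval takes the first in-focus frame after it
            src = b
            while src < n and removed[src]:
                src += 1
        report.substitution_source[(a, b)] = int(src)
    report.validate(n)
    log.info("detect_bad_frames: %d intervals, %d/%d frames flagged",
             len(merged), report.n_removed, n)
    return report


def apply_substitution(stack: TimelapseStack, report: FrameQCReport) -> TimelapseStack:
    """Replace each removed frame by its substitution source (timing preserved)."""
    report.validate(stack.n_frames)
    frames = stack.frames.copy()
    for iv in report.removed_intervals:
        frames[iv[0]:iv[1]] = frames[report.substitution_source[iv]]
    return stack.copy_with(frames)


def correct_drift(stack: TimelapseStack, reference: np.ndarray | None = None,
                  max_shift: float = 10.0, upsample: int = 20,
                  ) -> tuple[TimelapseStack, np.ndarray]:
    """Rigid per-frame translation registration by phase correlation.

    Each frame is aligned to the reference (default: frame-average image)
    with subpixel refinement; shifts beyond ``max_shift`` are clamped and
    logged.  The output's global mean is rescaled to match the input's.
    """
    h, w = stack.frames.shape[1:]
    if not max_shift < min(h, w) / 4:
        raise ValueError(f"max_shift {max_shift} too large for a {h}x{w} field")
    ref = stack.frames.mean(axis=0) if reference is None else np.asarray(reference)
    shifts = np.zeros((stack.n_frames, 2))     # estimated (dy, dx) drift per frame
    out = np.empty_like(stack.frames, dtype=np.float64)
    for k in range(stack.n_frames):
        corr, _, _ = phase_cross_correlation(ref, stack.frames[k],
                                             upsample_factor=upsample,
                                             normalization=None)
        drift = -corr
        if np.any(np.abs(drift) > max_shift):
            log.warning("correct_drift: frame %d drift %s clamped to ±%g",
                        k, drift, max_shift)
            drift = np.clip(drift, -max_shift, max_shift)
        shifts[k] = drift
        if np.all(drift == 0):
            out[k] = stack.frames[k]
        else:
            out[k] = ndimage.shift(stack.frames[k].astype(np.float64), -drift,
                                   order=1, mode="nearest")
    mean_in = stack.frames.mean()
    mean_out = out.mean()
    if mean_out > 0:
        out *= mean_in / mean_out
    return stack.copy_with(out), shifts


def preprocess_stack(stack: TimelapseStack, cfg: QCConfig,
                     manual_list: list[tuple[int, int]] | None = None,
                     correct_drift_frames: bool = False,
                     ) -> tuple[TimelapseStack, FrameQCReport, np.ndarray | None]:
    """Detect bad frames → substitute → smooth → (optionally) correct drift.

    Artifact detection and substitution run on the raw stack so the temporal
    Gaussian cannot smear a dimmed frame into its in-focus neighbours.
    """
    report = detect_bad_frames(stack, prominence_k=cfg.prominence_k,
                               template_threshold=cfg.template_threshold,
                               manual_list=manual_list,
                               detect_positive=cfg.detect_positive,
                               roi_fraction=cfg.qc_roi_fraction)
    cleaned = smooth_stack(apply_substitution(stack, report),
                           cfg.smooth_sigma, cfg.smooth_sigma_t)
    shifts = None
    if correct_drift_frames:
        cleaned, shifts = correct_drift(cleaned, max_shift=cfg.max_shift,
                                        upsample=cfg.drift_upsample)
    return cleaned, report, shifts
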