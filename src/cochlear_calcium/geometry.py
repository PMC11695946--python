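"""Cochlear coordinate frame.

The IHC row defines a curvilinear axis along the cochlear spiral.  Positions
in the field of view map to ``(s, d)``: longitudinal arc length along the row
and signed radial distance from it, with ``d > 0`` toward the modiolar side
(the greater epithelial ridge) and ``d < 0`` toward the pillar side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CochlearAxis:
    """Polyline through the IHC row, in µm, with a stated modiolar side."""

    vertices: np.ndarray        # (n, 2) of (x, y) µm
    modiolar_sign: int = 1      # +1: modiolar side is where the segment-normal cross product is positive

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("axis vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 2:
            raise ValueError("axis needs ≥2 vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive axis vertices must be distinct")

    @property
    def segment_lengths(self) -> np.ndarray:
        seg = np.diff(self.vertices, axis=0)
        return np.hypot(seg[:, 0], seg[:, 1])

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (x, y) µm points to (s, d).

        For each point the nearest location on the polyline is found; ``s`` is
        its arc-length coordinate, ``d`` the signed perpendicular distance
        (positive toward the modiolar side).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a = self.vertices[:-1]                    # (m, 2) segment starts
        b = self.vertices[1:]                     # (m, 2) segment ends
        ab = b - a
        ab_len2 = (ab ** 2).sum(axis=1)
        cum = np.concatenate([[0.0], np.cumsum(np.sqrt(ab_len2))])

        # (n, m) parameter of the foot of perpendicular on each segment
        ap = pts[:, None, :] - a[None, :, :]
        t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab_len2[None, :], 0.0, 1.0)
        foot = a[None, :, :] + t[..., None] * ab[None, :, :]
        dist2 = ((pts[:, None, :] - foot) ** 2).sum(axis=2)
        best = np.argmin(dist2, axis=1)
        idx = np.arange(len(pts))
        tb = t[idx, best]
        s = cum[best] + tb * np.sqrt(ab_len2[best])
        # signed distance via the cross product with the segment direction
        seg_dir = ab[best] / np.sqrt(ab_len2[best])[:, None]
        rel = pts - foot[idx, best]
        cross = seg_dir[:, 0] * rel[:, 1] - seg_dir[:, 1] * rel[:, 0]
        d = self.modiolar_sign * np.sign(cross) * np.sqrt(dist2[idx, best])
        d = np.where(dist2[idx, best] == 0, 0.0, d)
        return s, d

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Inverse map: (x, y) on the polyline at arc length ``s`` (clipped)."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        seg_len = self.segment_lengths
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s_arr = np.clip(s_arr, 0.0, cum[-1])
        seg = np.clip(np.searchsorted(cum, s_arr, side="right") - 1, 0, len(seg_len) - 1)
        frac = (s_arr - cum[seg]) / seg_len[seg]
        pts = self.vertices[seg] + frac[:, None] * (self.vertices[seg + 1] - self.vertices[seg])
        return pts if np.ndim(s) else pts[0]

    def normal_at(self, s: float | np.ndarray) -> np.ndarray:
        """Unit normal pointing toward the modiolar side at arc length ``s``."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        seg_len = self.segment_lengths
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        seg = np.clip(np.searchsorted(cum, np.clip(s_arr, 0, cum[-1]), side="right") - 1,
                      0, len(seg_len) - 1)
        d = self.vertices[seg + 1] - self.vertices[seg]
        d = d / np.hypot(d[:, 0], d[:, 1])[:, None]
        # rotate +90°: (dx, dy) -> (-dy, dx); positive cross-product side
        n = np.stack([-d[:, 1], d[:, 0]], axis=1) * self.modiolar_sign
        return n if np.ndim(s) else n[0]

    def flipped(self) -> "CochlearAxis":
        return CochlearAxis(self.vertices.copy(), -self.modiolar_sign)


def read_axis(path: str | Path) -> CochlearAxis:
    df = pd.read_csv(path)
    sign = int(df["modiolar_sign"].iloc[0]) if "modiolar_sign" in df else 1
    return CochlearAxis(df[["x_um", "y_um"]].to_numpy(), sign)


def write_axis(axis: CochlearAxis, path: str | Path) -> None:
    df = pd.DataFrame({"x_um": axis.vertices[:, 0], "y_um": axis.vertices[:, 1]})
    df["modiolar_sign"] = axis.modiolar_sign
    df.to_csv(path, index=False, float_format="%.9g")
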