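"""Core data model and file IO.

Conventions used throughout the package:

* pixel indices are 0-based; ``frames`` are indexed ``(t, y, x)``
* time is in seconds from recording start; intervals are half-open ``[start, end)``
* physical distances are ``pixels * pixel_size`` in µm
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("cochlear_calcium")


@dataclass
class TimelapseStack:
    """A timelapse recording: 3D intensity array plus acquisition metadata."""

    frames: np.ndarray          # (t, y, x), non-negative, finite
    frame_rate: float           # frames / s
    pixel_size: float           # µm / pixel
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (t, y, x), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("≥2 frames required")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def copy_with(self, frames: np.ndarray) -> "TimelapseStack":
        return TimelapseStack(frames, self.frame_rate, self.pixel_size, self.recording_id)


@dataclass
class RoiMap:
    """Labelled regions on the stack's (y, x) grid; 0 is background."""

    labels: np.ndarray                      # 2D int
    class_of: dict[int, str] = field(default_factory=dict)     # label -> IHC/SC/terminal/GER-box
    identity_of: dict[int, str] = field(default_factory=dict)  # label -> persistent identity

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"label image must be 2D, got shape {self.labels.shape}")
        if self.labels.min() < 0:
            raise ValueError("label image contains negative values")

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    @property
    def n_rois(self) -> int:
        return len(self.label_ids)

    def identity(self, label: int) -> str:
        return self.identity_of.get(label, str(label))


@dataclass
class FluorescenceTrace:
    """dF/F0 time series of one cell or terminal."""

    identity: str
    samples: np.ndarray                 # dF/F0, dimensionless
    interpolated_mask: np.ndarray       # True where a removed frame was filled
    frame_rate: float
    start_time: float = 0.0             # s, for stitching

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if self.samples.shape != self.interpolated_mask.shape:
            raise ValueError("interpolated_mask must have the same length as samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.identity} has non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.frame_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.frame_rate


# --------------------------------------------------------------------------
# stacks
# --------------------------------------------------------------------------

def read_stack(path: str | Path, frame_rate: float, pixel_size: float,
               recording_id: str | None = None) -> TimelapseStack:
    """Read a multi-page grayscale TIFF as a :class:`TimelapseStack`.

    Intensities are passed through unscaled; frame order is acquisition order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        raise ValueError("≥2 frames required")
    if frames.ndim != 3:
        raise ValueError(f"expected a multi-page grayscale TIFF, got shape {frames.shape}")
    stack = TimelapseStack(frames, frame_rate, pixel_size,
                           recording_id or path.stem)
    log.info("read_stack %s: shape=%s rate=%g px=%g", path.name, frames.shape,
             frame_rate, pixel_size)
    return stack


def write_stack(stack: TimelapseStack, path: str | Path) -> None:
    tifffile.imwrite(Path(path), stack.frames)


# --------------------------------------------------------------------------
# ROI maps
# --------------------------------------------------------------------------

def read_roi_map(path: str | Path, sidecar: str | Path | None = None) -> RoiMap:
    """Read a 16-bit label TIFF/PNG plus an optional JSON sidecar of classes/identities."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI map not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        labels = iio.imread(path)
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label image contains negative values")
    class_of: dict[int, str] = {}
    identity_of: dict[int, str] = {}
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        class_of = {int(k): v for k, v in meta.get("class_of", {}).items()}
        identity_of = {int(k): v for k, v in meta.get("identity_of", {}).items()}
    return RoiMap(labels.astype(np.int64), class_of, identity_of)


def write_roi_map(rois: RoiMap, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, rois.labels.astype(np.uint16))
    meta = {
        "class_of": {str(k): v for k, v in sorted(rois.class_of.items())},
        "identity_of": {str(k): v for k, v in sorted(rois.identity_of.items())},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

_FLOAT_FORMAT = "%.9g"


def write_table(records: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write a results table as CSV (deterministic float formatting)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def traces_to_table(traces: list[FluorescenceTrace], recording_id: str = "") -> pd.DataFrame:
    """Long-format trace table: recording, cell, time, dff, interpolated."""
    rows = []
    for tr in traces:
        t = tr.times
        rows.append(pd.DataFrame({
            "recording": recording_id,
            "cell": tr.identity,
            "time_s": t,
            "dff": tr.samples,
            "interpolated": tr.interpolated_mask.astype(int),
        }))
    if not rows:
        return pd.DataFrame(columns=["recording", "cell", "time_s", "dff", "interpolated"])
    return pd.concat(rows, ignore_index=True)


def traces_from_table(df: pd.DataFrame, frame_rate: float) -> list[FluorescenceTrace]:
    traces = []
    for cell, grp in df.groupby("cell", sort=True):
        grp = grp.sort_values("time_s")
        traces.append(FluorescenceTrace(
            identity=str(cell),
            samples=grp["dff"].to_numpy(),
            interpolated_mask=grp["interpolated"].to_numpy().astype(bool),
            frame_rate=frame_rate,
            start_time=float(grp["time_s"].iloc[0]),
        ))
    return traces
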