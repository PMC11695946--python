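"""End-to-end pipeline composition.

Thin orchestration over the stage modules so the CLI, the acceptance script
and tests all run the identical code path.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import preprocess as pp
from . import synthetic as syn
from . import terminals as term_mod
from . import traces as tr
from . import waves as wv
from .config import AnalysisConfig
from .geometry import CochlearAxis
from .io_core import RoiMap, TimelapseStack, traces_to_table

log = logging.getLogger("cochlear_calcium")


def simulate_recording(cfg: AnalysisConfig, duration_s: float, seed: int,
                       indicator_kinetics: bool = True):
    """Geometry → schedule → rendered movie with truth sidecar."""
    s = cfg.synthetic
    geometry = syn.generate_geometry(s.n_ihc, s.ihc_spacing_um, s.arc_curvature,
                                     cfg=s, seed=seed)
    schedule = syn.simulate_schedule(geometry, s, duration_s, seed=seed + 1)
    stack, roi_maps, sidecar = syn.render_movie(geometry, schedule, s, seed=seed + 2,
                                                indicator_kinetics=indicator_kinetics)
    return geometry, schedule, stack, roi_maps, sidecar


def ihc_pipeline(stack: TimelapseStack, ihc_rois: RoiMap, cfg: AnalysisConfig,
                 cell_positions: dict[str, int] | None = None,
                 preprocessed: bool = False) -> dict:
    """QC → traces → detrend → transients → events → frequencies/amplitudes."""
    if preprocessed:
        cleaned = stack
        report = pp.FrameQCReport()
    else:
        cleaned, report, _ = pp.preprocess_stack(stack, cfg.qc)
    eroded = tr.erode_rois(ihc_rois, cfg.traces.erosion_radius)
    traces = tr.extract_traces(cleaned, eroded, report,
                               cfg.traces.f0_rule, cfg.traces.f0_percentile)
    detrended = [tr.detrend(t, cfg.traces.detrend_window_s) for t in traces]
    transients: list[ev.Transient] = []
    for t in detrended:
        transients.extend(ev.detect_transients(
            t, cfg.events.min_fdhm_s, cfg.events.amp_k, cfg.events.prominence_k))
    if cell_positions is None:
        # order cells along the image x coordinate of their ROI centroid
        cents = term_mod.roi_centroids_um(eroded, stack.pixel_size)
        ordered = sorted(cents, key=lambda lab: cents[lab][0])
        cell_positions = {eroded.identity(lab): k for k, lab in enumerate(ordered)}
    evs = ev.group_events(transients, cell_positions,
                          cfg.events.window_s, cfg.events.gap_limit,
                          cfg.events.linkage)
    for e in evs:
        if e.event_class == "multiple":
            ev.find_skipped_cells(e, transients, cell_positions,
                                  cfg.events.skipped_amplitude_fraction,
                                  cfg.events.window_s)
    durations = {t.identity: t.duration for t in traces}
    freq = ev.compute_frequency(transients, durations, cfg.events.min_duration_s)
    return {
        "report": report,
        "traces": traces,
        "detrended": detrended,
        "transients": transients,
        "events": evs,
        "frequency": freq,
        "amplitude_by_class": ev.event_amplitude_by_class(evs),
        "cell_positions": cell_positions,
    }


def wave_pipeline(stack: TimelapseStack, axis: CochlearAxis, cfg: AnalysisConfig,
                  preprocessed: bool = False,
                  cell_labels=None) -> dict:
    if not preprocessed:
        stack, _, _ = pp.preprocess_stack(stack, cfg.qc)
    waves, dff = wv.segment_waves(stack, cfg.waves, cell_labels=cell_labels)
    for w in waves:
        wv.quantify_wave(w, axis, dff, cfg.waves.speed_estimator)
    return {
        "waves": waves,
        "dff": dff,
        "table": wv.waves_to_table(waves),
        "frequency_per_min": wv.wave_frequency(waves, stack.duration),
    }


def transients_to_table(transients: list[ev.Transient]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell": t.cell, "peak_time_s": t.peak_time, "amplitude_dff": t.amplitude,
        "prominence_dff": t.prominence, "fdhm_s": t.fdhm,
    } for t in transients])


def events_to_table(evs: list[ev.CellEvent]) -> pd.DataFrame:
    import json
    return pd.DataFrame([{
        "event_id": k, "event_class": e.event_class,
        "t_start_s": e.t_start, "t_end_s": e.t_end,
        "n_cells": len(e.cells),
        "cells": json.dumps(sorted(e.cells)),
        "skipped_cells": json.dumps(sorted(e.skipped_cells)),
    } for k, e in enumerate(evs)])
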