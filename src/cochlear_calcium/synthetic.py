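"""Ground-truthed synthetic GCaMP movies of the immature cochlear epithelium.

The generator builds three layers:

1. :func:`generate_geometry` — a curved row of IHCs with supporting cells in
   the greater epithelial ridge (GER) on the modiolar side and SGN terminal
   puncta around each IHC;
2. :func:`simulate_schedule` — the hidden truth: independent IHC transients
   (Poisson), intercellular Ca²⁺ waves in the GER, coordinated multicell IHC
   events triggered by a fraction of those waves (with lateral spread and
   skipped cells), terminal release events, and breathing-artifact intervals;
3. :func:`render_movie` — a photon-budgeted rasterization of the schedule
   with indicator kinetics, whole-frame dimming artifacts, optional drift and
   Poisson shot noise, plus a JSON-able truth sidecar.

All randomness flows through a single ``numpy`` generator seeded explicitly,
so identical ``(config, seed)`` reproduce the movie bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.signal import lfilter

from .config import SyntheticConfig
from .geometry import CochlearAxis
from .io_core import RoiMap, TimelapseStack


# --------------------------------------------------------------------------
# indicator kernel
# --------------------------------------------------------------------------

def transient_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials impulse response, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    tp = np.clip(t, 0.0, None)
    k = np.where(t >= 0, np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return k / peak


def kernel_fdhm(tau_rise: float, tau_decay: float) -> float:
    """Full duration at half maximum of the normalized kernel."""
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    f = lambda t: transient_kernel(np.array([t]), tau_rise, tau_decay)[0] - 0.5
    t_left = brentq(f, 0.0, t_peak)
    hi = t_peak
    while f(hi) > 0:
        hi += 10 * tau_decay
    t_right = brentq(f, t_peak, hi)
    return t_right - t_left


def decay_for_fdhm(fdhm: float, tau_rise: float) -> float:
    """Solve for the decay constant that yields a given kernel FDHM."""
    f = lambda td: kernel_fdhm(tau_rise, td) - fdhm
    return brentq(f, tau_rise * 1.01, max(100.0 * fdhm, 1.0))


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass
class Terminal:
    terminal_id: int
    parent_ihc: int                 # IHC index
    position: tuple[float, float]   # (x, y) µm
    side: str                       # modiolar / pillar / middle


@dataclass
class EpitheliumGeometry:
    ihc_centroids: np.ndarray       # (n, 2) µm, ordered along the row
    axis: CochlearAxis
    sc_centroids: np.ndarray        # (m, 2) µm in the GER
    terminals: list[Terminal]
    ger_offset: float               # µm, IHC row -> GER near edge
    ger_depth: float                # µm, radial depth of the GER

    @property
    def n_ihc(self) -> int:
        return len(self.ihc_centroids)

    @property
    def ihc_arc_positions(self) -> np.ndarray:
        s, _ = self.axis.project(self.ihc_centroids)
        return s


def generate_geometry(n_ihc: int, spacing: float, arc_curvature: float,
                      cfg: SyntheticConfig | None = None,
                      seed: int = 0) -> EpitheliumGeometry:
    """Lay out a curved IHC row with GER supporting cells and SGN terminals.

    The row follows a circular arc of the given curvature (1/µm); terminal
    counts per IHC follow a clipped normal distribution.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if n_ihc < 2:
        raise ValueError(f"n_ihc must be ≥ 2, got {n_ihc}")
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)

    # arc parameterized by arc length; curvature bends toward the pillar side
    # so the GER (modiolar, +normal) stays on the concave-free side
    arc = np.arange(n_ihc) * spacing
    if arc_curvature == 0:
        xs, ys = arc, np.zeros_like(arc)
    else:
        r = 1.0 / arc_curvature
        theta = arc / r
        xs = r * np.sin(theta)
        ys = -r * (1.0 - np.cos(theta))
    # place in the field with a pillar-side margin for the terminal band
    margin = cfg.terminal_radius_um + 10.0
    pts = np.stack([xs - xs.min() + margin, ys - ys.min() + margin], axis=1)

    axis = CochlearAxis(pts.copy(), modiolar_sign=1)

    # supporting cells: jittered grid filling the GER band
    sc_pts = []
    sc_spacing = 2 * cfg.sc_radius_um
    s_grid = np.arange(0.0, axis.arc_length + 1e-9, sc_spacing * 0.9)
    d_grid = np.arange(cfg.ger_offset_um + cfg.sc_radius_um,
                       cfg.ger_offset_um + cfg.ger_depth_um, sc_spacing * 0.9)
    for d in d_grid:
        for s in s_grid:
            p = axis.point_at(s) + d * axis.normal_at(s)
            sc_pts.append(p + rng.normal(0, 1.0, size=2))
    sc_centroids = np.array(sc_pts) if sc_pts else np.empty((0, 2))

    # terminals: clipped-normal count per IHC, puncta in a band around the cell
    terminals: list[Terminal] = []
    tid = 0
    for i, c in enumerate(pts):
        n_t = int(np.clip(np.rint(rng.normal(cfg.terminal_mean, cfg.terminal_sd)),
                          cfg.terminal_min, cfg.terminal_max))
        s_i, _ = axis.project(c[None, :])
        for _ in range(n_t):
            u = rng.random()
            if u < 0.45:
                side, d = "pillar", -rng.uniform(3.0, cfg.terminal_radius_um)
            elif u < 0.90:
                side, d = "modiolar", rng.uniform(3.0, cfg.terminal_radius_um)
            else:
                side, d = "middle", rng.uniform(-1.5, 1.5)
            s = s_i[0] + rng.uniform(-spacing / 3, spacing / 3)
            p = axis.point_at(float(s)) + d * axis.normal_at(float(s))
            terminals.append(Terminal(tid, i, (float(p[0]), float(p[1])), side))
            tid += 1

    return EpitheliumGeometry(pts, axis, sc_centroids, terminals,
                              cfg.ger_offset_um, cfg.ger_depth_um)


# --------------------------------------------------------------------------
# activity schedule
# --------------------------------------------------------------------------

@dataclass
class WaveRecord:
    wave_id: int
    t_start: float          # s, footprint onset
    origin_s: float         # µm along the axis
    origin_d: float         # µm radial (modiolar positive)
    v_exp: float            # µm/s equivalent-radius expansion speed
    v_con: float            # µm/s contraction speed (magnitude)
    a_long: float           # µm, longitudinal semi-extent at maximum
    b_rad: float            # µm, radial semi-extent at maximum
    duration: float         # s, footprint lifetime (derived from extent and speeds)
    event_id: int | None    # coordinated IHC event initiated by this wave, if any

    @property
    def r_max(self) -> float:
        return float(np.sqrt(self.a_long * self.b_rad))

    @property
    def t_max(self) -> float:
        """Time of maximal expansion."""
        return self.t_start + self.r_max / self.v_exp


@dataclass
class CoordinatedEventRecord:
    event_id: int
    wave_id: int
    cells: list[int]                 # recruited IHC indices (contiguous minus skipped)
    times: dict[int, float]          # cell -> activation time (s)
    skipped: list[int]


@dataclass
class TransientRecord:
    cell: int
    time: float
    amplitude: float                 # dF/F0
    event_id: int | None = None      # None = independent


@dataclass
class TerminalEventRecord:
    terminal_id: int
    time: float
    amplitude: float
    source: str                      # coupled / spontaneous
    parent_event_id: int | None = None


@dataclass
class ArtifactInterval:
    start_frame: int
    end_frame: int                   # half-open
    depth: float                     # multiplicative dimming, frames *= (1 - depth)
    shift_px: int = 0


@dataclass
class ActivitySchedule:
    duration: float
    ihc_transients: list[TransientRecord] = field(default_factory=list)
    waves: list[WaveRecord] = field(default_factory=list)
    events: list[CoordinatedEventRecord] = field(default_factory=list)
    terminal_events: list[TerminalEventRecord] = field(default_factory=list)
    artifacts: list[ArtifactInterval] = field(default_factory=list)
    seed: int = 0

    def transients_of(self, cell: int) -> list[TransientRecord]:
        return [tr for tr in self.ihc_transients if tr.cell == cell]


def _clipped_normal(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def simulate_schedule(geometry: EpitheliumGeometry, cfg: SyntheticConfig,
                      duration: float, seed: int = 0) -> ActivitySchedule:
    """Draw the hidden activity truth for one recording of ``duration`` seconds."""
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if not 0 <= cfg.p_skip <= 1:
        raise ValueError(f"p_skip must lie in [0, 1], got {cfg.p_skip}")
    if not 0 <= cfg.p_reach <= 1:
        raise ValueError(f"p_reach must lie in [0, 1], got {cfg.p_reach}")
    rng = np.random.default_rng(seed)
    sched = ActivitySchedule(duration=duration, seed=seed)
    n = geometry.n_ihc
    s_ihc = geometry.ihc_arc_positions
    order = np.argsort(s_ihc)

    # --- independent IHC transients (homogeneous Poisson per cell) ---------
    lam = cfg.lambda_ind_per_min / 60.0
    for cell in range(n):
        k = rng.poisson(lam * duration)
        for t in np.sort(rng.uniform(0, duration, size=k)):
            amp = cfg.amp_single * np.exp(rng.normal(0, 0.2))
            sched.ihc_transients.append(TransientRecord(cell, float(t), float(amp)))

    # --- GER waves ---------------------------------------------------------
    n_waves = rng.poisson(cfg.wave_rate_per_min / 60.0 * duration)
    t_waves = np.sort(rng.uniform(0, duration, size=n_waves))
    event_id = 0
    for wid, t0 in enumerate(t_waves):
        a_long = float(_clipped_normal(rng, cfg.wave_a_long_um, cfg.wave_a_long_sd_um,
                                       6.0, 3 * cfg.wave_a_long_um))
        b_rad = a_long / cfg.wave_aspect
        v_exp = float(_clipped_normal(rng, cfg.v_exp_um_s, cfg.v_exp_um_s * 0.35, 6.0, 60.0))
        v_con = float(_clipped_normal(rng, cfg.v_con_um_s, cfg.v_con_um_s * 0.35, 4.0, 45.0))
        r_max = float(np.sqrt(a_long * b_rad))
        dur = r_max * (1.0 / v_exp + 1.0 / v_con)
        origin_s = float(rng.uniform(0, geometry.axis.arc_length))
        # most waves originate close to the sensory cells
        origin_d = float(np.clip(geometry.ger_offset + abs(rng.normal(0, 8.0)),
                                 geometry.ger_offset,
                                 geometry.ger_offset + geometry.ger_depth - b_rad / 2))
        reached = rng.random() < cfg.p_reach
        eid = None
        if reached:
            eid = event_id
            event_id += 1
        sched.waves.append(WaveRecord(wid, float(t0), origin_s, origin_d,
                                      v_exp, v_con, a_long, b_rad, dur, eid))

    # --- coordinated IHC events from reaching waves -------------------------
    for wave in sched.waves:
        if wave.event_id is None:
            continue
        cohort_size = int(np.clip(np.rint(rng.normal(cfg.cohort_mean, cfg.cohort_sd)),
                                  cfg.cohort_min, min(cfg.cohort_max, n)))
        seed_cell = int(order[np.argmin(np.abs(s_ihc[order] - wave.origin_s))])
        seed_rank = int(np.where(order == seed_cell)[0][0])
        lo = max(0, min(seed_rank - cohort_size // 2, n - cohort_size))
        cohort = [int(order[r]) for r in range(lo, lo + cohort_size)]
        # wave must first travel radially from its origin to the row
        t_arrive = wave.t_start + max(wave.origin_d, 0.0) / wave.v_exp
        times = {}
        for cell in cohort:
            dt = abs(s_ihc[cell] - s_ihc[seed_cell]) / cfg.v_ihc_um_s
            times[cell] = float(t_arrive + dt + abs(rng.normal(0, 0.05)))
        # internal cells may be skipped: no transient despite lying in the cohort
        internal = cohort[1:-1]
        skipped = [c for c in internal if rng.random() < cfg.p_skip]
        active = [c for c in cohort if c not in skipped]
        if len(active) < 2:
            active = cohort[:2]
            skipped = [c for c in cohort if c not in active]
        rec = CoordinatedEventRecord(wave.event_id, wave.wave_id, active,
                                     {c: times[c] for c in active}, skipped)
        sched.events.append(rec)
        for cell in active:
            if times[cell] < duration:
                amp = cfg.amp_single * cfg.amp_coordinated_scale * np.exp(rng.normal(0, 0.2))
                sched.ihc_transients.append(
                    TransientRecord(cell, times[cell], float(amp), wave.event_id))

    sched.ihc_transients.sort(key=lambda tr: (tr.time, tr.cell))

    # --- terminal activity ---------------------------------------------------
    by_parent: dict[int, list[Terminal]] = {}
    for term in geometry.terminals:
        by_parent.setdefault(term.parent_ihc, []).append(term)
    for tr in sched.ihc_transients:
        p = cfg.p_terminal_multiple if tr.event_id is not None else cfg.p_terminal_single
        for term in by_parent.get(tr.cell, []):
            if rng.random() < p:
                amp = cfg.terminal_amp * np.exp(rng.normal(0, 0.2))
                t = tr.time + abs(rng.normal(0, 0.05))
                if t < duration:
                    sched.terminal_events.append(TerminalEventRecord(
                        term.terminal_id, float(t), float(amp), "coupled", tr.event_id))
    # sporadic terminal-only transients, pillar side more active
    for term in geometry.terminals:
        lam_t = {"pillar": cfg.lambda_term_pillar_per_min,
                 "modiolar": cfg.lambda_term_modiolar_per_min}.get(
            term.side, 0.5 * (cfg.lambda_term_pillar_per_min + cfg.lambda_term_modiolar_per_min))
        k = rng.poisson(lam_t / 60.0 * duration)
        for t in rng.uniform(0, duration, size=k):
            amp_scale = 1.3 if term.side == "pillar" else 1.0
            amp = cfg.terminal_amp * amp_scale * np.exp(rng.normal(0, 0.2))
            sched.terminal_events.append(TerminalEventRecord(
                term.terminal_id, float(t), float(amp), "spontaneous", None))
    sched.terminal_events.sort(key=lambda te: (te.time, te.terminal_id))

    # --- breathing artifact bouts -------------------------------------------
    n_frames = int(round(duration * cfg.frame_rate))
    n_bouts = rng.poisson(cfg.artifact_rate_per_min / 60.0 * duration)
    occupied = np.zeros(n_frames, dtype=bool)
    for _ in range(n_bouts):
        length = int(rng.integers(cfg.artifact_len_frames[0], cfg.artifact_len_frames[1] + 1))
        if n_frames <= length + 2:
            continue
        start = int(rng.integers(1, n_frames - length - 1))
        if occupied[max(0, start - 2):start + length + 2].any():
            continue
        occupied[start:start + length] = True
        depth = float(rng.uniform(*cfg.artifact_depth_range))
        sched.artifacts.append(ArtifactInterval(start, start + length, depth))
    sched.artifacts.sort(key=lambda a: a.start_frame)
    return sched


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _activity_trace(times_amps: list[tuple[float, float]], t: np.ndarray,
                    tau_rise: float, tau_decay: float) -> np.ndarray:
    a = np.zeros_like(t)
    for t0, amp in times_amps:
        a += amp * transient_kernel(t - t0, tau_rise, tau_decay)
    return a


def _disc_mask(shape, center_px, radius_px):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2 <= radius_px ** 2


def render_movie(geometry: EpitheliumGeometry, schedule: ActivitySchedule,
                 cfg: SyntheticConfig, seed: int = 0,
                 indicator_kinetics: bool = True,
                 ) -> tuple[TimelapseStack, dict[str, RoiMap], dict]:
    """Rasterize a schedule into a GCaMP-like movie.

    Returns the stack, ground-truth ROI maps (``ihc``, ``terminal``, ``sc``)
    and a JSON-able truth sidecar.  With ``indicator_kinetics=False`` wave
    footprints are rendered instantaneously (no indicator convolution), which
    isolates geometric/kinetic estimators from indicator decay.
    """
    if cfg.fdhm_s < 2.0 / cfg.frame_rate:
        raise ValueError("kernel FDHM shorter than 2 frame periods is unresolvable")
    tau_decay = decay_for_fdhm(cfg.fdhm_s, cfg.tau_rise_s)
    px = cfg.pixel_size_um
    rng = np.random.default_rng(seed)

    # canvas from content bounds
    all_pts = [geometry.ihc_centroids, geometry.axis.vertices]
    if len(geometry.sc_centroids):
        all_pts.append(geometry.sc_centroids)
    if geometry.terminals:
        all_pts.append(np.array([t.position for t in geometry.terminals]))
    pts = np.vstack(all_pts)
    margin = 8.0
    w = int(np.ceil((pts[:, 0].max() + margin) / px))
    h = int(np.ceil((pts[:, 1].max() + margin) / px))

    def to_px(p):
        return (p[1] / px, p[0] / px)   # (row, col)

    # ---- baseline image and label maps -----------------------------------
    base = np.full((h, w), cfg.baseline_bg, dtype=np.float64)
    ihc_labels = np.zeros((h, w), dtype=np.int32)
    term_labels = np.zeros((h, w), dtype=np.int32)
    sc_mask = np.zeros((h, w), dtype=bool)

    for i, c in enumerate(geometry.ihc_centroids):
        m = _disc_mask((h, w), to_px(c), cfg.ihc_radius_um / px)
        base[m] = cfg.baseline_ihc
        ihc_labels[m] = i + 1
    for c in geometry.sc_centroids:
        m = _disc_mask((h, w), to_px(c), cfg.sc_radius_um / px)
        m &= ihc_labels == 0
        base[m] = np.maximum(base[m], cfg.baseline_sc)
        sc_mask |= m
    yy, xx = np.mgrid[:h, :w]
    for term in geometry.terminals:
        r0, c0 = to_px(term.position)
        sig = 1.2 / px
        spot = np.exp(-(((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sig ** 2)))
        base += cfg.baseline_terminal * spot * (ihc_labels == 0)
        term_labels[((yy - r0) ** 2 + (xx - c0) ** 2 <= (1.5 / px) ** 2)
                    & (ihc_labels == 0)] = term.terminal_id + 1

    n_frames = int(round(schedule.duration * cfg.frame_rate))
    t = np.arange(n_frames) / cfg.frame_rate
    movie = np.repeat(base[None, :, :].astype(np.float32), n_frames, axis=0)

    # ---- IHC and terminal transients (multiplicative dF/F on cell pixels) --
    by_cell: dict[int, list[tuple[float, float]]] = {}
    for tr in schedule.ihc_transients:
        by_cell.setdefault(tr.cell, []).append((tr.time, tr.amplitude))
    for cell, ta in by_cell.items():
        m = ihc_labels == cell + 1
        if not m.any():
            continue
        a = _activity_trace(ta, t, cfg.tau_rise_s, tau_decay)
        movie[:, m] *= (1.0 + a)[:, None]

    by_term: dict[int, list[tuple[float, float]]] = {}
    for te in schedule.terminal_events:
        by_term.setdefault(te.terminal_id, []).append((te.time, te.amplitude))
    for tid, ta in by_term.items():
        m = term_labels == tid + 1
        if not m.any():
            continue
        a = _activity_trace(ta, t, cfg.tau_rise_s, tau_decay)
        movie[:, m] *= (1.0 + a)[:, None]

    # ---- GER waves ---------------------------------------------------------
    # precompute the (s, d) coordinate images once
    coords_um = np.stack([xx.ravel() * px, yy.ravel() * px], axis=1)
    s_img, d_img = geometry.axis.project(coords_um)
    s_img = s_img.reshape(h, w)
    d_img = d_img.reshape(h, w)
    wave_zone = d_img > cfg.ihc_radius_um      # waves live modiolar of the row

    tau_w = cfg.wave_tau_decay_s
    for wave in schedule.waves:
        t_end = wave.t_start + wave.duration
        pad = 5 * tau_w if indicator_kinetics else 0.0
        f0 = max(0, int(np.floor(wave.t_start * cfg.frame_rate)))
        f1 = min(n_frames, int(np.ceil((t_end + pad) * cfg.frame_rate)) + 1)
        if f1 <= f0:
            continue
        center = geometry.axis.point_at(wave.origin_s) + \
            wave.origin_d * geometry.axis.normal_at(wave.origin_s)
        # bounding box in px with a safety margin
        rmax_um = max(wave.a_long, wave.b_rad) + 4 * cfg.wave_edge_um
        r0 = max(0, int((center[1] - rmax_um) / px)); r1 = min(h, int((center[1] + rmax_um) / px) + 1)
        c0 = max(0, int((center[0] - rmax_um) / px)); c1 = min(w, int((center[0] + rmax_um) / px) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        sub_s = s_img[r0:r1, c0:c1] - wave.origin_s
        sub_d = d_img[r0:r1, c0:c1] - wave.origin_d
        fa = np.sqrt(wave.a_long / wave.b_rad)
        frames_idx = np.arange(f0, f1)
        tt = frames_idx / cfg.frame_rate
        # equivalent radius over time: expand then contract
        r_eq = np.where(tt < wave.t_start + wave.r_max / wave.v_exp,
                        wave.v_exp * (tt - wave.t_start),
                        wave.r_max - wave.v_con * (tt - wave.t_start - wave.r_max / wave.v_exp))
        r_eq = np.clip(r_eq, 0.0, None)
        foot = np.zeros((len(frames_idx),) + sub_s.shape)
        for k, r in enumerate(r_eq):
            if r <= 0:
                continue
            a, b = fa * r, r / fa
            e = np.sqrt((sub_s / a) ** 2 + (sub_d / b) ** 2)
            # plateau inside the ellipse, Gaussian rim outside
            rim = np.maximum(e - 1.0, 0.0) * r
            foot[k] = np.exp(-0.5 * (rim / cfg.wave_edge_um) ** 2)
        if indicator_kinetics:
            # causal exponential release of the indicator, unit-area kernel
            nk = int(np.ceil(5 * tau_w * cfg.frame_rate)) + 1
            kk = np.exp(-np.arange(nk) / (tau_w * cfg.frame_rate))
            kk /= kk.sum()
            foot = lfilter(kk, [1.0], foot, axis=0)
        sig = cfg.wave_amp * foot * wave_zone[r0:r1, c0:c1]
        movie[f0:f1, r0:r1, c0:c1] *= (1.0 + sig)

    # ---- artifacts ---------------------------------------------------------
    for art in schedule.artifacts:
        a0, a1 = max(0, art.start_frame), min(n_frames, art.end_frame)
        movie[a0:a1] *= (1.0 - art.depth)
        if art.shift_px:
            movie[a0:a1] = np.roll(movie[a0:a1], art.shift_px, axis=2)

    # ---- drift -------------------------------------------------------------
    drift_path = np.zeros((n_frames, 2))
    if cfg.drift_amplitude_px > 0:
        drift_path[:, 1] = cfg.drift_amplitude_px * np.sin(2 * np.pi * t / cfg.drift_period_s)
        drift_path[:, 0] = 0.5 * cfg.drift_amplitude_px * (1 - np.cos(2 * np.pi * t / cfg.drift_period_s))
        for k in range(n_frames):
            if np.any(drift_path[k] != 0):
                movie[k] = ndimage.shift(movie[k], drift_path[k], order=1, mode="nearest")

    # ---- shot noise --------------------------------------------------------
    if cfg.photon_gain > 0:
        for k in range(0, n_frames, 256):       # chunked to bound peak memory
            blk = np.clip(movie[k:k + 256], 0, None) / cfg.photon_gain
            movie[k:k + 256] = rng.poisson(blk) * cfg.photon_gain
    movie = movie.astype(np.float32)

    stack = TimelapseStack(movie, cfg.frame_rate, px, recording_id=f"synthetic-{seed}")
    roi_maps = {
        "ihc": RoiMap(ihc_labels,
                      {i + 1: "IHC" for i in range(geometry.n_ihc)},
                      {i + 1: f"IHC{i}" for i in range(geometry.n_ihc)}),
        "terminal": RoiMap(term_labels,
                           {t_.terminal_id + 1: "terminal" for t_ in geometry.terminals},
                           {t_.terminal_id + 1: f"T{t_.terminal_id}" for t_ in geometry.terminals}),
        "sc": RoiMap(sc_mask.astype(np.int32), {1: "GER-box"}, {1: "GER"}),
    }
    sidecar = schedule_to_dict(geometry, schedule)
    return stack, roi_maps, sidecar


# --------------------------------------------------------------------------
# schedule-level trace rendering (no rasterization)
# --------------------------------------------------------------------------

def render_traces(geometry: EpitheliumGeometry, schedule: ActivitySchedule,
                  cfg: SyntheticConfig, noise_sd: float = 0.0, seed: int = 0,
                  ) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray], np.ndarray]:
    """Kernel-rendered per-IHC and per-terminal dF/F0 traces.

    A fast alternative to pixel rendering for statistics that only need
    traces; returns (ihc traces, terminal traces, time vector).
    """
    tau_decay = decay_for_fdhm(cfg.fdhm_s, cfg.tau_rise_s)
    n_frames = int(round(schedule.duration * cfg.frame_rate))
    t = np.arange(n_frames) / cfg.frame_rate
    rng = np.random.default_rng(seed)
    ihc = {}
    for cell in range(geometry.n_ihc):
        ta = [(tr.time, tr.amplitude) for tr in schedule.ihc_transients if tr.cell == cell]
        tr_arr = _activity_trace(ta, t, cfg.tau_rise_s, tau_decay)
        if noise_sd > 0:
            tr_arr = tr_arr + rng.normal(0, noise_sd, size=n_frames)
        ihc[cell] = tr_arr
    term = {}
    for terminal in geometry.terminals:
        ta = [(te.time, te.amplitude) for te in schedule.terminal_events
              if te.terminal_id == terminal.terminal_id]
        tr_arr = _activity_trace(ta, t, cfg.tau_rise_s, tau_decay)
        if noise_sd > 0:
            tr_arr = tr_arr + rng.normal(0, noise_sd, size=n_frames)
        term[terminal.terminal_id] = tr_arr
    return ihc, term, t


# --------------------------------------------------------------------------
# sidecar serialization
# --------------------------------------------------------------------------

def schedule_to_dict(geometry: EpitheliumGeometry, schedule: ActivitySchedule) -> dict:
    return {
        "duration": schedule.duration,
        "seed": schedule.seed,
        "ihc_centroids": geometry.ihc_centroids.tolist(),
        "axis_vertices": geometry.axis.vertices.tolist(),
        "modiolar_sign": geometry.axis.modiolar_sign,
        "terminals": [dataclasses.asdict(t) for t in geometry.terminals],
        "ihc_transients": [dataclasses.asdict(tr) for tr in schedule.ihc_transients],
        "waves": [dataclasses.asdict(w) for w in schedule.waves],
        "events": [{**dataclasses.asdict(e),
                    "times": {str(k): v for k, v in e.times.items()}}
                   for e in schedule.events],
        "terminal_events": [dataclasses.asdict(te) for te in schedule.terminal_events],
        "artifacts": [dataclasses.asdict(a) for a in schedule.artifacts],
    }


def write_sidecar(sidecar: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
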