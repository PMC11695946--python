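import numpy as np
import pytest

from cochlear_calcium import synthetic as syn
from cochlear_calcium import waves as wv
from cochlear_calcium.config import WaveConfig
from cochlear_calcium.events import CellEvent, Transient
from cochlear_calcium.geometry import CochlearAxis
from cochlear_calcium.io_core import TimelapseStack


def _render_wave_movie(geometry, cfg, wave, duration=30.0):
    """Noise-free movie containing exactly the given wave record."""
    sched = syn.ActivitySchedule(duration=duration)
    sched.waves.append(wave)
    stack, _, _ = syn.render_movie(geometry, sched, cfg, seed=0,
                                   indicator_kinetics=False)
    return stack


def _truth_voxels(geometry, cfg, wave, stack, bin_factor):
    """Analytic binned voxel set of the wave footprint (plateau region)."""
    h = stack.frames.shape[1] // bin_factor
    w = stack.frames.shape[2] // bin_factor
    bpx = bin_factor * stack.pixel_size
    yy, xx = np.mgrid[:h, :w]
    pts = np.stack([(xx.ravel() + 0.5) * bpx, (yy.ravel() + 0.5) * bpx], axis=1)
    s, d = geometry.axis.project(pts)
    s = s.reshape(h, w) - wave.origin_s
    dd = d.reshape(h, w)
    rel_d = dd - wave.origin_d
    zone = dd > cfg.ihc_radius_um
    fa = np.sqrt(wave.a_long / wave.b_rad)
    vox = set()
    for f in range(stack.n_frames):
        t = f / cfg.frame_rate
        if t < wave.t_start or t > wave.t_start + wave.duration:
            continue
        te = t - wave.t_start
        r = min(wave.v_exp * te, wave.r_max - wave.v_con * (te - wave.r_max / wave.v_exp)
                if te > wave.r_max / wave.v_exp else wave.v_exp * te)
        if r <= 0:
            continue
        e = np.sqrt((s / (fa * r)) ** 2 + (rel_d / (r / fa)) ** 2)
        for (iy, ix) in np.argwhere((e <= 1) & zone):
            vox.add((f, iy, ix))
    return vox


@pytest.fixture
def wave_setup(quiet_synth, small_geometry):
    cfg = quiet_synth
    cfg.wave_edge_um = 0.3          # sharp rim for geometric truth
    return cfg, small_geometry


class TestSegmentWaves:
    def test_single_wave_one_object_jaccard(self, wave_setup):
        cfg, geom = wave_setup
        wave = syn.WaveRecord(0, 5.0, geom.axis.arc_length / 2, 22.0,
                              v_exp=22.0, v_con=15.0, a_long=17.0, b_rad=7.0,
                              duration=np.sqrt(17 * 7) * (1 / 22 + 1 / 15),
                              event_id=None)
        stack = _render_wave_movie(geom, cfg, wave)
        waves, dff = wv.segment_waves(stack, WaveConfig())
        assert len(waves) == 1
        got = {tuple(v) for v in waves[0].voxels}
        truth = _truth_voxels(geom, cfg, wave, stack, 2)
        jac = len(got & truth) / len(got | truth)
        assert jac >= 0.7

    def test_two_distant_waves_two_objects(self, wave_setup):
        cfg, geom = wave_setup
        sched = syn.ActivitySchedule(duration=20.0)
        for origin_s in (5.0, geom.axis.arc_length - 5.0):   # ~53 µm apart
            sched.waves.append(syn.WaveRecord(
                len(sched.waves), 5.0, origin_s, 22.0, 25.0, 18.0,
                a_long=8.0, b_rad=5.0, duration=0.8, event_id=None))
        stack, _, _ = syn.render_movie(geom, sched, cfg, seed=0,
                                       indicator_kinetics=False)
        waves, _ = wv.segment_waves(stack, WaveConfig())
        assert len(waves) == 2

    def test_single_cell_blob_excluded(self, wave_setup):
        """A transient confined to one cell-sized footprint is not a wave."""
        cfg, geom = wave_setup
        wave = syn.WaveRecord(0, 5.0, geom.axis.arc_length / 2, 22.0,
                              v_exp=22.0, v_con=15.0, a_long=4.0, b_rad=4.0,
                              duration=4.0 * (1 / 22 + 1 / 15), event_id=None)
        stack = _render_wave_movie(geom, cfg, wave)
        waves, _ = wv.segment_waves(stack, WaveConfig())
        assert waves == []

    def test_empty_stack_warns_empty(self, quiet_synth, small_geometry):
        sched = syn.ActivitySchedule(duration=10.0)
        stack, _, _ = syn.render_movie(small_geometry, sched, quiet_synth, seed=0)
        waves, _ = wv.segment_waves(stack, WaveConfig())
        assert waves == []

    def test_translation_equivariance(self, wave_setup):
        cfg, geom = wave_setup
        wave = syn.WaveRecord(0, 3.0, geom.axis.arc_length / 2, 22.0,
                              22.0, 15.0, 12.0, 6.0,
                              duration=np.sqrt(72) * (1 / 22 + 1 / 15), event_id=None)
        stack = _render_wave_movie(geom, cfg, wave, duration=15.0)
        shifted = TimelapseStack(np.roll(stack.frames, 4, axis=1),
                                 stack.frame_rate, stack.pixel_size)
        w1, _ = wv.segment_waves(stack, WaveConfig())
        w2, _ = wv.segment_waves(shifted, WaveConfig())
        assert len(w1) == len(w2) == 1
        v1 = {tuple(v) for v in w1[0].voxels}
        v2 = {(t, y - 2, x) for (t, y, x) in {tuple(v) for v in w2[0].voxels}}
        jac = len(v1 & v2) / len(v1 | v2)
        assert jac > 0.9


class TestQuantifyWave:
    def test_ellipse_extents_and_centroid(self, wave_setup):
        cfg, geom = wave_setup
        d0 = 22.0
        wave = syn.WaveRecord(0, 5.0, geom.axis.arc_length / 2, d0,
                              v_exp=22.0, v_con=15.0, a_long=17.0, b_rad=7.0,
                              duration=np.sqrt(17 * 7) * (1 / 22 + 1 / 15),
                              event_id=None)
        stack = _render_wave_movie(geom, cfg, wave)
        waves, dff = wv.segment_waves(stack, WaveConfig())
        w = wv.quantify_wave(waves[0], geom.axis, dff)
        bpx = 2 * stack.pixel_size
        assert w.longitudinal_extent == pytest.approx(34.0, abs=bpx + 1.0)
        assert w.radial_extent == pytest.approx(14.0, abs=bpx + 1.0)
        assert w.centroid_distance == pytest.approx(d0, abs=bpx)
        assert w.max_area == pytest.approx(np.pi * 17 * 7, rel=0.15)

    def test_disc_growth_speed_recovery(self, wave_setup):
        """Disc grown at 22 µm/s and contracted at 15 µm/s → speeds within 5%."""
        cfg, geom = wave_setup
        wave = syn.WaveRecord(0, 2.0, geom.axis.arc_length / 2, 24.0,
                              v_exp=22.0, v_con=15.0, a_long=15.0, b_rad=15.0,
                              duration=15.0 * (1 / 22 + 1 / 15), event_id=None)
        stack = _render_wave_movie(geom, cfg, wave, duration=10.0)
        waves, dff = wv.segment_waves(stack, WaveConfig())
        assert len(waves) == 1
        w = wv.quantify_wave(waves[0], geom.axis, dff)
        assert w.expansion_speed == pytest.approx(22.0, rel=0.05)
        assert w.contraction_speed == pytest.approx(15.0, rel=0.05)

    def test_fdhm_skipped_when_truncated(self):
        vox = np.array([(0, 5, 5), (0, 5, 6), (1, 5, 5)])
        w = wv.WaveObject(0, vox, 2, 1.0, 10.0, boundary_truncated=True)
        axis = CochlearAxis(np.array([[0.0, 0.0], [100.0, 0.0]]))
        wv.quantify_wave(w, axis, dff=np.zeros((5, 10, 10)))
        assert w.fdhm is None


class TestWaveFrequency:
    def _wave(self, wid, truncated=False):
        vox = np.array([(2 + wid, 5, 5), (3 + wid, 5, 5)])
        return wv.WaveObject(wid, vox, 2, 1.0, 10.0, boundary_truncated=truncated)

    def test_simple_rate(self):
        waves = [self._wave(i) for i in range(5)]
        assert wv.wave_frequency(waves, 600.0) == pytest.approx(0.5)

    def test_truncated_counts_toward_frequency_not_fdhm(self):
        waves = [self._wave(0), self._wave(1, truncated=True)]
        assert wv.wave_frequency(waves, 60.0) == pytest.approx(2.0)
        table = wv.waves_to_table(waves)
        assert len(table) == 2
        axis = CochlearAxis(np.array([[0.0, 0.0], [100.0, 0.0]]))
        for w in waves:
            wv.quantify_wave(w, axis, np.random.default_rng(0).random((10, 10, 10)))
        table = wv.waves_to_table(waves)
        assert np.isnan(table.loc[table.boundary_truncated == 1, "fdhm_s"]).all()

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            wv.wave_frequency([], 0.0)


class TestKymograph:
    def _line(self):
        return CochlearAxis(np.array([[5.0, 20.0], [95.0, 20.0]]))

    def test_static_image_rows_identical(self):
        frames = np.tile(np.random.default_rng(0).random((40, 100)) * 50, (6, 1, 1))
        kymo = wv.build_kymograph(TimelapseStack(frames, 10.0, 1.0), self._line())
        for r in range(1, 6):
            np.testing.assert_allclose(kymo.data[r], kymo.data[0])

    def test_column_count(self):
        frames = np.zeros((3, 40, 100))
        kymo = wv.build_kymograph(TimelapseStack(frames, 10.0, 1.0), self._line(),
                                  step_um=1.0)
        assert kymo.data.shape[1] == int(np.floor(90.0 / 1.0)) + 1

    def test_moving_bar_ridge_speed(self):
        """A bright bar sweeping at 60 µm/s reads out as a ~60 µm/s ridge."""
        rate, speed = 20.0, 60.0
        frames = np.zeros((60, 40, 200))
        for k in range(60):
            x = int(10 + speed * k / rate)
            frames[k, :, max(0, x - 2):x + 3] = 100.0
        line = CochlearAxis(np.array([[0.0, 20.0], [199.0, 20.0]]))
        kymo = wv.build_kymograph(TimelapseStack(frames, rate, 1.0), line)
        v = wv.measure_kymo_speed(kymo, (0.0, 3.0), (0.0, 199.0))
        assert v == pytest.approx(speed, rel=0.10)

    def test_ridge_20um_in_1s(self):
        rate = 10.0
        frames = np.zeros((30, 20, 60))
        for k in range(10):
            x = 10 + 2 * k               # 2 µm/frame at 10 fps = 20 µm/s
            frames[k + 5, :, x] = 100.0
        line = CochlearAxis(np.array([[0.0, 10.0], [59.0, 10.0]]))
        kymo = wv.build_kymograph(TimelapseStack(frames, rate, 1.0), line,
                                  half_width_px=2)
        v = wv.measure_kymo_speed(kymo, (0.0, 3.0), (0.0, 59.0))
        assert v == pytest.approx(20.0, rel=0.15)

    def test_stationary_blob_zero_speed(self):
        frames = np.zeros((20, 20, 60))
        frames[5:15, :, 30] = 100.0
        line = CochlearAxis(np.array([[0.0, 10.0], [59.0, 10.0]]))
        kymo = wv.build_kymograph(TimelapseStack(frames, 10.0, 1.0), line)
        assert wv.measure_kymo_speed(kymo, (0.0, 2.0), (0.0, 59.0)) == 0.0


class TestMatchWaves:
    def _wave(self, onset_frame, centroid_d=10.0, extent=30.0):
        vox = np.array([(onset_frame, 5, 5), (onset_frame + 1, 5, 5)])
        w = wv.WaveObject(0, vox, 2, 1.0, 10.0)
        w.centroid_distance = centroid_d
        w.longitudinal_extent = extent
        return w

    def _event(self, t0, cells):
        trs = [Transient(c, t0 + 0.1 * k, 0.5, 0.5, 1.0)
               for k, c in enumerate(cells)]
        from cochlear_calcium.events import classify
        return CellEvent(trs, set(cells), classify(len(cells)))

    def test_unmatched_wave_recorded(self):
        waves = [self._wave(10)]
        df = wv.match_wave_to_ihc_events(waves, [], {"a": 0.0})
        assert len(df) == 1
        assert df.iloc[0]["matched"] == 0

    def test_matching_and_span(self):
        waves = [self._wave(10)]                       # onset 1.0 s
        events = [self._event(1.5, ["a", "b", "c"])]
        pos = {"a": 0.0, "b": 9.0, "c": 18.0}
        df = wv.match_wave_to_ihc_events(waves, events, pos)
        assert df.iloc[0]["matched"] == 1
        assert df.iloc[0]["ihc_span_um"] == pytest.approx(18.0)
        assert df.iloc[0]["coordinated_3plus"] == 1

    def test_far_wave_excluded(self):
        waves = [self._wave(10, centroid_d=50.0)]
        df = wv.match_wave_to_ihc_events(waves, [], {"a": 0.0},
                                         origin_window_um=35.0)
        assert len(df) == 0
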