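import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cochlear_calcium import events as ev
from cochlear_calcium.io_core import FluorescenceTrace
from cochlear_calcium.traces import detrend, stitch_recordings, total_duration
from tests.conftest import make_kernel_trace


def _trace(x, rate=30.0, ident="c"):
    x = np.asarray(x, dtype=float)
    return FluorescenceTrace(ident, x, np.zeros_like(x, bool), rate)


def _tr(cell, t, amp=0.5):
    return ev.Transient(cell, t, amp, amp, 1.0)


class TestDetectTransients:
    def test_constructed_transient_recovered(self):
        """One 5σ kernel transient of FDHM 1.0 s → exactly one detection with
        FDHM within 10%."""
        noise = 0.05
        x = make_kernel_trace([30.0], [5 * noise * 2], 60.0, fdhm=1.0,
                              noise_sd=noise, seed=3)
        out = ev.detect_transients(detrend(_trace(x), 30.0, 30.0))
        assert len(out) == 1
        assert out[0].fdhm == pytest.approx(1.0, rel=0.10)
        assert out[0].peak_time == pytest.approx(30.0, abs=0.5)

    def test_short_transient_rejected(self):
        x = make_kernel_trace([30.0], [1.0], 60.0, fdhm=0.15)
        out = ev.detect_transients(detrend(_trace(x), 30.0, 30.0))
        assert out == []

    def test_low_amplitude_rejected(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.1, 1800)
        x = noise + make_kernel_trace([30.0], [0.15], 60.0)  # 1.5 sigma
        out = ev.detect_transients(_trace(x))
        assert all(abs(t.peak_time - 30.0) > 1 for t in out)

    def test_interpolated_span_rejected(self):
        x = make_kernel_trace([30.0], [1.0], 60.0)
        t = _trace(x)
        t.interpolated_mask[:] = False
        t.interpolated_mask[int(28 * 30):int(33 * 30)] = True
        assert ev.detect_transients(t) == []

    def test_noise_fp_rate_small(self):
        rng = np.random.default_rng(7)
        tot = 0
        for _ in range(10):
            x = rng.normal(0, 0.02, 30 * 600)
            tot += len(ev.detect_transients(_trace(x)))
        assert tot / (10 * 10.0) < 0.05      # events/min

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            ev.detect_transients(_trace(np.zeros(10)))


class TestFrequency:
    def test_simple_rate(self):
        trs = [_tr("a", t) for t in np.linspace(0, 590, 12)]
        freq = ev.compute_frequency(trs, {"a": 600.0})
        assert freq["a"] == pytest.approx(1.2)

    def test_short_observation_excluded(self):
        freq = ev.compute_frequency([_tr("a", 1.0)], {"a": 240.0})
        assert "a" not in freq

    def test_invariant_to_recording_split(self):
        """Stitching one 10-min recording as two 5-min halves leaves the
        frequency unchanged."""
        x = make_kernel_trace([100.0, 300.0, 500.0], [0.5] * 3, 600.0,
                              noise_sd=0.01, seed=1)
        whole = detrend(_trace(x, ident="a"), 30.0, 30.0)
        halves = [detrend(_trace(x[:9000], ident="a"), 30.0, 30.0),
                  detrend(_trace(x[9000:], ident="a"), 30.0, 30.0)]
        per_cell = stitch_recordings([[halves[0]], [halves[1]]])
        trs_whole = ev.detect_transients(whole)
        trs_split = ev.detect_transients_stitched(per_cell["a"])
        f_whole = len(trs_whole) / 10.0
        f_split = len(trs_split) / (total_duration(per_cell["a"]) / 60.0)
        assert f_whole == f_split == pytest.approx(0.3)


class TestGroupEvents:
    POS = {f"c{i}": i for i in range(20)}

    def test_chained_linkage_single_event(self):
        trs = [_tr("c1", 0.0), _tr("c2", 1.9), _tr("c3", 3.8)]
        out = ev.group_events(trs, self.POS)
        assert len(out) == 1
        assert out[0].event_class == "multiple"

    def test_complete_linkage_splits_chain(self):
        trs = [_tr("c1", 0.0), _tr("c2", 1.9), _tr("c3", 3.8)]
        out = ev.group_events(trs, self.POS, linkage="complete")
        assert len(out) == 2

    def test_gap_of_five_splits(self):
        trs = [_tr(f"c{i}", 0.1 * i) for i in (1, 2, 3)] + \
              [_tr(f"c{i}", 0.1 * i) for i in (9, 10, 11)]
        out = ev.group_events(trs, self.POS)
        assert len(out) == 2
        assert all(e.event_class == "multiple" for e in out)

    def test_gap_of_exactly_four_stays_one(self):
        trs = [_tr(f"c{i}", 0.1 * i) for i in (1, 2, 3, 8, 9, 10)]
        out = ev.group_events(trs, self.POS)
        assert len(out) == 1

    def test_classes_partition_transients(self):
        rng = np.random.default_rng(0)
        trs = [_tr(f"c{rng.integers(0, 12)}", float(rng.uniform(0, 100)))
               for _ in range(40)]
        out = ev.group_events(trs, self.POS)
        assert sum(len(e.transients) for e in out) == len(trs)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cells = int(rng.integers(2, 13))
        pos = {f"c{i}": i for i in range(n_cells)}
        trs = [_tr(f"c{rng.integers(0, n_cells)}", float(rng.uniform(0, 60)))
               for _ in range(rng.integers(1, 31))]
        fast = ev.group_events(trs, pos)
        brute = ev.group_events_bruteforce(trs, pos)
        key = lambda e: (sorted((t.cell, t.peak_time) for t in e.transients))
        assert sorted(map(key, fast)) == sorted(map(key, brute))
        assert sorted(e.event_class for e in fast) == \
               sorted(e.event_class for e in brute)


class TestSkippedCells:
    POS = {f"c{i}": i for i in range(10)}

    def test_internal_silent_but_active_elsewhere(self):
        event = ev.CellEvent([_tr(f"c{i}", 0.0) for i in (1, 2, 4, 5)],
                             {"c1", "c2", "c4", "c5"}, "multiple")
        all_trs = event.transients + [_tr("c3", 60.0)]
        assert ev.find_skipped_cells(event, all_trs, self.POS) == ["c3"]

    def test_no_internal_silent(self):
        event = ev.CellEvent([_tr(f"c{i}", 0.0) for i in (1, 2, 3)],
                             {"c1", "c2", "c3"}, "multiple")
        assert ev.find_skipped_cells(event, event.transients, self.POS) == []

    def test_truly_silent_cell_not_skipped(self):
        event = ev.CellEvent([_tr(f"c{i}", 0.0) for i in (1, 2, 4, 5)],
                             {"c1", "c2", "c4", "c5"}, "multiple")
        # c3 has no transient anywhere: fails the "not silent" clause
        assert ev.find_skipped_cells(event, event.transients, self.POS) == []

    def test_reduced_amplitude_counts_as_skipped(self):
        members = [_tr(f"c{i}", 0.0, amp=0.5) for i in (1, 2, 4, 5)]
        weak = _tr("c3", 0.0, amp=0.05)          # ≪ 0.25 × cohort median
        event = ev.CellEvent(members + [weak], {f"c{i}" for i in (1, 2, 3, 4, 5)},
                             "multiple")
        all_trs = event.transients + [_tr("c3", 90.0)]
        assert ev.find_skipped_cells(event, all_trs, self.POS) == ["c3"]


class TestAmplitudeByClass:
    def test_partition_conservation(self):
        events = [
            ev.CellEvent([_tr("a", 0.0, 0.2)], {"a"}, "single"),
            ev.CellEvent([_tr("a", 10.0, 0.3), _tr("b", 10.5, 0.5)], {"a", "b"}, "pair"),
            ev.CellEvent([_tr(c, 20.0, 0.4) for c in "abc"], {"a", "b", "c"}, "multiple"),
        ]
        df = ev.event_amplitude_by_class(events)
        assert df["n_transients"].sum() == 6

    def test_all_single_leaves_multiple_empty(self):
        events = [ev.CellEvent([_tr("a", 0.0, 0.2)], {"a"}, "single")]
        df = ev.event_amplitude_by_class(events)
        row = df[df.event_class == "multiple"].iloc[0]
        assert row["n_transients"] == 0 and np.isnan(row["amplitude_mean"])


class TestFisher:
    def test_closed_form_half(self):
        # tanh(mean(arctanh{0, 0.8})) = (3-1)/(3+1) = 0.5 exactly
        assert ev.fisher_mean(np.array([0.0, 0.8])) == pytest.approx(0.5, abs=1e-12)

    @given(st.lists(st.floats(-0.99, 0.99), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_composition(self, rs):
        rs = np.asarray(rs)
        assert ev.fisher_mean(rs) == pytest.approx(
            float(np.tanh(np.mean(np.arctanh(rs)))), abs=1e-12)
        if len(rs) > 1:
            assert ev.fisher_sd(rs) == pytest.approx(
                float(np.tanh(np.std(np.arctanh(rs), ddof=1))), abs=1e-12)


class TestCorrelationAnalysis:
    def _df(self, cols):
        return pd.DataFrame({k: v for k, v in cols.items()})

    def test_identical_traces_r_one(self):
        x = make_kernel_trace([50.0, 150.0], [0.5, 0.4], 400.0, noise_sd=0.01, seed=2)
        df = self._df({"a": x, "b": x.copy()})
        res = ev.correlation_analysis(df, {"a": 0.0, "b": 9.0}, 30.0,
                                      min_overlap_s=300.0)
        assert res["r_matrix"].loc["a", "b"] == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_overlap_undefined_not_zero(self):
        x = make_kernel_trace([10.0], [0.5], 400.0, noise_sd=0.01, seed=3)
        y = x.copy()
        y[:11000] = np.nan                       # < 5 min overlap remains
        res = ev.correlation_analysis(self._df({"a": x, "b": y}),
                                      {"a": 0.0, "b": 9.0}, 30.0)
        assert np.isnan(res["r_matrix"].loc["a", "b"])
        assert res["n_pairs"] == 0

    def test_distance_decay_recovered(self):
        """Coupling that decays over d0 = 40 µm is recovered within 25%."""
        rng = np.random.default_rng(4)
        n_cells, rate, dur = 12, 10.0, 600.0
        n = int(dur * rate)
        d0, spacing = 40.0, 9.0
        positions = {f"c{i}": spacing * i for i in range(n_cells)}
        # spatial AR(1) across the row: r(i, j) = exp(-|s_i - s_j| / d0)
        rho = np.exp(-spacing / d0)
        x = np.empty((n_cells, n))
        x[0] = rng.normal(0, 1.0, n)
        for i in range(1, n_cells):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * rng.normal(0, 1.0, n)
        cols = {f"c{i}": x[i] for i in range(n_cells)}
        res = ev.correlation_analysis(pd.DataFrame(cols), positions, rate,
                                      min_overlap_s=300.0, detrend_window_s=60.0)
        assert res["decay_d0_um"] == pytest.approx(d0, rel=0.25)

    def test_needs_two_cells(self):
        with pytest.raises(ValueError, match="2 cells"):
            ev.correlation_analysis(pd.DataFrame({"a": [0.1, 0.2]}), {"a": 0}, 10.0)
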