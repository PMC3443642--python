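import numpy as np
import pytest

from rhmap import io
from rhmap.deletions import (
    call_deletions,
    cr_span_to_mb,
    cr_to_mb,
    locus_states,
    summarize_deletions,
)
from rhmap.mapping import LocusGroup, RHMap, classify_lines, deletion_frequency
from rhmap.simulate import SimBin, SimConfig, simulate_panel, truth_map


def _map_and_matrix(states, positions, bins=None):
    """One line whose loci carry the given states at the given positions."""
    ids = [f"m{i}" for i in range(len(states))]
    m = io.GenotypeMatrix(["L1"], ids, np.array([states], dtype=np.int8))
    rh = RHMap(
        [LocusGroup(i, (i,)) for i in ids],
        np.asarray(positions, dtype=float),
        list(bins) if bins else [],
    )
    return m, rh


class TestCallDeletions:
    def test_midpoint_convention(self):
        m, rh = _map_and_matrix([1, 0, 0, 1], [0, 10, 20, 30])
        (call,) = call_deletions("L1", m, rh)
        assert call.inner_span_cR == 10.0
        assert call.outer_span_cR == 30.0
        assert call.size_cR == 20.0
        assert call.n_deleted_loci == 2

    def test_all_retained_empty(self):
        m, rh = _map_and_matrix([1, 1, 1], [0, 5, 9])
        assert call_deletions("L1", m, rh) == []

    def test_missing_bridges_but_does_not_extend(self):
        m, rh = _map_and_matrix([1, 0, -1, 0, 1, -1], [0, 10, 20, 30, 40, 50])
        calls = call_deletions("L1", m, rh)
        assert len(calls) == 1
        assert calls[0].first_deleted_locus == "m1"
        assert calls[0].last_deleted_locus == "m3"

    def test_terminal_run_bounded_by_map_end(self):
        m, rh = _map_and_matrix([0, 0, 1], [0, 10, 30])
        (call,) = call_deletions("L1", m, rh)
        assert call.inner_span_cR == 10.0
        assert call.outer_span_cR == 30.0

    def test_non_informative_line_rejected(self):
        m, rh = _map_and_matrix([0, 0, 0], [0, 1, 2])
        with pytest.raises(ValueError, match="INFORMATIVE"):
            call_deletions("L1", m, rh, line_class=io.WHOLE_LOSS)

    def test_planted_deletions_counted_exactly(self):
        bins = (SimBin("A", "S", 0.0, 1.0, 200.0, 1.0, 40),)
        cfg = SimConfig(
            seed=9, n_lines=30, bins=bins, class_mix=(0, 0, 0, 1),
            lam=0.004, mu=25, eps=0.0, missing_rate=0.0,
        )
        panel = simulate_panel(cfg)
        rh, spans, res = truth_map(panel)
        pos = panel.truth.positions_mb
        for line in panel.matrix.line_ids:
            # independent count: deletions merge when no retained marker
            # separates them, and are visible when covering >= 1 marker
            covered = np.zeros(len(pos), dtype=bool)
            for lo, hi in panel.truth.deletions[line]:
                covered |= (pos >= lo) & (pos <= hi)
            visible = int(
                np.sum(covered[1:] & ~covered[:-1]) + (1 if covered[0] else 0)
            )
            calls = call_deletions(line, panel.matrix, rh)
            assert len(calls) == visible

    def test_deleted_locus_counts_add_up(self, preset_panel):
        rh, spans, res = truth_map(preset_panel)
        classes = classify_lines(preset_panel.matrix, preset_panel.truth.marker_arms)
        line = next(
            l for l, c in zip(preset_panel.matrix.line_ids, classes)
            if c == io.INFORMATIVE
        )
        calls = call_deletions(line, preset_panel.matrix, rh)
        states = locus_states(preset_panel.matrix, rh, line)
        assert sum(c.n_deleted_loci for c in calls) == int((states == io.DELETED).sum())


class TestCrToMb:
    def test_single_bin_conversions(self):
        # the two worked conversions: 120.2 cR at 1.2 Mb/cR and 13.1 cR at
        # 0.1 Mb/cR
        assert cr_span_to_mb(120.2, 1.2) == pytest.approx(144.24)
        assert cr_span_to_mb(13.1, 0.1) == pytest.approx(1.31)

    def test_zero_span(self):
        assert cr_span_to_mb(0.0, 1.2) == 0.0

    def test_partition_across_bins(self):
        spans = {"b1": (0.0, 10.0), "b2": (10.0, 30.0)}
        res = {"b1": 2.0, "b2": 0.5}
        # 5 cR in b1 at 2 Mb/cR + 10 cR in b2 at 0.5 Mb/cR
        assert cr_to_mb(5.0, 20.0, spans, res) == pytest.approx(5 * 2.0 + 10 * 0.5)

    def test_undefined_resolution_errors(self):
        spans = {"b1": (0.0, 10.0)}
        with pytest.raises(ValueError, match="no\\s+defined|no defined"):
            cr_to_mb(0.0, 5.0, spans, {"b1": None})


class TestSummaries:
    def _panel_calls(self, panel):
        rh, spans, res = truth_map(panel)
        classes = classify_lines(panel.matrix, panel.truth.marker_arms)
        calls = []
        for line, cls in zip(panel.matrix.line_ids, classes):
            if cls != io.INFORMATIVE:
                continue
            calls.extend(
                call_deletions(line, panel.matrix, rh, bin_spans=spans, resolutions=res)
            )
        return rh, spans, calls

    def test_single_call_summary(self):
        m, rh = _map_and_matrix([1, 0, 0, 1], [0, 10, 20, 30], ["b", "b", "b", "b"])
        calls = call_deletions(
            "L1", m, rh, bin_spans={"b": (0.0, 30.0)}, resolutions={"b": 1.0}
        )
        summaries, per_line, overall = summarize_deletions(calls, {"b": (0.0, 30.0)})
        assert summaries["b"].n_deletions == 1
        assert summaries["b"].mean_size_mb == pytest.approx(20.0)
        assert per_line == {"L1": 1}
        assert overall == pytest.approx(20.0)

    def test_mean_deletion_frequency_identity(self, preset_panel):
        rh, spans, calls = self._panel_calls(preset_panel)
        summaries, _, _ = summarize_deletions(
            calls, spans, matrix=preset_panel.matrix, rh_map=rh
        )
        # definition identity: bin mean equals the column mean over the
        # bin's markers
        bin_name = "3BL7"
        cols = [
            j for j, b in enumerate(preset_panel.truth.marker_bins) if b == bin_name
        ]
        expected = np.mean(
            [deletion_frequency(preset_panel.matrix.calls[:, j]) for j in cols]
        )
        assert summaries[bin_name].mean_deletion_frequency == pytest.approx(expected)

    def test_open_bins_get_more_smaller_deletions(self):
        # two bins, 16-fold openness contrast, equal size: the open bin
        # collects more and smaller deletions (sign test over replicates)
        more, smaller = 0, 0
        reps = 12
        for seed in range(reps):
            bins = (
                SimBin("open", "S", 0.0, 1.0, 150.0, 4.0, 30),
                SimBin("closed", "L", 0.0, 1.0, 150.0, 0.25, 30),
            )
            cfg = SimConfig(
                seed=seed, n_lines=60, bins=bins, class_mix=(0, 0, 0, 1),
                lam=0.004, mu=20, eps=0.0, missing_rate=0.0,
            )
            panel = simulate_panel(cfg)
            rh, spans, calls = self._panel_calls(panel)
            summaries, _, _ = summarize_deletions(calls, spans)
            s_open, s_closed = summaries["open"], summaries["closed"]
            more += s_open.n_deletions > s_closed.n_deletions
            if s_open.mean_size_mb and s_closed.mean_size_mb:
                smaller += s_open.mean_size_mb < s_closed.mean_size_mb
        assert more >= reps - 2
        assert smaller >= reps - 2
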