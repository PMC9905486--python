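"""Node detection, trace extraction/alignment/averaging and metrics."""

import numpy as np
import pytest

from vncorr import (
    CorrelationMatrix,
    NodeTrace,
    align_traces,
    average_traces,
    detect_nodes,
    extract_trace,
    internodal_metrics,
)
from vncorr.traces import estimate_period, refine_node_bins


def _matrix(values, bin_length=1.0):
    return CorrelationMatrix(values=np.asarray(values, float), bin_length=bin_length)


def _trace(values, step=1.0):
    vals = np.asarray(values, float)
    return NodeTrace(positions=(np.arange(len(vals)) + 0.5) * step, values=vals)


def banded_matrix(n=60, k=12, base=0.3, amp=0.6):
    """Synthetic self-matrix with node bins every k bins (planted banding)."""
    f = np.maximum(0.0, np.cos(2 * np.pi * np.arange(n) / k)) ** 4
    M = base + amp * np.outer(f, f)
    np.fill_diagonal(M, 1.0)
    return _matrix(np.clip(M, 0, 1))


class TestDetectNodes:
    def test_constant_matrix_yields_no_nodes(self):
        M = _matrix(np.full((20, 20), 0.5))
        assert detect_nodes(M) == []

    def test_planted_banding_gives_peaks_spaced_k_bins(self):
        k = 12
        M = banded_matrix(n=60, k=k)
        nodes = detect_nodes(M, min_separation=0.5 * k)
        assert len(nodes) >= 4
        assert np.allclose(np.diff(nodes), k)

    def test_phantom_matrix_one_node_per_segment(self, tiny_params, tiny_matrix):
        period = estimate_period(tiny_matrix)
        nodes = detect_nodes(tiny_matrix, min_separation=0.5 * period)
        assert len(nodes) == tiny_params.n_segments
        true_bins = (np.asarray(tiny_params.node_positions) / tiny_matrix.bin_length) - 0.5
        # grid detection localizes coarsely; refine_node_bins sharpens it
        assert np.all(np.abs(np.asarray(nodes) - true_bins) <= 3)

    def test_rectangular_matrix_rejected(self):
        M = CorrelationMatrix(values=np.full((4, 6), 0.5), bin_length=1.0,
                              labels=("a", "b"))
        with pytest.raises(ValueError, match="self"):
            detect_nodes(M)


class TestEstimatePeriod:
    def test_phantom_period_recovered(self, tiny_params, tiny_matrix):
        per = estimate_period(tiny_matrix)
        assert per == pytest.approx(tiny_params.period, abs=tiny_matrix.bin_length)

    def test_planted_banding_period(self):
        assert estimate_period(banded_matrix(n=60, k=12)) == pytest.approx(12.0, abs=1.0)

    def test_flat_profile_raises(self):
        with pytest.raises(ValueError):
            estimate_period(_matrix(np.full((20, 20), 0.5)))


class TestRefineNodeBins:
    def test_refined_bins_land_on_true_nodes(self, tiny_params, tiny_matrix):
        period = estimate_period(tiny_matrix)
        nodes = refine_node_bins(tiny_matrix, detect_nodes(tiny_matrix, min_separation=0.5 * period))
        true_bins = (np.asarray(tiny_params.node_positions) / tiny_matrix.bin_length) - 0.5
        assert np.all(np.abs(np.asarray(nodes) - true_bins) <= 1.0)


class TestExtractTrace:
    def test_all_ones_matrix_gives_unit_trace(self):
        M = _matrix(np.ones((7, 7)))
        tr = extract_trace(M, 3)
        assert np.allclose(tr.values, 1.0)

    def test_three_row_mean_away_from_diagonal(self):
        n, r, c = 9, 4, 7
        M = np.full((n, n), 0.9)
        M[r - 1, c], M[r, c], M[r + 1, c] = 0.2, 0.4, 0.6
        tr = extract_trace(_matrix(M), r)
        assert tr.values[c] == pytest.approx(0.4)

    def test_diagonal_entries_excluded(self):
        # hand-computed on a 5x5 matrix: at column r the row-r entry is the
        # diagonal and must be dropped, leaving the mean of the two neighbours
        M = np.full((5, 5), 0.5)
        r = 2
        M[r - 1, r], M[r + 1, r] = 0.8, 0.6
        M[r, r] = 1.0  # diagonal, ignored
        tr = extract_trace(_matrix(M), r)
        assert tr.values[r] == pytest.approx(0.7)

    def test_edge_node_uses_two_rows_and_is_flagged(self):
        M = _matrix(np.full((6, 6), 0.5))
        tr = extract_trace(M, 0)
        assert tr.edge
        assert np.isfinite(tr.values).all()

    def test_out_of_range_node_raises(self):
        with pytest.raises(ValueError, match="node_bin"):
            extract_trace(_matrix(np.ones((4, 4))), 9)


class TestAlignTraces:
    def _periodic(self, shift=0, n=50, period=12.0):
        pos = (np.arange(n) + 0.5) * 1.0
        vals = 0.6 + 0.3 * np.cos(2 * np.pi * (pos - shift) / period)
        return NodeTrace(positions=pos, values=vals)

    def test_planted_shifts_recovered(self):
        ref = self._periodic()
        t_plus = self._periodic(shift=2)
        t_minus = self._periodic(shift=-1)
        aligned = align_traces([ref, t_plus, t_minus], window=(10, 40), max_shift=5)
        for t in aligned[1:]:
            sel = slice(10, 40)
            assert np.nanmax(np.abs(t.values[sel] - ref.values[sel])) < 1e-6

    def test_single_trace_unchanged(self):
        tr = self._periodic()
        assert align_traces([tr])[0] is tr

    def test_antiphase_traces_shift_by_half_period(self):
        a = self._periodic()
        b = self._periodic(shift=6.0)  # half of the 12-bin period
        aligned = align_traces([a, b], window=(12, 36), max_shift=8)
        moved = np.nansum(np.abs(aligned[1].values - b.values) > 1e-12)
        assert moved > 0
        sel = slice(12, 36)
        assert np.corrcoef(aligned[1].values[sel], a.values[sel])[0, 1] > 0.99

    def test_idempotent(self):
        traces = [self._periodic(), self._periodic(2), self._periodic(-1)]
        once = align_traces(traces, window=(10, 40), max_shift=5)
        twice = align_traces(once, window=(10, 40), max_shift=5)
        for t1, t2 in zip(once, twice):
            assert np.allclose(t1.values, t2.values, equal_nan=True)

    def test_window_outside_support_raises(self):
        with pytest.raises(ValueError, match="window"):
            align_traces([self._periodic(), self._periodic(1)], window=(500, 600))


class TestAverageTraces:
    def test_identical_traces_have_zero_sd(self):
        tr = _trace([0.2, 0.4, 0.6])
        avg = average_traces([tr, tr, tr])
        assert np.allclose(avg.values, tr.values)
        assert np.allclose(avg.sd, 0.0)

    def test_two_traces_mean_and_sample_sd(self):
        avg = average_traces([_trace([0.2, 0.2]), _trace([0.6, 0.6])])
        assert np.allclose(avg.values, 0.4)
        assert np.allclose(avg.sd, 0.2828, atol=1e-3)  # sample (n-1) convention

    def test_single_coverage_positions_have_undefined_sd(self):
        a = _trace([0.2, 0.4, np.nan])
        b = _trace([0.4, 0.6, 0.8])
        avg = average_traces([a, b])
        assert np.isnan(avg.sd[2])
        assert avg.values[2] == pytest.approx(0.8)
        assert avg.n_contrib[2] == 1


class TestInternodalMetrics:
    def test_pure_cosine_gives_symmetric_metrics(self):
        pos = (np.arange(90) + 0.5) * 1.0
        vals = 0.6 + 0.35 * np.cos(2 * np.pi * pos / 28.0)
        tr = NodeTrace(positions=pos, values=np.clip(vals, 0, 1))
        m = internodal_metrics(tr, min_separation=14.0)
        assert m.mean_internodal_distance == pytest.approx(28.0, abs=0.5)
        assert np.mean(m.node_to_min_offsets) == pytest.approx(14.0, abs=0.5)

    def test_sawtooth_minimum_nine_after_peak(self):
        # asymmetric profile: drop over 9 μm, recover over 19 μm
        period, drop = 28.0, 9.0
        pos = (np.arange(90) + 0.5) * 1.0
        phase = np.mod(pos - 14.0, period)
        vals = np.where(
            phase <= drop,
            1.0 - 0.6 * phase / drop,
            0.4 + 0.6 * (phase - drop) / (period - drop),
        )
        tr = NodeTrace(positions=pos, values=vals)
        m = internodal_metrics(tr, min_separation=14.0)
        assert np.allclose(m.node_to_min_offsets, 9.0, atol=1.0)
        assert m.mean_internodal_distance == pytest.approx(28.0, abs=1.0)

    def test_fewer_than_two_peaks_raises(self):
        tr = _trace(np.linspace(0.2, 0.9, 30))
        with pytest.raises(ValueError, match="insufficient nodes"):
            internodal_metrics(tr)
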