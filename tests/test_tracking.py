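"""Deterministic streamline tractography: seeding, propagation, filtering."""

import numpy as np
import pytest

from qconn.phantom import PhantomConfig, build_phantom, simulate_dwi
from qconn.reconstruct import (
    PeakField,
    dsi_odf,
    extract_peaks,
    fit_tensor,
    tensor_peaks,
    true_peak_field,
)
from qconn.tracking import (
    StreamlineSet,
    TrackingParams,
    filter_fibers,
    generate_seeds,
    propagate,
    track_wholebrain,
)


def corridor_peaks(shape=(30, 6, 6), direction=(1, 0, 0)):
    """Uniform single-direction peak field in a 1-voxel-wide corridor."""
    wm = np.zeros(shape, bool)
    wm[:, 2:4, 2:4] = True
    vecs = np.zeros(shape + (3, 3))
    vecs[..., 0, :] = np.asarray(direction, float)
    counts = np.where(wm, 1, 0)
    return PeakField(vecs, counts, np.ones(3)), wm


class TestGenerateSeeds:
    def test_seed_count_law(self, crossing_truth):
        """Total seeds = seeds_per_vector * sum_v n_v, exactly."""
        pk = true_peak_field(crossing_truth)
        params = TrackingParams()
        rng = np.random.default_rng(0)
        pos, dirs = generate_seeds(pk, crossing_truth.wm_mask, params, rng)
        expected = 32 * int(crossing_truth.n_dirs[crossing_truth.wm_mask].sum())
        assert len(pos) == expected == len(dirs)

    def test_two_vector_voxel_gets_64_seeds(self, crossing_truth):
        pk = true_peak_field(crossing_truth)
        rng = np.random.default_rng(0)
        pos, _ = generate_seeds(pk, crossing_truth.wm_mask, TrackingParams(), rng)
        vs = crossing_truth.voxel_size
        vox2 = np.argwhere(crossing_truth.n_dirs == 2)[0]
        inside = np.all(np.floor(pos / vs).astype(int) == vox2, axis=1)
        assert inside.sum() == 64

    def test_seeds_inside_their_voxel(self, straight_truth):
        pk = true_peak_field(straight_truth)
        rng = np.random.default_rng(1)
        pos, _ = generate_seeds(pk, straight_truth.wm_mask, TrackingParams(), rng)
        idx = np.floor(pos / straight_truth.voxel_size).astype(int)
        seeded = straight_truth.wm_mask[tuple(idx.T)]
        assert np.all(seeded)

    def test_masked_out_voxels_get_no_seeds(self, straight_truth):
        pk = true_peak_field(straight_truth)
        rng = np.random.default_rng(0)
        empty = np.zeros_like(straight_truth.wm_mask)
        pos, _ = generate_seeds(pk, empty, TrackingParams(), rng)
        assert len(pos) == 0


class TestPropagate:
    def test_straight_corridor_spans_it(self):
        pk, wm = corridor_peaks()
        line = propagate((15.0, 3.0, 3.0), (1, 0, 0), pk, wm, TrackingParams())
        length = (len(line) - 1) * 1.0
        assert abs(length - 30.0) <= 2.0  # within 2 steps of the corridor span

    def test_sharp_turn_aborts_walk(self):
        """Field switching to +y mid-corridor: 90 deg > 60 deg/mm limit."""
        pk, wm = corridor_peaks()
        pk.vectors[15:, :, :, 0, :] = [0.0, 1.0, 0.0]
        line = propagate((5.0, 3.0, 3.0), (1, 0, 0), pk, wm, TrackingParams())
        xs = line[:, 0]
        assert xs.max() <= 16.0  # stopped at the interface, not beyond

    def test_no_direction_voxel_terminates(self):
        pk, wm = corridor_peaks()
        pk.counts[15:] = 0
        line = propagate((5.0, 3.0, 3.0), (1, 0, 0), pk, wm, TrackingParams())
        assert line[:, 0].max() <= 16.0

    def test_seed_outside_wm_returns_none(self):
        pk, wm = corridor_peaks()
        assert propagate((1.0, 1.0, 1.0), (1, 0, 0), pk, wm, TrackingParams()) is None

    def test_step_spacing_constant(self):
        pk, wm = corridor_peaks()
        line = propagate((15.0, 3.0, 3.0), (1, 0, 0), pk, wm, TrackingParams())
        gaps = np.linalg.norm(np.diff(line, axis=0), axis=1)
        assert np.allclose(gaps, 1.0, atol=1e-5)


class TestFilterFibers:
    def _line(self, n_pts, y=3.0):
        return np.stack(
            [np.arange(n_pts, dtype=float), np.full(n_pts, y), np.full(n_pts, 3.0)],
            axis=1,
        ).astype(np.float32)

    def test_length_window(self):
        labels = np.ones((300, 6, 6), dtype=int)
        lines = [self._line(5), self._line(11), self._line(251)]  # 4, 10, 250 mm
        out = filter_fibers(
            StreamlineSet(lines), labels, TrackingParams(), np.ones(3)
        )
        assert out.count == 1
        assert len(out.streamlines[0]) == 11

    def test_endpoint_in_background_removed(self):
        labels = np.ones((30, 6, 6), dtype=int)
        labels[0] = 0  # first voxel slab is background
        out = filter_fibers(
            StreamlineSet([self._line(11)]), labels, TrackingParams(), np.ones(3)
        )
        assert out.count == 0

    def test_empty_input(self):
        out = filter_fibers(
            StreamlineSet([]), np.ones((5, 5, 5), int), TrackingParams(), np.ones(3)
        )
        assert out.count == 0


class TestTrackWholebrain:
    def test_straight_phantom_connects_true_rois(self, straight_truth):
        pk = true_peak_field(straight_truth)
        ss = track_wholebrain(
            pk, straight_truth.wm_mask, straight_truth.roi_labels,
            TrackingParams(rng_seed=3),
        )
        assert ss.count > 0
        pairs = np.sort(ss.endpoint_labels, axis=1)
        frac = np.mean((pairs[:, 0] == 1) & (pairs[:, 1] == 2))
        assert frac >= 0.95

    def test_deterministic_given_seed(self, straight_truth):
        pk = true_peak_field(straight_truth)
        args = (pk, straight_truth.wm_mask, straight_truth.roi_labels)
        a = track_wholebrain(*args, TrackingParams(rng_seed=7))
        b = track_wholebrain(*args, TrackingParams(rng_seed=7))
        assert a.count == b.count
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))

    def test_no_peaks_yields_empty_set(self, straight_truth):
        pk = true_peak_field(straight_truth)
        pk.counts[:] = 0
        ss = track_wholebrain(
            pk, straight_truth.wm_mask, straight_truth.roi_labels, TrackingParams()
        )
        assert ss.count == 0

    def test_retained_fiber_invariants(self, crossing_truth):
        """Lengths in [5, 200] mm, endpoints labeled, turns within limit."""
        pk = true_peak_field(crossing_truth)
        params = TrackingParams(rng_seed=5)
        ss = track_wholebrain(
            pk, crossing_truth.wm_mask, crossing_truth.roi_labels, params
        )
        L = ss.lengths()
        assert np.all((L >= params.min_len) & (L <= params.max_len))
        assert np.all(ss.endpoint_labels > 0)
        cos_lim = np.cos(np.radians(params.max_turn * params.step)) - 1e-6
        for line in ss.streamlines[:200]:
            seg = np.diff(line.astype(float), axis=0)
            seg /= np.linalg.norm(seg, axis=1, keepdims=True)
            cos = np.einsum("ij,ij->i", seg[:-1], seg[1:])
            assert np.all(cos >= cos_lim)


class TestCrossingSchemesOrdering:
    def test_dsi_beats_dti_through_crossing(self, crossing_truth, dsi_scheme, dti_scheme, tess):
        """At SNR 20, DSI peaks carry far more fibers across the 90-degree
        crossing between the correct ROI pairs than tensor peaks, for every
        RNG seed tried (the single-tensor model collapses at the crossing)."""
        true_pairs = {(1, 2), (3, 4)}

        def true_fibers(ss):
            if ss.count == 0:
                return 0
            lab = np.sort(ss.endpoint_labels, axis=1)
            return sum(1 for l in lab if tuple(l) in true_pairs)

        for seed in range(5):
            d = simulate_dwi(crossing_truth, dsi_scheme, snr=20, seed=seed)
            t = simulate_dwi(
                crossing_truth, dti_scheme, snr=20, n_averages=4, seed=seed + 1000
            )
            pk_d = extract_peaks(dsi_odf(d, tess))
            pk_t = tensor_peaks(fit_tensor(t))
            params = TrackingParams(rng_seed=seed)
            n_seeds_d = 32 * int(pk_d.counts[crossing_truth.wm_mask].sum())
            n_seeds_t = 32 * int(pk_t.counts[crossing_truth.wm_mask].sum())
            r_d = true_fibers(
                track_wholebrain(pk_d, crossing_truth.wm_mask,
                                 crossing_truth.roi_labels, params)
            ) / n_seeds_d
            r_t = true_fibers(
                track_wholebrain(pk_t, crossing_truth.wm_mask,
                                 crossing_truth.roi_labels, params)
            ) / max(n_seeds_t, 1)
            assert r_d > r_t
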