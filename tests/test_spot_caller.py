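"""3D LoG filtering, detection, cell assignment, summaries, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.signal import fftconvolve

import episwitch as ep
from episwitch.errors import ParameterError


def toy_stack(data, voxel_xy=0.13, z_step=0.2):
    return ep.ImageStack(data=np.asarray(data, dtype=float), voxel_xy=voxel_xy, z_step=z_step)


def add_gaussian(data, z, y, x, amp, sz, sxy):
    zz, yy, xx = np.mgrid[0 : data.shape[0], 0 : data.shape[1], 0 : data.shape[2]]
    data += amp * np.exp(
        -(((zz - z) ** 2) / (2 * sz**2) + ((yy - y) ** 2 + (xx - x) ** 2) / (2 * sxy**2))
    )


class TestLoGFilter:
    def test_constant_stack_gives_zero_response(self):
        stack = toy_stack(np.full((16, 32, 32), 5.0))
        resp = ep.log_filter_3d(stack, 0.15, 0.30)
        assert np.abs(resp).max() < 1e-10 * 5.0

    def test_linearity(self, rng):
        data = rng.random((16, 24, 24))
        r1 = ep.log_filter_3d(toy_stack(data), 0.15, 0.30)
        r2 = ep.log_filter_3d(toy_stack(2 * data), 0.15, 0.30)
        assert np.allclose(r2, 2 * r1, atol=1e-12)

    def test_kernel_larger_than_stack_rejected(self):
        with pytest.raises(ParameterError, match="exceeds"):
            ep.log_filter_3d(toy_stack(np.zeros((4, 32, 32))), 0.15, 1.5)

    def test_matches_dense_convolution_oracle(self):
        """Argmax of the separable implementation agrees within 1 voxel with
        direct FFT convolution against the analytic anisotropic LoG kernel
        on a 32^3 stack containing one matched Gaussian spot."""
        stack = toy_stack(np.zeros((32, 32, 32)))
        sz, sxy = 0.30 / 0.2, 0.15 / 0.13  # voxel sigmas
        center = (16.3, 15.6, 14.9)
        add_gaussian(stack.data, *center, amp=50.0, sz=sz, sxy=sxy)

        resp = ep.log_filter_3d(stack, 0.15, 0.30)

        r = 8
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].astype(float)
        g = np.exp(-(zz**2 / (2 * sz**2) + (yy**2 + xx**2) / (2 * sxy**2)))
        g /= g.sum()
        lap = g * ((zz**2 / sz**4 - 1 / sz**2) + (yy**2 / sxy**4 - 1 / sxy**2) + (xx**2 / sxy**4 - 1 / sxy**2))
        oracle = -fftconvolve(stack.data, lap, mode="same")

        ours = np.array(np.unravel_index(np.argmax(resp), resp.shape))
        ref = np.array(np.unravel_index(np.argmax(oracle), oracle.shape))
        assert np.all(np.abs(ours - ref) <= 1)
        assert np.all(np.abs(ours - np.array(center)) <= 1)


class TestDetection:
    def test_blank_stack_yields_no_calls(self):
        assert ep.detect_spots(np.zeros((8, 16, 16)), threshold=1.0) == []

    def test_five_separated_spots_recovered_exactly(self):
        stack = toy_stack(np.zeros((24, 48, 48)))
        centers = [(6, 8, 8), (6, 8, 30), (12, 24, 12), (12, 38, 38), (18, 12, 40)]
        for c in centers:
            add_gaussian(stack.data, *c, amp=100.0, sz=1.5, sxy=1.15)
        resp = ep.log_filter_3d(stack, 0.15, 0.30)
        calls = ep.detect_spots(resp, threshold=0.2 * resp.max())
        assert len(calls) == 5
        got = sorted((round(s.z), round(s.y), round(s.x)) for s in calls)
        for (gz, gy, gx), (cz, cy, cx) in zip(got, sorted(centers)):
            assert abs(gz - cz) <= 1 and abs(gy - cy) <= 1 and abs(gx - cx) <= 1

    def test_resolves_overlapping_spots_along_z(self):
        """Two spots at the same x-y, 4 z-slices apart, SNR 10: a projection
        would merge them; 3D detection returns two calls."""
        rng = np.random.default_rng(7)
        stack = toy_stack(np.zeros((24, 32, 32)))
        for z in (10, 14):
            add_gaussian(stack.data, z, 16.0, 16.0, amp=100.0, sz=1.5, sxy=1.15)
        stack.data += 10.0 + rng.normal(0, 10.0, stack.data.shape)
        stack.data = np.clip(stack.data, 0, None)
        resp = ep.log_filter_3d(stack, 0.15, 0.30)
        calls = ep.detect_spots(resp, ep.suggest_threshold(resp))
        assert len(calls) == 2
        zs = sorted(s.z for s in calls)
        assert abs(zs[0] - 10) <= 1 and abs(zs[1] - 14) <= 1

    def test_call_count_non_increasing_in_threshold(self, rng):
        stack = toy_stack(np.zeros((20, 64, 64)))
        pts = [(5, 10, 10), (9, 30, 40), (14, 50, 20), (15, 20, 50), (10, 45, 45)]
        for c in pts:
            add_gaussian(stack.data, *c, amp=rng.uniform(40, 120), sz=1.5, sxy=1.15)
        stack.data += 10 + rng.normal(0, 8, stack.data.shape)
        stack.data = np.clip(stack.data, 0, None)
        resp = ep.log_filter_3d(stack, 0.15, 0.30)
        thresholds = np.linspace(0.5, 1.2, 8) * ep.suggest_threshold(resp)
        n_calls = [len(ep.detect_spots(resp, t)) for t in thresholds]
        assert n_calls == sorted(n_calls, reverse=True)

    def test_size_gate_and_threshold_validation(self):
        with pytest.raises(ParameterError):
            ep.detect_spots(np.zeros((4, 4, 4)), threshold=0.0)
        with pytest.raises(ParameterError):
            ep.detect_spots(np.zeros((4, 4, 4)), threshold=1.0, size_range=(5, 4))


class TestAssignment:
    def make_mask(self):
        mask = np.zeros((32, 32), dtype=np.uint16)
        mask[4:12, 4:12] = 7
        mask[20:30, 18:28] = 9
        return mask

    def test_spots_assigned_by_centroid_label(self):
        mask = self.make_mask()
        spots = [
            ep.SpotCall(z=3, y=8.2, x=7.9, size=10, response=5.0),
            ep.SpotCall(z=5, y=24.0, x=22.0, size=12, response=6.0),
            ep.SpotCall(z=4, y=1.0, x=1.0, size=8, response=4.0),  # background
        ]
        labeled, counts = ep.assign_spots_to_cells(spots, mask)
        assert [s.cell for s in labeled] == [7, 9, 0]
        assert counts.loc[7] == 1 and counts.loc[9] == 1
        assert counts.sum() == 2  # background spot excluded from counts
        assert len(labeled) == 3  # ...but retained in the table

    def test_cells_without_spots_count_zero(self):
        _, counts = ep.assign_spots_to_cells([], self.make_mask())
        assert set(counts.index) == {7, 9}
        assert (counts == 0).all()

    def test_out_of_extent_spot_rejected(self):
        with pytest.raises(ParameterError, match="outside the mask"):
            ep.assign_spots_to_cells(
                [ep.SpotCall(z=0, y=100.0, x=5.0, size=5, response=1.0)], self.make_mask()
            )

    def test_mask_must_be_2d(self):
        with pytest.raises(ParameterError):
            ep.assign_spots_to_cells([], np.zeros((4, 4, 4)))


class TestSummaries:
    def test_hand_computed_summary(self):
        s = ep.summarize_counts([0, 0, 0, 4])
        assert s.mean_spots_per_cell == 1.0
        assert s.variance == 4.0
        assert s.pct_cells_gt0 == 25.0 and s.pct_cells_gt1 == 25.0
        assert s.dispersion_index == 4.0

    def test_all_zero_counts(self):
        s = ep.summarize_counts([0, 0, 0])
        assert s.mean_spots_per_cell == 0.0 and s.pct_cells_gt0 == 0.0
        assert s.dispersion_index is None

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            ep.summarize_counts([])

    def test_poisson_counts_have_unit_dispersion(self):
        x = ep.sample_counts(ep.CountModel.poisson(7.3), 10_000, 3)
        s = ep.summarize_counts(x)
        assert 0.9 <= s.dispersion_index <= 1.1
        assert s.pct_cells_gt1 <= s.pct_cells_gt0


class TestScoring:
    def test_perfect_calls(self):
        truth = pd.DataFrame({"z": [5.0, 9.0], "y": [10.0, 20.0], "x": [10.0, 20.0]})
        calls = [ep.SpotCall(z=5, y=10, x=10, size=5, response=1.0),
                 ep.SpotCall(z=9, y=20, x=20, size=5, response=1.0)]
        score = ep.score_detection(calls, truth)
        assert score.precision == 1.0 and score.recall == 1.0 and score.f1 == 1.0

    def test_no_calls_flags_undefined_precision(self):
        truth = pd.DataFrame({"z": [5.0], "y": [1.0], "x": [1.0]})
        score = ep.score_detection([], truth)
        assert score.recall == 0.0 and score.precision is None and score.f1 is None

    def test_greedy_matches_exhaustive_assignment(self, rng):
        """Greedy one-to-one matching reproduces the F1 of optimal bipartite
        matching on a small mixed fixture (missed spots + false calls)."""
        radius = 3.0
        truth_pos = rng.uniform(5, 35, size=(15, 3))
        calls = [
            ep.SpotCall(z=z + rng.normal(0, 0.4), y=y + rng.normal(0, 0.4),
                        x=x + rng.normal(0, 0.4), size=6, response=1.0)
            for z, y, x in truth_pos[:13]  # two truths missed
        ] + [ep.SpotCall(z=1.0, y=1.0 + i, x=38.0, size=6, response=1.0) for i in range(3)]
        truth = pd.DataFrame(truth_pos, columns=["z", "y", "x"])
        score = ep.score_detection(calls, truth, match_radius=radius)

        c = np.array([[s.z, s.y, s.x] for s in calls])
        t = truth.to_numpy()
        d = np.sqrt(((c[:, None] - t[None]) ** 2).sum(-1))
        cost = np.where(d <= radius, 0.0, 1.0)
        ri, ci = linear_sum_assignment(cost)
        n_opt = int((d[ri, ci] <= radius).sum())
        f1_opt = 2 * n_opt / (len(calls) + len(truth))
        assert score.n_matched == n_opt
        assert score.f1 == pytest.approx(f1_opt)


class TestEndToEnd:
    def test_high_snr_recovery_with_default_parameters(self):
        """SNR 10, spots >= 6 voxels apart: precision and recall >= 0.95 and
        per-cell counts conserved (assigned + unassigned = total calls)."""
        spec = ep.StackSpec(shape=(21, 256, 256), n_cells=12, min_separation=6.0)
        counts = ep.sample_counts(ep.CountModel.negbin(12, 53), spec.n_cells, 71)
        stack, mask, truth = ep.generate_stack(spec, counts, 73)
        resp = ep.log_filter_3d(stack, spec.sigma_xy, spec.sigma_z)
        spots = ep.detect_spots(resp, ep.suggest_threshold(resp))
        spots, per_cell = ep.assign_spots_to_cells(spots, mask)
        score = ep.score_detection(spots, truth.spots)
        assert score.precision >= 0.95 and score.recall >= 0.95
        unassigned = sum(1 for s in spots if s.cell == 0)
        assert per_cell.sum() + unassigned == len(spots)
        detected = ep.summarize_counts(per_cell.to_numpy())
        true = ep.summarize_counts(truth.per_cell_counts.to_numpy())
        assert detected.mean_spots_per_cell == pytest.approx(true.mean_spots_per_cell, rel=0.1)
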