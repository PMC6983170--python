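"""Occupancy, interval, RMSD, clustering and replicate statistics."""

import math

import numpy as np
import pytest

from xbtraj.exceptions import EmptyInputError, ParameterError
from xbtraj.io_structures import Frame, Trajectory
from xbtraj.traj_stats import (
    boxplot_stats,
    cluster_frames,
    interval_medians,
    ligand_rmsd,
    select_replicate,
    summarize,
)
from xbtraj.xb_geometry import GeometrySeries

from conftest import build_pocket_trajectory


def _series(d, theta, times=None):
    d = np.asarray(d, dtype=float)
    if times is None:
        times = np.arange(len(d), dtype=float)
    return GeometrySeries.from_arrays(times, d, np.asarray(theta, dtype=float))


class TestSummarize:
    def test_all_primary_occupancy_one(self):
        s = _series([3.5] * 10, [160.0] * 10)
        assert summarize(s).primary_occupancy == 1.0

    def test_constant_distance_zero_sd(self):
        s = _series([3.5] * 7, [160.0] * 7)
        summ = summarize(s)
        assert summ.mean_d == pytest.approx(3.5)
        assert summ.sd_d == 0.0

    def test_population_sd_convention(self):
        d = [3.0, 4.0, 5.0]
        s = _series(d, [160.0] * 3)
        assert summarize(s).sd_d == pytest.approx(np.std(d, ddof=0))

    def test_region_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        s = _series(rng.uniform(2.5, 6, 500), rng.uniform(60, 180, 500))
        fr = summarize(s).region_fractions
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_two_state_occupancy_within_binomial_interval(self):
        # planted weight 0.6, n=1000: 99% binomial interval = p ± 2.576*SE
        rng = np.random.default_rng(123)
        n, p = 1000, 0.6
        primary = rng.random(n) < p
        d = np.where(primary, 3.6, 5.5)
        th = np.where(primary, 162.0, 110.0)
        occ = summarize(_series(d, th)).primary_occupancy
        assert abs(occ - p) <= 2.576 * math.sqrt(p * (1 - p) / n)

    def test_empty_series_raises(self):
        import pandas as pd

        s = GeometrySeries(None, pd.DataFrame(
            columns=["time_ns", "distance_A", "sigma_hole_deg", "region"]))
        with pytest.raises(EmptyInputError):
            summarize(s)


class TestIntervalMedians:
    def test_constant_series_all_medians_equal(self):
        s = _series([3.5] * 100, [160.0] * 100,
                    times=np.linspace(0, 59.97, 100))
        im = interval_medians(s, 6.0)
        assert np.allclose(im.table["median_d"], 3.5)

    def test_sixty_ns_gives_ten_intervals(self):
        times = np.arange(0, 60.0, 0.06)  # 1000 frames over 60 ns
        s = _series(np.full(len(times), 3.5), np.full(len(times), 150.0), times)
        assert len(interval_medians(s, 6.0)) == 10

    def test_final_frame_joins_last_interval(self):
        times = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        s = _series([1, 2, 3, 4, 5], [150.0] * 5, times)
        im = interval_medians(s, 6.0)
        assert len(im) == 2
        # second interval holds frames at 6, 9 and the final frame at 12
        assert im.table["median_d"].iloc[1] == pytest.approx(4.0)

    def test_odd_count_interval_median(self):
        s = _series([3, 4, 5], [150.0] * 3, times=[0.0, 1.0, 2.0])
        assert interval_medians(s, 6.0).table["median_d"].iloc[0] == 4.0

    def test_empty_interval_recorded_as_nan(self):
        times = np.array([0.0, 1.0, 13.0])  # nothing in [6, 12)
        s = _series([1.0, 2.0, 3.0], [150.0] * 3, times)
        im = interval_medians(s, 6.0)
        assert len(im) == 3
        assert math.isnan(im.table["median_d"].iloc[1])

    def test_merged_series_equals_per_interval_oracle(self):
        rng = np.random.default_rng(8)
        times = np.sort(rng.uniform(0, 30, 400))
        d = rng.uniform(3, 6, 400)
        th = rng.uniform(90, 180, 400)
        im = interval_medians(_series(d, th, times), 6.0)
        t0 = times[0]
        n_int = len(im)
        for k in range(n_int):
            mask = (times >= t0 + 6 * k) & (times < t0 + 6 * (k + 1))
            if k == n_int - 1:
                mask |= times >= t0 + 6 * n_int
            assert im.table["median_d"].iloc[k] == pytest.approx(
                np.median(d[mask]))


class TestBoxplotStats:
    def test_constant_interval_all_five_equal(self):
        s = _series([3.5] * 20, [150.0] * 20, times=np.linspace(0, 5, 20))
        row = boxplot_stats(s, 6.0).iloc[0]
        for stat in ("d_lo", "d_q1", "d_median", "d_q3", "d_hi"):
            assert row[stat] == pytest.approx(3.5)

    def test_one_to_five_quartiles(self):
        s = _series([1, 2, 3, 4, 5], [150.0] * 5, times=[0, 1, 2, 3, 4])
        row = boxplot_stats(s, 6.0).iloc[0]
        assert row["d_median"] == 3.0
        assert row["d_q1"] == 2.0
        assert row["d_q3"] == 4.0

    def test_against_sort_based_oracle(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(4.0, 0.5, 101)
        s = _series(vals, np.full(101, 150.0), times=np.linspace(0, 5, 101))
        row = boxplot_stats(s, 6.0).iloc[0]

        def oracle_quantile(x, q):  # sort + linear interpolation
            xs = sorted(x)
            h = (len(xs) - 1) * q
            lo = math.floor(h)
            return xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])

        assert row["d_q1"] == pytest.approx(oracle_quantile(vals, 0.25), abs=1e-10)
        assert row["d_median"] == pytest.approx(oracle_quantile(vals, 0.5), abs=1e-10)
        assert row["d_q3"] == pytest.approx(oracle_quantile(vals, 0.75), abs=1e-10)
        # whiskers: extreme values inside the 1.5*IQR fences
        iqr = row["d_q3"] - row["d_q1"]
        inside = vals[(vals >= row["d_q1"] - 1.5 * iqr)
                      & (vals <= row["d_q3"] + 1.5 * iqr)]
        assert row["d_lo"] == pytest.approx(inside.min())
        assert row["d_hi"] == pytest.approx(inside.max())


def _kabsch_oracle(P, Q):
    """Brute-force Kabsch: rotation best mapping P (centred) onto Q (centred)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    return Vt.T @ D @ U.T


class TestLigandRmsd:
    def test_identical_frames_zero(self):
        lig = np.tile(np.array([[0.0, 0, 0], [1.74, 0, 0], [-1.4, 0.3, 0]]),
                      (5, 1, 1))
        traj = build_pocket_trajectory(lig)
        rmsd = ligand_rmsd(traj)
        assert np.allclose(rmsd["rmsd_A"], 0.0, atol=1e-6)

    def test_rigid_ligand_shift_with_fixed_receptor(self):
        base = np.array([[0.0, 0, 0], [1.74, 0, 0], [-1.4, 0.3, 0]])
        lig = np.stack([base, base + np.array([2.0, 0.0, 0.0])])
        traj = build_pocket_trajectory(lig)
        rmsd = ligand_rmsd(traj)
        assert rmsd["rmsd_A"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert rmsd["rmsd_A"].iloc[1] == pytest.approx(2.0, abs=1e-6)

    def test_invariance_to_whole_frame_rigid_transform(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        base = np.array([[0.0, 0, 0], [1.74, 0, 0], [-1.4, 0.3, 0]])
        jitter = rng.normal(scale=0.3, size=(4, 3, 3))
        lig = np.stack([base + jitter[k] for k in range(4)])
        traj = build_pocket_trajectory(lig)
        ref = ligand_rmsd(traj)["rmsd_A"].to_numpy()

        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 8
        frames = [Frame(fr.time_ns, fr.coordinates @ R.T + t)
                  for fr in traj.frames]
        moved = Trajectory(traj.topology, frames)
        assert np.allclose(ligand_rmsd(moved)["rmsd_A"].to_numpy(), ref,
                           atol=1e-6)

    def test_matches_independent_kabsch_oracle(self):
        rng = np.random.default_rng(17)
        base = np.array([[0.0, 0, 0], [1.74, 0, 0], [-1.4, 0.3, 0]])
        pert = base + rng.normal(scale=0.4, size=(3, 3))
        lig = np.stack([base, pert])
        # jitter the pocket too so the fit is non-trivial
        traj = build_pocket_trajectory(lig)
        f1 = traj.frames[1]
        pocket_idx = [a.coords_index for a in traj.topology if not a.is_ligand]
        coords = f1.coordinates.copy()
        coords[pocket_idx] += rng.normal(scale=0.2, size=(len(pocket_idx), 3))
        traj.frames[1] = Frame(f1.time_ns, coords)

        got = ligand_rmsd(traj)["rmsd_A"].iloc[1]

        ref = traj.frames[0].coordinates
        mob = traj.frames[1].coordinates
        R = _kabsch_oracle(mob[pocket_idx], ref[pocket_idx])
        lig_idx = [a.coords_index for a in traj.topology if a.is_ligand]
        fitted = (mob[lig_idx] - mob[pocket_idx].mean(axis=0)) @ R.T \
            + ref[pocket_idx].mean(axis=0)
        expected = math.sqrt(np.mean(np.sum((fitted - ref[lig_idx]) ** 2,
                                            axis=1)))
        assert got == pytest.approx(expected, abs=1e-8)


class TestClusterFrames:
    def test_planted_two_conformations_recovered(self):
        rng = np.random.default_rng(6)
        conf_a = np.array([[0.0, 0, 0], [1.74, 0, 0], [-1.4, 0.3, 0]])
        conf_b = conf_a + np.array([4.0, 0.0, 0.0])
        labels = rng.integers(0, 2, size=100)
        lig = np.stack([
            (conf_a if lab == 0 else conf_b) + rng.normal(scale=0.05, size=(3, 3))
            for lab in labels
        ])
        traj = build_pocket_trajectory(lig)
        result = cluster_frames(traj, k=2)
        # exact recovery up to label permutation
        assignment = result.assignment
        match_direct = np.mean(assignment == labels)
        assert match_direct in (0.0, 1.0)
        assert sum(result.sizes.values()) == 100
        assert assignment[result.representative_frame] == max(
            result.sizes, key=result.sizes.get)

    def test_sizes_sum_to_n_for_random_data(self):
        rng = np.random.default_rng(9)
        lig = rng.normal(scale=1.0, size=(40, 3, 3))
        traj = build_pocket_trajectory(lig)
        result = cluster_frames(traj, k=10)
        assert sum(result.sizes.values()) == 40
        assert len(result.sizes) == 10

    def test_degenerate_identical_frames_split_into_singletons(self):
        lig = np.tile(np.array([[0.0, 0, 0], [1.74, 0, 0], [-1.4, 0.3, 0]]),
                      (10, 1, 1))
        traj = build_pocket_trajectory(lig)
        result = cluster_frames(traj, k=10)
        assert len(result.sizes) == 10
        assert sorted(result.sizes.values()) == [1] * 10

    def test_too_few_frames_raises(self):
        lig = np.tile(np.array([[0.0, 0, 0], [1.74, 0, 0], [-1.4, 0.3, 0]]),
                      (5, 1, 1))
        traj = build_pocket_trajectory(lig)
        with pytest.raises(ParameterError):
            cluster_frames(traj, k=10)


class TestSelectReplicate:
    def test_single_replicate_returns_zero(self):
        s = _series([3.5, 3.6], [160.0, 161.0])
        assert select_replicate([s]) == 0

    def test_constant_beats_noisy(self):
        const = _series([3.5] * 50, [160.0] * 50)
        rng = np.random.default_rng(2)
        noisy = _series(3.5 + rng.normal(0, 0.4, 50),
                        160.0 + rng.normal(0, 10, 50))
        assert select_replicate([noisy, const]) == 1

    def test_argmin_of_planted_variances(self):
        rng = np.random.default_rng(5)
        sds = [0.3, 0.05, 0.6]
        reps = [
            _series(3.8 + rng.normal(0, sd, 400), 150.0 + rng.normal(0, sd * 30, 400))
            for sd in sds
        ]
        # independent direct CV computation
        scores = []
        for s in reps:
            d = s.data["distance_A"].to_numpy()
            t = s.data["sigma_hole_deg"].to_numpy()
            scores.append(d.std() / d.mean() + t.std() / t.mean())
        assert select_replicate(reps) == int(np.argmin(scores)) == 1

    def test_empty_list_raises(self):
        with pytest.raises(EmptyInputError):
            select_replicate([])
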