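import numpy as np
import pytest

from fibrilsurf import dynamics, metrics
from fibrilsurf.metrics import kabsch, rmsd_series, rmsf_profile

from oracles import double_loop_rmsd, double_loop_rmsf


def toy_trajectory(reduced_model, coords_list):
    coords = np.stack(coords_list)
    return dynamics.Trajectory(
        topology=reduced_model,
        coords=coords,
        frame_times=np.arange(len(coords_list)) * 2.5,
    )


@pytest.fixture()
def base_coords(reduced_model):
    return reduced_model.coords()


SEL = {"segment": "D5", "layer": "surface_A", "representative": True}


class TestRMSD:
    def test_static_trajectory_is_zero(self, reduced_model, base_coords):
        traj = toy_trajectory(reduced_model, [base_coords] * 4)
        series = rmsd_series(traj, SEL)
        assert np.allclose(series.values, 0.0)
        assert series.values[0] == 0.0

    def test_rigid_translation_closed_form(self, reduced_model, base_coords):
        shifted = base_coords + np.array([3.0, 0.0, 4.0])
        traj = toy_trajectory(reduced_model, [base_coords, shifted])
        assert rmsd_series(traj, SEL, fit="none").final == pytest.approx(5.0)
        assert rmsd_series(traj, SEL, fit="rigid").final < 1e-9

    def test_rigid_fit_invariant_under_global_transform(self, reduced_model,
                                                        base_coords, rng):
        jitter = base_coords + rng.normal(0, 0.5, base_coords.shape)
        traj = toy_trajectory(reduced_model, [base_coords, jitter])
        ref = rmsd_series(traj, SEL, fit="rigid").final
        # rotate + translate every frame rigidly
        R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = np.array([10.0, -5.0, 2.0])
        traj2 = toy_trajectory(
            reduced_model,
            [base_coords @ R.T + t, jitter @ R.T + t],
        )
        assert rmsd_series(traj2, SEL, fit="rigid").final == pytest.approx(
            ref, abs=1e-6)

    def test_matches_double_loop_oracle(self, rng):
        # 10-atom toy, explicit double-loop accumulation
        ref = rng.normal(size=(10, 3))
        frame = ref + rng.normal(0, 1.0, size=(10, 3))
        expected = double_loop_rmsd(ref.tolist(), frame.tolist())
        d = frame - ref
        got = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_selection_rejected(self, reduced_model, base_coords):
        traj = toy_trajectory(reduced_model, [base_coords] * 2)
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, {"segment": "D5", "layer": "nowhere"})


class TestRMSF:
    def test_static_trajectory_is_zero(self, reduced_model, base_coords):
        traj = toy_trajectory(reduced_model, [base_coords] * 6)
        series = rmsf_profile(traj, SEL)
        assert np.allclose(series.values, 0.0)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self, reduced_model,
                                                       base_coords, rng):
        sigma = 0.8
        sel_rows = np.flatnonzero(
            reduced_model.mask(name="CA", segment="D2", layer="core",
                               representative=True))
        frames = [base_coords + rng.normal(0, sigma, base_coords.shape)
                  for _ in range(2000)]
        traj = toy_trajectory(reduced_model, frames)
        series = rmsf_profile(traj, sel_rows, equilibration_fraction=0.0)
        assert series.values.mean() == pytest.approx(
            sigma * np.sqrt(3), rel=0.05)

    def test_matches_double_loop_oracle(self, reduced_model, rng):
        coords0 = reduced_model.coords()
        rows = np.flatnonzero(reduced_model.mask(name="CA"))[:10]
        frames = [coords0 + rng.normal(0, 0.3, coords0.shape)
                  for _ in range(5)]
        traj = toy_trajectory(reduced_model, frames)
        series = rmsf_profile(traj, rows, equilibration_fraction=0.0)
        oracle = double_loop_rmsf([f[rows].tolist() for f in frames])
        # series is axially sorted; compare as sorted multisets of values
        np.testing.assert_allclose(np.sort(series.values),
                                   np.sort(oracle), atol=1e-9)

    def test_frame_order_permutation_invariance(self, reduced_model, rng):
        coords0 = reduced_model.coords()
        frames = [coords0 + rng.normal(0, 0.4, coords0.shape)
                  for _ in range(8)]
        t1 = toy_trajectory(reduced_model, frames)
        perm = rng.permutation(8)
        t2 = toy_trajectory(reduced_model, [frames[i] for i in perm])
        a = rmsf_profile(t1, SEL, equilibration_fraction=0.0)
        b = rmsf_profile(t2, SEL, equilibration_fraction=0.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_window_leaving_one_frame_rejected(self, reduced_model,
                                               base_coords):
        traj = toy_trajectory(reduced_model, [base_coords] * 3)
        with pytest.raises(ValueError, match="two frames"):
            rmsf_profile(traj, SEL, equilibration_fraction=0.9)


class TestKabsch:
    def test_recovers_known_rotation(self, rng):
        P = rng.normal(size=(20, 3))
        Rtrue, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Rtrue) < 0:
            Rtrue[:, 0] *= -1
        Q = P @ Rtrue.T + np.array([1.0, 2.0, 3.0])
        R, t = kabsch(P, Q)
        np.testing.assert_allclose(P @ R.T + t, Q, atol=1e-9)


class TestLayerExcess:
    def test_surface_excess_peaks_in_d5_and_gap_d4(self, calibrated_traj):
        junction_nm = (calibrated_traj.topology.geometry.d5_fraction
                       * calibrated_traj.topology.cell.c / 10)
        # D5 mean surface-minus-core RMSF excess dominates the segments
        means = {}
        for seg in ("D1", "D2", "D3", "D4", "D5"):
            sub = metrics.paired_layer_excess(calibrated_traj, segment=seg,
                                              n_bins=12).dropna()
            means[seg] = sub["excess"].mean()
        assert max(means, key=means.get) == "D5"
        # and within D4, the gap region out-fluctuates the overlap region
        d4 = metrics.paired_layer_excess(calibrated_traj, segment="D4",
                                         n_bins=12).dropna()
        gap = d4[d4["axial_nm"] >= junction_nm]["excess"].mean()
        overlap = d4[d4["axial_nm"] < junction_nm]["excess"].mean()
        assert gap > overlap
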