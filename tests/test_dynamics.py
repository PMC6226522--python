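import numpy as np
import pytest

from fibrilsurf import dynamics
from fibrilsurf.dynamics import (ModeSchedule, generate_trajectory,
                                 restraint_envelope)


def quiet_schedule(**kw):
    base = dict(telopeptide_shift=0.0, d5_drop=0.0, d5_bulge=0.0,
                gap_contraction=0.0, thermal_sigma=0.0,
                drift_amplitude=0.0, seed=0, n_frames=4)
    base.update(kw)
    return ModeSchedule(**base)


class TestGeneration:
    def test_all_zero_amplitudes_freeze_every_frame(self, reduced_model):
        traj = generate_trajectory(reduced_model, quiet_schedule())
        for t in range(1, traj.n_frames):
            np.testing.assert_allclose(traj.coords[t], traj.coords[0],
                                       atol=1e-12)

    def test_telopeptide_shift_moves_c_telo_minus_c(self, reduced_model):
        sched = quiet_schedule(telopeptide_shift=20.0, n_frames=6)
        traj = generate_trajectory(reduced_model, sched)
        atoms = traj.topology.atoms
        m = ((atoms["layer"] == "surface_A") & atoms["is_telopeptide"]
             & (atoms["segment"] == "D5")).to_numpy()
        dz = traj.coords[-1][m, 2] - traj.coords[0][m, 2]
        assert dz.mean() == pytest.approx(-20.0, abs=1e-9)
        # everything else untouched
        others = ~m
        np.testing.assert_allclose(traj.coords[-1][others],
                                   traj.coords[0][others], atol=1e-12)

    def test_same_seed_is_bit_identical(self, reduced_model):
        s = ModeSchedule(seed=11, n_frames=5)
        a = generate_trajectory(reduced_model, s)
        b = generate_trajectory(reduced_model, ModeSchedule(seed=11,
                                                            n_frames=5))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_different_seed_differs(self, reduced_model):
        a = generate_trajectory(reduced_model, ModeSchedule(seed=1,
                                                            n_frames=3))
        b = generate_trajectory(reduced_model, ModeSchedule(seed=2,
                                                            n_frames=3))
        assert not np.allclose(a.coords[-1], b.coords[-1])

    def test_schedule_validation(self, reduced_model):
        bad = ModeSchedule(contacts=[dynamics.Contact(
            donor=10**9, mover=0, target_offset=np.zeros(3), frame=1)])
        with pytest.raises(ValueError, match="absent"):
            generate_trajectory(reduced_model, bad)
        with pytest.raises(ValueError, match="finite"):
            generate_trajectory(reduced_model,
                                ModeSchedule(d5_drop=np.inf))

    def test_fewer_than_two_frames_rejected(self, reduced_model):
        with pytest.raises(ValueError, match="two frames"):
            generate_trajectory(reduced_model, ModeSchedule(n_frames=1))

    def test_boundary_frames_replay_the_generation(self, reduced_model,
                                                   calibrated_schedule_42,
                                                   calibrated_traj):
        topo, first, last, presence = dynamics._boundary_frames(
            reduced_model, calibrated_schedule_42)
        np.testing.assert_allclose(first, calibrated_traj.coords[0], atol=1e-12)
        np.testing.assert_allclose(last, calibrated_traj.coords[-1], atol=1e-12)
        np.testing.assert_array_equal(presence, calibrated_traj.presence[-1])


class TestInvariants:
    def test_restrained_termini_stay_put(self, reduced_model, calibrated_traj,
                                         calibrated_schedule_42):
        atoms = calibrated_traj.topology.atoms
        env = restraint_envelope(atoms)
        pinned = np.flatnonzero((env < 0.06)
                                & (atoms["role"] != "water").to_numpy())
        disp = np.linalg.norm(
            calibrated_traj.coords[:, pinned, :]
            - calibrated_traj.coords[0][None, pinned, :], axis=2)
        bound = 3 * (calibrated_schedule_42.thermal_sigma
                     + 0.05 * (calibrated_schedule_42.drift_amplitude
                               + calibrated_schedule_42.d5_drop
                               + calibrated_schedule_42.gap_contraction
                               + abs(calibrated_schedule_42.packing_strain) * 40))
        assert disp.max() < max(bound, 1.5)

    def test_modes_are_layer_local(self, reduced_model, calibrated_schedule_42,
                                   calibrated_traj):
        # a noise-only run with the same seed moves the core layer
        # identically: mode application leaves the core untouched
        import dataclasses
        noise_only = dataclasses.replace(
            calibrated_schedule_42, telopeptide_shift=0.0, d5_drop=0.0,
            d5_bulge=0.0, gap_contraction=0.0, packing_strain=0.0,
            contacts=[], waters=list(calibrated_schedule_42.waters),
        )
        ref = generate_trajectory(reduced_model, noise_only)
        atoms = calibrated_traj.topology.atoms
        core = np.flatnonzero(
            (atoms["layer"] == "core").to_numpy()
            & (atoms["role"] != "water").to_numpy())
        np.testing.assert_allclose(calibrated_traj.coords[-1][core],
                                   ref.coords[-1][core], atol=1e-9)

    def test_scheduled_contacts_bonded_at_and_after_their_frame(
            self, calibrated_traj, calibrated_schedule_42):
        coords_mid = calibrated_traj.coords
        for c in calibrated_schedule_42.contacts[::25]:
            for t in (c.frame, calibrated_traj.n_frames - 1):
                d = np.linalg.norm(coords_mid[t][c.mover]
                                   - coords_mid[t][c.donor])
                assert d <= 3.0 + 1e-6

    def test_water_expulsion_schedule_is_respected(self, calibrated_traj,
                                                   calibrated_schedule_42):
        n_prot = (calibrated_traj.topology.atoms["role"] != "water").sum()
        for w_i, w in enumerate(calibrated_schedule_42.waters):
            col = calibrated_traj.presence[:, n_prot + w_i]
            if w.expel_frame is None:
                assert col.all()
            else:
                assert col[:w.expel_frame].all()
                assert not col[w.expel_frame:].any()

    def test_contact_schedule_is_monotone(self, calibrated_schedule_42):
        frames = [c.frame for c in calibrated_schedule_42.contacts]
        assert frames == sorted(frames)
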