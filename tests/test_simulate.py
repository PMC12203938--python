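"""Tests of the synthetic-data generator against closed-form oracles and
its own ground-truth manifests."""
import dataclasses

import numpy as np
import pytest

from smstoich import simulate
from smstoich.errors import CapacityError, InvalidParameterError
from smstoich.types import ChannelTransform


class TestSimulateTrajectory:
    def test_zero_fluorophores_gives_flat_background(self, quiet_acq, unit_fluor):
        traj, steps = simulate.simulate_trajectory(0, unit_fluor, quiet_acq, seed=1)
        assert steps == []
        assert np.allclose(traj.intensity, quiet_acq.background_mean)

    def test_forced_bleach_frames_give_exact_staircase(self, quiet_acq, fixed_fluor):
        traj, steps = simulate.simulate_trajectory(
            3, fixed_fluor, quiet_acq, seed=1, bleach_frames=np.array([10, 20, 30])
        )
        x = traj.intensity
        assert np.allclose(x[:10], 3 * 200.0)
        assert np.allclose(x[10:20], 2 * 200.0)
        assert np.allclose(x[20:30], 200.0)
        assert np.allclose(x[30:], 0.0)
        assert sorted(s.bleach_frame for s in steps) == [10, 20, 30]
        assert all(s.height == 200.0 for s in steps)

    def test_bleach_counts_match_geometric_survival(self, unit_fluor):
        """Mean bleach events by frame 100 ~ n (1 - (1-p)^100), within 3 SE."""
        p = 0.01
        fluor = dataclasses.replace(unit_fluor, bleach_rate=p)
        acq = simulate.AcquisitionParams(
            n_frames=120, shot_noise=False, read_noise_sd=0.0, background_mean=0.0
        )
        rng = np.random.default_rng(42)
        n_rep, n_fl = 3000, 5
        bleached = []
        for _ in range(n_rep):
            _, steps = simulate.simulate_trajectory(n_fl, fluor, acq, rng)
            bleached.append(sum(s.bleach_frame <= 100 for s in steps))
        q = 1 - (1 - p) ** 100
        expected = n_fl * q
        se = np.sqrt(n_fl * q * (1 - q) / n_rep)
        assert abs(np.mean(bleached) - expected) < 3 * se

    def test_frame_zero_mean_matches_expected_intensity(self, unit_fluor):
        """With noise on, the mean frame-0 intensity over replicates sits
        within 3 SE of background + n * i_step_mean."""
        acq = simulate.AcquisitionParams(
            n_frames=5, shot_noise=True, read_noise_sd=10.0, background_mean=100.0
        )
        rng = np.random.default_rng(7)
        vals = [
            simulate.simulate_trajectory(4, unit_fluor, acq, rng)[0].intensity[0]
            for _ in range(3000)
        ]
        expected = 100.0 + 4 * 200.0
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_deterministic_under_fixed_seed(self, snr8_acq, unit_fluor):
        a, _ = simulate.simulate_trajectory(5, unit_fluor, snr8_acq, seed=99)
        b, _ = simulate.simulate_trajectory(5, unit_fluor, snr8_acq, seed=99)
        assert np.array_equal(a.intensity, b.intensity)

    def test_invalid_parameters_raise(self, unit_fluor, quiet_acq):
        with pytest.raises(InvalidParameterError):
            simulate.simulate_trajectory(-1, unit_fluor, quiet_acq, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate.AcquisitionParams(n_frames=0)
        with pytest.raises(InvalidParameterError):
            simulate.FluorophoreModel(bleach_rate=0.0)


class TestSimulatePopulation:
    def test_zero_colocalised_fraction_gives_zero_complexes(self):
        kin = simulate.preset_kinetics("negative-control")
        mols = simulate.simulate_population(
            kin, simulate.LabellingModel({1: 1.0}), 100, 0.0, seed=0
        )
        assert all(m.complex_id is None for m in mols)
        assert all(m.channel == "client" for m in mols)

    def test_realised_fraction_within_binomial_se(self):
        kin = simulate.preset_kinetics("aBc-FLUC")   # frac 0.40 at 0.3 h
        n = 10_000
        mols = simulate.simulate_population(
            kin, simulate.LabellingModel({1: 1.0}), n, 0.3, seed=1
        )
        clients = [m for m in mols if m.channel == "client"]
        frac = np.mean([m.complex_id is not None for m in clients])
        assert abs(frac - 0.40) < 3 * np.sqrt(0.4 * 0.6 / n)

    @pytest.mark.parametrize(
        "preset,timepoint,median",
        [("aBc-FLUC", 1.0, 2.5), ("Hsp27-rhodanese", 7.0, 0.67)],
    )
    def test_preset_median_molar_ratio(self, preset, timepoint, median):
        kin = simulate.preset_kinetics(preset)
        mols = simulate.simulate_population(
            kin, simulate.LabellingModel({1: 1.0}), 10_000, timepoint, seed=2
        )
        clients = {m.complex_id: m for m in mols if m.channel == "client" and m.complex_id is not None}
        ratios = [
            m.subunits / clients[m.complex_id].subunits
            for m in mols
            if m.channel == "shsp"
        ]
        assert abs(np.median(ratios) - median) / median < 0.10

    def test_unknown_timepoint_raises(self):
        kin = simulate.preset_kinetics("aBc-FLUC")
        with pytest.raises(InvalidParameterError):
            simulate.simulate_population(
                kin, simulate.LabellingModel({1: 1.0}), 10, 2.7, seed=0
            )

    def test_labelling_model_mean(self):
        lab = simulate.LabellingModel({0: 0.1, 1: 0.5, 2: 0.4})
        assert lab.mean == pytest.approx(1.3)
        with pytest.raises(InvalidParameterError):
            simulate.LabellingModel({1: 0.6, 2: 0.6})


class TestRenderField:
    def _one_molecule(self, subunits=4):
        return [
            simulate.TrueMolecule(
                molecule_id=0, channel="client", subunits=subunits,
                n_fluorophores=subunits, complex_id=None,
            )
        ]

    def test_integrated_spot_matches_trajectory_model(self, fixed_fluor):
        """Noise off: per-frame integrated spot intensity within 1% of the
        emission model (PSF truncation only)."""
        acq = simulate.AcquisitionParams(
            n_frames=60, field_px=(48, 48), shot_noise=False,
            read_noise_sd=0.0, background_mean=50.0,
        )
        stack, _, manifest = simulate.render_field(
            self._one_molecule(), acq, ChannelTransform.identity(), seed=3,
            fluor_client=fixed_fluor, fluor_shsp=fixed_fluor,
        )
        m = manifest.molecules[0]
        alive = np.array(
            [sum(s.height for s in m.steps if s.bleach_frame > f) for f in range(acq.n_frames)]
        )
        integrated = stack.sum(axis=(1, 2)) - 50.0 * 48 * 48
        live = alive > 0
        assert np.all(
            np.abs(integrated[live] - alive[live]) <= 0.01 * alive[live] + 1e-6
        )

    def test_identity_transform_positions_match(self):
        kin = simulate.preset_kinetics("aBc-FLUC")
        mols = simulate.simulate_population(
            kin, simulate.LabellingModel({1: 1.0}), 20, 1.0, seed=4
        )
        acq = simulate.AcquisitionParams(n_frames=5, field_px=(96, 96))
        _, _, man = simulate.render_field(mols, acq, ChannelTransform.identity(), seed=5)
        coloc_clients = {
            m.complex_id: m.position for m in man.molecules
            if m.channel == "client" and m.complex_id is not None
        }
        for m in man.molecules:
            if m.channel == "shsp" and m.complex_id in coloc_clients:
                assert m.position == coloc_clients[m.complex_id]

    def test_translation_offsets_exact_in_manifest(self):
        tf = ChannelTransform.translation(3.2, -1.7)
        kin = simulate.preset_kinetics("aBc-FLUC")
        mols = simulate.simulate_population(
            kin, simulate.LabellingModel({1: 1.0}), 30, 1.0, seed=6
        )
        acq = simulate.AcquisitionParams(n_frames=5, field_px=(96, 96))
        _, _, man = simulate.render_field(mols, acq, tf, seed=7)
        pos_a = np.array([m.position for m in man.molecules if m.channel == "shsp"])
        if len(pos_a):
            mapped = man.positions("shsp")
            np.testing.assert_allclose(mapped - pos_a, [[3.2, -1.7]] * len(pos_a), atol=1e-9)

    def test_fluorophore_conservation(self):
        kin = simulate.preset_kinetics("aBc-FLUC")
        mols = simulate.simulate_population(
            kin, simulate.LabellingModel({1: 0.5, 2: 0.5}), 25, 0.6, seed=8
        )
        acq = simulate.AcquisitionParams(n_frames=5, field_px=(96, 96))
        _, _, man = simulate.render_field(mols, acq, ChannelTransform.identity(), seed=9)
        assert man.total_fluorophores == sum(m.n_fluorophores for m in man.molecules)
        assert man.total_fluorophores == sum(len(m.steps) * 0 + m.n_fluorophores for m in mols)

    def test_capacity_error_when_field_too_small(self):
        mols = [
            simulate.TrueMolecule(molecule_id=i, channel="client", subunits=1, n_fluorophores=1)
            for i in range(500)
        ]
        acq = simulate.AcquisitionParams(n_frames=2, field_px=(32, 32))
        with pytest.raises(CapacityError):
            simulate.render_field(mols, acq, ChannelTransform.identity(), seed=0)

    def test_stack_determinism(self):
        mols = self._one_molecule()
        acq = simulate.AcquisitionParams(n_frames=10, field_px=(48, 48))
        import copy
        a, _, _ = simulate.render_field(copy.deepcopy(mols), acq, ChannelTransform.identity(), seed=11)
        b, _, _ = simulate.render_field(copy.deepcopy(mols), acq, ChannelTransform.identity(), seed=11)
        assert np.array_equal(a, b)


class TestMakeBeadPair:
    def test_rotation_truth_matches_formula(self):
        acq = simulate.AcquisitionParams(n_frames=1, field_px=(64, 64))
        tf = ChannelTransform.rotation(0.5, centre=(31.5, 31.5))
        _, _, pos = simulate.make_bead_pair(3, tf, acq, seed=1)
        th = np.deg2rad(0.5)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected = (pos - [31.5, 31.5]) @ rot.T + [31.5, 31.5]
        np.testing.assert_allclose(tf.apply(pos), expected, atol=1e-9)

    def test_zero_beads_raises(self):
        acq = simulate.AcquisitionParams(n_frames=1)
        with pytest.raises(InvalidParameterError):
            simulate.make_bead_pair(0, ChannelTransform.identity(), acq, seed=0)
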