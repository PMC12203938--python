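"""Stack correction, bead registration, spot detection and photometry."""
import numpy as np
import pytest

from smstoich import register, simulate
from smstoich.errors import (
    BorderExclusionError,
    DimensionError,
    InvalidParameterError,
    RegistrationError,
)
from smstoich.types import ChannelTransform, Spot, TrueMolecule


def _noise_free_acq(**kw):
    defaults = dict(
        n_frames=1, field_px=(64, 64), shot_noise=False,
        read_noise_sd=0.0, background_mean=100.0,
    )
    defaults.update(kw)
    return simulate.AcquisitionParams(**defaults)


class TestCorrectStack:
    def test_offset_and_unit_flatfield(self):
        stack = np.full((2, 4, 4), 350.0)
        out = register.correct_stack(stack, dark_offset=100.0, flatfield=np.ones((4, 4)))
        assert np.allclose(out, 250.0)

    def test_identity_when_no_correction(self):
        stack = np.random.default_rng(0).uniform(0, 100, (3, 8, 8))
        assert np.array_equal(register.correct_stack(stack), stack)

    def test_vignette_round_trip(self):
        """A stack multiplied by a known vignette map and corrected with
        that map recovers the flat stack."""
        rng = np.random.default_rng(1)
        flat_stack = rng.uniform(50, 200, (4, 16, 16))
        yy, xx = np.mgrid[0:16, 0:16]
        vignette = 1.0 - 0.4 * ((xx - 7.5) ** 2 + (yy - 7.5) ** 2) / (2 * 7.5**2)
        corrected = register.correct_stack(flat_stack * vignette, flatfield=vignette)
        np.testing.assert_allclose(corrected, flat_stack, rtol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            register.correct_stack(np.ones((2, 4, 4)), flatfield=np.ones((5, 5)))
        with pytest.raises(InvalidParameterError):
            register.correct_stack(np.ones((2, 4, 4)), flatfield=np.zeros((4, 4)))


class TestEstimateTransform:
    def test_identity_recovered_noise_free(self):
        acq = _noise_free_acq(field_px=(96, 96))
        img_a, img_b, _ = simulate.make_bead_pair(
            8, ChannelTransform.identity(), acq, seed=1
        )
        est = register.estimate_transform(img_a, img_b, model="affine")
        np.testing.assert_allclose(
            est.matrix, ChannelTransform.identity().matrix, atol=1e-3
        )
        assert est.residual_rms_px < 0.05

    def test_translation_recovered_within_tenth_pixel(self):
        acq = simulate.AcquisitionParams(n_frames=1, field_px=(96, 96))
        truth = ChannelTransform.translation(3.2, -1.7)
        img_a, img_b, _ = simulate.make_bead_pair(10, truth, acq, seed=2)
        est = register.estimate_transform(img_a, img_b, model="translation")
        np.testing.assert_allclose(est.matrix[:, 2], [3.2, -1.7], atol=0.1)

    def test_underdetermined_affine_raises(self):
        acq = _noise_free_acq()
        img_a, img_b, _ = simulate.make_bead_pair(
            2, ChannelTransform.identity(), acq, seed=3, min_separation_px=20.0
        )
        with pytest.raises(RegistrationError) as err:
            register.estimate_transform(img_a, img_b, model="affine")
        assert err.value.n_matched is not None and err.value.n_matched <= 2

    @pytest.mark.parametrize("model", ["translation", "similarity", "affine"])
    def test_exact_on_noiseless_centroids(self, model):
        """Least-squares fit is exact for its own model class on exactly
        known point pairs."""
        rng = np.random.default_rng(4)
        src = rng.uniform(10, 90, (12, 2))
        truth = ChannelTransform(np.array([[1.002, -0.004, 2.5], [0.003, 0.998, -3.1]]))
        if model == "translation":
            truth = ChannelTransform.translation(2.5, -3.1)
        elif model == "similarity":
            truth = ChannelTransform.rotation(1.0, centre=(50, 50))
        dst = truth.apply(src)
        est = register.fit_transform_points(src, dst, model=model)
        assert est.residual_rms_px < 1e-6
        np.testing.assert_allclose(est.matrix, truth.matrix, atol=1e-9)


class TestDetectSpots:
    def test_recall_and_precision_on_dense_field(self):
        """50 well-separated spots at SNR >= 10: recall and precision both
        >= 0.98 within a 1 px match radius."""
        mols = [
            TrueMolecule(molecule_id=i, channel="client", subunits=5, n_fluorophores=5)
            for i in range(50)
        ]
        acq = simulate.AcquisitionParams(n_frames=10, field_px=(200, 200))
        stack, _, man = simulate.render_field(
            mols, acq, ChannelTransform.identity(), seed=5
        )
        spots = register.detect_spots(stack)
        true = man.positions("client")
        det = np.array([[s.x, s.y] for s in spots])
        from scipy.spatial.distance import cdist

        d = cdist(true, det)
        recall = np.mean(d.min(axis=1) < 1.0)
        precision = np.mean(d.min(axis=0) < 1.0)
        assert recall >= 0.98
        assert precision >= 0.98

    def test_blank_field_usually_empty(self):
        """Background-only frames produce zero detections in >= 95% of
        seeds at the default threshold."""
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stack = rng.poisson(100.0, (10, 128, 128)).astype(float)
            stack += rng.normal(0, 10.0, stack.shape)
            empty += len(register.detect_spots(stack)) == 0
        assert empty / 20 >= 0.95

    def test_noiseless_spot_subpixel_centre(self):
        mols = [TrueMolecule(molecule_id=0, channel="client", subunits=3, n_fluorophores=3)]
        acq = _noise_free_acq(n_frames=3, field_px=(41, 41))
        stack, _, man = simulate.render_field(
            mols, acq, ChannelTransform.identity(), seed=6,
            fluor_client=simulate.FluorophoreModel(i_step_cv=0.0, bleach_rate=0.001),
        )
        (spot,) = register.detect_spots(stack, threshold=10.0)
        tx, ty = man.molecules[0].position
        assert np.hypot(spot.x - tx, spot.y - ty) < 0.1

    def test_empty_stack_raises(self):
        with pytest.raises(DimensionError):
            register.detect_spots(np.empty((0, 4, 4)))


class TestExtractTrajectory:
    def _render_single(self, seed=7, noise=False):
        mols = [TrueMolecule(molecule_id=0, channel="client", subunits=3, n_fluorophores=3)]
        acq = simulate.AcquisitionParams(
            n_frames=80, field_px=(41, 41), shot_noise=noise,
            read_noise_sd=5.0 if noise else 0.0, background_mean=100.0,
        )
        stack, _, man = simulate.render_field(
            mols, acq, ChannelTransform.identity(), seed=seed,
            fluor_client=simulate.FluorophoreModel(i_step_cv=0.0, bleach_rate=0.01),
        )
        return stack, man

    def test_noiseless_staircase_recovered_within_one_percent(self):
        stack, man = self._render_single()
        m = man.molecules[0]
        spot = Spot(x=m.position[0], y=m.position[1], channel="client")
        # a 4 px aperture captures >99.9% of the sigma = 1.1 px PSF, so the
        # trace should match the rendered staircase within 1%
        traj = register.extract_trajectory(
            stack, spot, aperture_radius_px=4.0, annulus=(6.0, 9.0)
        )
        truth = np.array(
            [sum(s.height for s in m.steps if s.bleach_frame > f) for f in range(80)]
        )
        live = truth > 0
        assert np.all(np.abs(traj.intensity[live] - truth[live]) <= 0.01 * truth[live])

    def test_background_location_near_zero(self):
        stack, _ = self._render_single(noise=True)
        spot = Spot(x=10.0, y=30.0, channel="client")
        traj = register.extract_trajectory(stack, spot)
        se = np.std(traj.intensity, ddof=1) / np.sqrt(len(traj))
        assert abs(np.mean(traj.intensity)) < 3 * se + 1e-9

    def test_corner_spot_border_excluded(self):
        stack, _ = self._render_single()
        with pytest.raises(BorderExclusionError):
            register.extract_trajectory(stack, Spot(x=1.0, y=1.0, channel="client"))

    def test_linearity_in_pixel_values(self):
        stack, man = self._render_single()
        m = man.molecules[0]
        spot = Spot(x=m.position[0], y=m.position[1], channel="client")
        t1 = register.extract_trajectory(stack, spot).intensity
        t2 = register.extract_trajectory(stack * 2.0, spot).intensity
        np.testing.assert_allclose(t2, 2.0 * t1, rtol=1e-9, atol=1e-6)

    def test_bad_annulus_raises(self):
        stack, _ = self._render_single()
        with pytest.raises(InvalidParameterError):
            register.extract_trajectory(
                stack, Spot(x=20, y=20, channel="c"), aperture_radius_px=6.0, annulus=(5, 8)
            )
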