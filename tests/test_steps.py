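"""Step counting: segmentation vs the brute-force oracle, classification,
unit-step estimation and labelling correction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smstoich import simulate, steps
from smstoich.errors import EstimationError, InvalidParameterError, TrainingError
from smstoich.types import Trajectory

from conftest import make_staircase


class TestDetectSteps:
    def test_noiseless_staircase_exact(self):
        x = make_staircase(3, step=100.0, spacing=10, first=10)
        fit = steps.detect_steps(x)
        assert list(fit.changepoints) == [10, 20, 30]
        np.testing.assert_allclose(fit.step_sizes, [100.0, 100.0, 100.0])
        assert fit.final_step == pytest.approx(100.0)
        assert not fit.incomplete_bleach

    def test_constant_trace_flagged_no_steps(self):
        fit = steps.detect_steps(np.full(200, 7.0))
        assert fit.no_steps
        assert fit.n_steps == 0
        assert fit.final_step is None

    def test_incomplete_bleach_flagged(self):
        x = make_staircase(2, step=100.0) + 300.0   # never reaches baseline
        fit = steps.detect_steps(x)
        assert fit.incomplete_bleach
        assert fit.final_step is None

    def test_too_short_trace_raises(self):
        with pytest.raises(InvalidParameterError):
            steps.detect_steps(np.array([1.0, 2.0, 3.0]))

    def test_never_worse_than_brute_force_oracle(self):
        """The DP is an exact optimiser: its penalised cost is never above
        the exhaustive enumeration's, and when the enumeration attains the
        same cost the change points agree."""
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(30, 51))
            k = int(rng.integers(0, 4))
            x = np.zeros(n)
            cps = np.sort(rng.choice(np.arange(3, n - 3), size=k, replace=False))
            bounds = [0, *cps, n]
            for lv, (a, b) in zip(200.0 * np.arange(k, -1, -1), zip(bounds[:-1], bounds[1:])):
                x[a:b] = lv
            x += rng.normal(0, 25, n)
            sigma = steps.robust_noise_sd(x)
            pen = steps.DEFAULT_PENALTY_BETA * sigma**2 * np.log(n)
            fit = steps.detect_steps(x, penalty=pen)
            bf_cps, bf_cost = steps.brute_force_segment(x, pen)
            assert fit.score <= bf_cost + 1e-9
            if abs(fit.score - bf_cost) < 1e-9:
                assert list(fit.changepoints) == bf_cps

    def test_bayes_method_agrees_on_clear_staircase(self):
        x = make_staircase(3, step=200.0, spacing=20, first=20, noise_sd=20.0, seed=3)
        ls = steps.detect_steps(x, method="ls")
        by = steps.detect_steps(x, method="bayes")
        assert list(ls.changepoints) == list(by.changepoints) == [20, 40, 60]

    def test_false_step_rate_below_two_percent_at_snr8(self):
        """Penalty calibration: constant traces at SNR 8 rarely gain steps."""
        rng = np.random.default_rng(11)
        false = sum(
            steps.detect_steps(600 + rng.normal(0, 25, 300)).n_steps > 0
            for _ in range(200)
        )
        assert false / 200 < 0.02 + 1e-9


@pytest.fixture(scope="module")
def training_data():
    rng = np.random.default_rng(0)
    acq = simulate.AcquisitionParams(
        n_frames=400, shot_noise=False, read_noise_sd=25.0, background_mean=0.0
    )
    fluor = simulate.FluorophoreModel(i_step_mean=200, i_step_cv=0.2, bleach_rate=0.005)
    trajs, labels = [], []
    for _ in range(250):
        n = int(rng.integers(1, 13))
        t, _ = simulate.simulate_trajectory(n, fluor, acq, rng, subtract_background=True)
        trajs.append(t)
        labels.append("stepwise")
    for kind in ("flat", "drift", "non_bleaching", "erratic"):
        for _ in range(60):
            trajs.append(simulate.make_artefact_trace(kind, acq, fluor, rng))
            labels.append("reject")
    return trajs, labels


class TestClassifier:
    def test_trained_classifier_validation_accuracy(self, training_data):
        model = steps.train_classifier(*training_data, seed=1)
        assert model.validation_accuracy >= 0.95

    def test_heuristic_filter_meets_same_threshold(self, training_data):
        trajs, labels = training_data
        pred = [steps.heuristic_classify(t)[0] for t in trajs]
        assert np.mean([p == l for p, l in zip(pred, labels)]) >= 0.95

    def test_same_seed_gives_identical_model(self, training_data):
        import pickle

        m1 = steps.train_classifier(*training_data, seed=3)
        m2 = steps.train_classifier(*training_data, seed=3)
        assert pickle.dumps(m1.estimator) == pickle.dumps(m2.estimator)
        assert m1.validation_accuracy == m2.validation_accuracy

    def test_single_class_input_raises(self, training_data):
        trajs, _ = training_data
        with pytest.raises(TrainingError):
            steps.train_classifier(trajs[:10], ["stepwise"] * 10, seed=0)
        with pytest.raises(TrainingError):
            steps.train_classifier([], [], seed=0)

    def test_staircase_accepted_noise_rejected(self, training_data):
        model = steps.train_classifier(*training_data, seed=2)
        stair = Trajectory(make_staircase(3, step=200.0, spacing=30, first=30, noise_sd=10, seed=1))
        assert steps.classify_trajectory(stair, model)[0] == "stepwise"
        noise = Trajectory(np.random.default_rng(0).normal(0, 30, 300))
        assert steps.classify_trajectory(noise, model)[0] == "reject"

    def test_monotone_drift_mostly_rejected(self, training_data):
        model = steps.train_classifier(*training_data, seed=4)
        rng = np.random.default_rng(9)
        acq = simulate.AcquisitionParams(
            n_frames=400, shot_noise=False, read_noise_sd=25.0, background_mean=0.0
        )
        fluor = simulate.FluorophoreModel()
        rejected = sum(
            steps.classify_trajectory(
                simulate.make_artefact_trace("drift", acq, fluor, rng), model
            )[0]
            == "reject"
            for _ in range(50)
        )
        assert rejected / 50 >= 0.90

    def test_short_trace_rejected_outright(self, training_data):
        model = steps.train_classifier(*training_data, seed=5)
        label, conf = steps.classify_trajectory(Trajectory(np.ones(10)), model)
        assert label == "reject" and conf == 1.0


class TestUnitStepAndCounting:
    def test_unit_step_is_median_of_final_steps(self):
        fits = [steps.detect_steps(make_staircase(1, step=s)) for s in (90.0, 100.0, 110.0)]
        assert steps.estimate_unit_step(fits) == pytest.approx(100.0)
        single = [steps.detect_steps(make_staircase(1, step=137.0))]
        assert steps.estimate_unit_step(single) == pytest.approx(137.0)

    def test_empty_cohort_raises(self):
        with pytest.raises(EstimationError):
            steps.estimate_unit_step([])

    def test_unit_step_on_dispersed_cohort_near_lognormal_median(self, snr8_acq, unit_fluor):
        """n=500 molecules with CV-0.2 lognormal brightness: the cohort
        I_step lands within 5% of the 200-count mean (sampling oracle:
        lognormal median = mean / sqrt(1 + cv^2) ~ 196)."""
        rng = np.random.default_rng(21)
        fits = []
        for _ in range(500):
            nf = int(rng.integers(1, 6))
            traj, _ = simulate.simulate_trajectory(
                nf, unit_fluor, snr8_acq, rng, subtract_background=True
            )
            fit = steps.detect_steps(traj)
            if fit.final_step is not None:
                fits.append(fit)
        i_step = steps.estimate_unit_step(fits)
        assert abs(i_step - 200.0) / 200.0 < 0.05

    def test_count_subunits_ratio(self):
        traj = Trajectory(make_staircase(3, step=100.0, spacing=10, first=25, n_frames=80))
        size = steps.count_subunits(traj, i_step=100.0)
        assert size.subunits_raw == pytest.approx(3.0)
        with pytest.raises(InvalidParameterError):
            steps.count_subunits(traj, i_step=0.0)
        with pytest.raises(InvalidParameterError):
            steps.count_subunits(Trajectory(np.ones(10)), i_step=100.0)

    def test_mean_fluorophores_per_monomer(self):
        two_step = [steps.detect_steps(make_staircase(2)) for _ in range(3)]
        assert steps.mean_fluorophores_per_monomer(two_step) == pytest.approx(2.0)
        one_step = [steps.detect_steps(make_staircase(1)) for _ in range(3)]
        assert steps.mean_fluorophores_per_monomer(one_step) == pytest.approx(1.0)
        with pytest.raises(EstimationError):
            steps.mean_fluorophores_per_monomer([])

    def test_labelling_correction_mixed_cohort(self, snr8_acq, unit_fluor):
        """Monomer control with p(1)=p(2)=0.5 recovers ~1.5 fluorophores per
        monomer within 5% at n=500."""
        rng = np.random.default_rng(31)
        lab = simulate.LabellingModel({1: 0.5, 2: 0.5})
        fits = []
        for _ in range(500):
            nf = lab.sample(1, rng)
            traj, _ = simulate.simulate_trajectory(
                nf, unit_fluor, snr8_acq, rng, subtract_background=True
            )
            fit = steps.detect_steps(traj)
            if not fit.no_steps:
                fits.append(fit)
        est = steps.mean_fluorophores_per_monomer(fits)
        assert abs(est - 1.5) / 1.5 < 0.05

    def test_correct_for_labelling_arithmetic(self):
        size = steps.MoleculeSize(i_initial=1000.0, i_step=100.0, subunits_raw=10.0)
        same = steps.correct_for_labelling(size, 1.0)
        assert same.subunits_corrected == pytest.approx(10.0)
        corr = steps.correct_for_labelling(size, 1.5)
        assert corr.subunits_corrected == pytest.approx(6.6667, rel=1e-3)
        assert corr.subunits_int == 7          # round half-up
        with pytest.raises(InvalidParameterError):
            steps.correct_for_labelling(size, 0.0)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(min_value=0.01, max_value=100.0), k=st.integers(1, 8))
    def test_scale_invariance_of_counting(self, scale, k):
        """Multiplying a trajectory and I_step by the same constant leaves
        the subunit count unchanged."""
        x = make_staircase(k, step=100.0, spacing=5, first=25, n_frames=80)
        a = steps.count_subunits(Trajectory(x), 100.0)
        b = steps.count_subunits(Trajectory(x * scale), 100.0 * scale)
        assert b.subunits_raw == pytest.approx(a.subunits_raw, rel=1e-9)

    def test_recovery_error_degrades_monotonically_with_snr(self, fixed_fluor):
        """With dispersion-free fluorophores (read noise the only error
        source), the median absolute subunit-recovery error is
        non-decreasing as SNR falls from 12 to 3."""
        import dataclasses

        rng = np.random.default_rng(100)
        true = rng.integers(2, 11, size=100)
        lab = simulate.LabellingModel({1: 1.0})
        fluor = dataclasses.replace(fixed_fluor, bleach_rate=0.004)
        errors = []
        for snr in (12, 8, 5, 3):
            acq = simulate.AcquisitionParams(
                n_frames=700, shot_noise=False,
                read_noise_sd=200.0 / snr, background_mean=0.0,
            )
            trajs, _ = simulate.simulate_cohort(true, lab, fluor, acq, seed=17)
            fits = [steps.detect_steps(t) for t in trajs]
            try:
                i_step = steps.estimate_unit_step(fits)
            except EstimationError:
                errors.append(np.inf)
                continue
            rec = np.array([steps.count_subunits(t, i_step).subunits_raw for t in trajs])
            errors.append(float(np.median(np.abs(rec - true))))
        assert all(b >= a - 0.01 for a, b in zip(errors, errors[1:]))
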