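import numpy as np
import pandas as pd
import pytest

from saccadapt import model, synthetic_data as sd
from saccadapt.errors import DesignError


class TestBuildDesign:
    @pytest.mark.parametrize("experiment", sd.EXPERIMENTS)
    @pytest.mark.parametrize("condition", sd.CONDITIONS)
    @pytest.mark.parametrize("side", sd.SIDES)
    def test_phase_schedule_and_breaks(self, experiment, condition, side):
        d = sd.build_design(experiment, condition, side)
        assert d.n_trials == 350
        counts = pd.Series(d.phase).value_counts()
        assert counts["baseline"] == 50
        assert counts["adaptation"] == 200
        assert counts["retention"] == 100
        # phases in order: baseline then adaptation then retention
        assert list(dict.fromkeys(d.phase)) == ["baseline", "adaptation", "retention"]
        assert d.set_break_after == tuple(range(50, 351, 50))

    @pytest.mark.parametrize("condition", sd.CONDITIONS)
    def test_candidates_mirror_each_other(self, condition):
        d = sd.build_design("small_target", condition, "plus")
        adapt = d.phase == "adaptation"
        both = np.isfinite(d.loc_first) & np.isfinite(d.loc_second)
        assert not both[~adapt].any()
        np.testing.assert_allclose(d.loc_first[both], -d.loc_second[both])
        shown = np.where(np.isfinite(d.loc_first), d.loc_first, d.loc_second)
        assert np.all(np.abs(shown[adapt]) == 2.0)

    def test_discriminate_first_geometry(self):
        d = sd.build_design("small_target", "discriminate_1st", "plus")
        adapt = d.phase == "adaptation"
        assert np.all(d.loc_first[adapt] == 2.0)
        assert np.all(d.loc_second[adapt] == -2.0)
        assert np.all(d.loc_task_relevant[adapt] == 2.0)

    def test_single_candidate_conditions_define_exactly_one_location(self):
        d = sd.build_design("small_target", "discriminate_2nd_no_1st", "plus")
        adapt = d.phase == "adaptation"
        assert np.all(np.isnan(d.loc_first[adapt]))
        assert np.all(d.loc_second[adapt] == -2.0)
        assert np.all(d.loc_task_relevant[adapt] == -2.0)

        d = sd.build_design("small_target", "discriminate_1st_no_2nd", "plus")
        adapt = d.phase == "adaptation"
        assert np.all(d.loc_first[adapt] == 2.0)
        assert np.all(np.isnan(d.loc_second[adapt]))
        assert np.all(d.loc_task_relevant[adapt] == 2.0)

    @pytest.mark.parametrize("condition", sd.CONDITIONS)
    def test_task_relevant_location_zero_outside_adaptation(self, condition):
        d = sd.build_design("large_target", condition, "minus")
        outside = d.phase != "adaptation"
        assert np.all(d.loc_task_relevant[outside] == 0.0)

    def test_invalid_enums_rejected(self):
        with pytest.raises(DesignError):
            sd.build_design("tiny_target", "discriminate_1st", "plus")
        with pytest.raises(DesignError):
            sd.build_design("small_target", "discriminate_3rd", "plus")
        with pytest.raises(DesignError):
            sd.build_design("small_target", "discriminate_1st", "left")

    def test_deterministic(self):
        a = sd.build_design("small_target", "discriminate_2nd", "plus")
        b = sd.build_design("small_target", "discriminate_2nd", "plus")
        np.testing.assert_array_equal(a.loc_task_relevant, b.loc_task_relevant)
        np.testing.assert_array_equal(a.phase, b.phase)


class TestSimulateAmplitudes:
    def test_noiseless_matches_forward_simulate_bitwise(self, design_plus):
        params = model.ModelParams(w=0.4, r=0.25, d=1, init=0.0)
        truth = sd.GroundTruth(params_true=params, noise_sd=0.0)
        amps = sd.simulate_amplitudes(design_plus, truth, seed=0)
        state = model.forward_simulate(params, design_plus.loc_task_relevant)
        np.testing.assert_array_equal(amps, state.hor_amp)

    def test_no_learning_no_noise_constant_at_init(self, design_plus):
        truth = sd.GroundTruth(
            params_true=model.ModelParams(w=0.0, r=0.0, d=1, init=0.3), noise_sd=0.0
        )
        amps = sd.simulate_amplitudes(design_plus, truth, seed=0)
        np.testing.assert_allclose(amps, 0.3)

    def test_gradual_geometric_closed_form(self, design_plus):
        truth = sd.GroundTruth(
            params_true=model.ModelParams(w=0.0, r=0.3, d=1, init=0.0), noise_sd=0.0
        )
        amps = sd.simulate_amplitudes(design_plus, truth, seed=0)
        k = np.arange(1, 201)
        expected = 2.0 * (1.0 - 0.7 ** (k - 1))
        np.testing.assert_allclose(amps[50:250], expected, atol=1e-12)
        assert amps[51] == pytest.approx(0.6)
        assert amps[52] == pytest.approx(1.02)

    def test_strategic_step(self, design_plus):
        truth = sd.GroundTruth(
            params_true=model.ModelParams(w=1.0, r=0.0, d=1, init=0.0), noise_sd=0.0
        )
        amps = sd.simulate_amplitudes(design_plus, truth, seed=0)
        np.testing.assert_allclose(amps[:51], 0.0)      # through 1st adaptation trial
        np.testing.assert_allclose(amps[51:250], 2.0)   # exact step to loc*d

    def test_seed_determinism(self, design_plus):
        truth = sd.GroundTruth(params_true=model.ModelParams(0.5, 0.2, 1, 0.0))
        a = sd.simulate_amplitudes(design_plus, truth, seed=11)
        b = sd.simulate_amplitudes(design_plus, truth, seed=11)
        c = sd.simulate_amplitudes(design_plus, truth, seed=12)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_side_flip_mirrors_exactly(self, design_plus, design_minus):
        truth = sd.GroundTruth(params_true=model.ModelParams(0.5, 0.2, 1, 0.0))
        plus = sd.simulate_amplitudes(design_plus, truth, seed=5)
        minus = sd.simulate_amplitudes(design_minus, truth, seed=5)
        np.testing.assert_array_equal(plus, -minus)


class TestSimulateTrialTrace:
    def test_millisecond_sampling(self):
        tr = sd.simulate_trial_trace(1.0, 10.0, 0.5, 50.0)
        np.testing.assert_allclose(np.diff(tr.t_ms), 1.0)

    def test_no_horizontal_motion(self):
        tr = sd.simulate_trial_trace(0.0, 10.0, 0.5, 50.0)
        np.testing.assert_allclose(tr.x_deg, 0.0)
        assert tr.y_deg[-1] == pytest.approx(10.0, abs=1e-9)

    def test_symmetric_profile_splits_evenly(self):
        from saccadapt import kinematics

        tr = sd.simulate_trial_trace(2.0, 10.0, 0.5, 50.0)
        split = kinematics.split_at_peak(tr)
        assert split.acc_hor_disp == pytest.approx(split.dec_hor_disp, abs=0.06)

    def test_displacement_conservation(self):
        from saccadapt import kinematics

        for frac in (0.2, 0.5, 0.8):
            tr = sd.simulate_trial_trace(2.0, 10.0, frac, 50.0)
            split = kinematics.split_at_peak(tr)
            assert split.acc_hor_disp + split.dec_hor_disp == pytest.approx(
                split.total_hor_disp, abs=1e-12
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_trial_trace(1.0, 10.0, 1.2, 50.0)
        with pytest.raises(ValueError):
            sd.simulate_trial_trace(1.0, 10.0, 0.5, 10.0)


class TestSimulateResponses:
    def test_probability_at_zero_error_is_asymptote(self):
        psy = {"asymptote": 0.9, "chance": 0.25, "scale": 1.0}
        assert sd.response_probability(0.0, psy) == pytest.approx(0.9)

    def test_probability_decays_to_chance(self):
        psy = {"asymptote": 0.9, "chance": 0.25, "scale": 1.0}
        assert sd.response_probability(50.0, psy) == pytest.approx(0.25, abs=1e-6)
        probs = sd.response_probability(np.linspace(0, 10, 50), psy)
        assert np.all(np.diff(probs) <= 0)

    def test_empirical_rate_within_binomial_bounds(self):
        psy = {"asymptote": 0.9, "chance": 0.25, "scale": 1.0}
        e = 1.5
        p = float(sd.response_probability(e, psy))
        n = 10_000
        correct = sd.simulate_responses(np.full(n, e), psy, seed=21)
        sdev = np.sqrt(p * (1 - p) / n)
        assert abs(correct.mean() - p) < 3 * sdev

    def test_seed_determinism(self):
        psy = {"asymptote": 0.8, "chance": 0.25, "scale": 1.0}
        a = sd.simulate_responses(np.ones(100), psy, seed=4)
        b = sd.simulate_responses(np.ones(100), psy, seed=4)
        np.testing.assert_array_equal(a, b)


class TestInjectArtifacts:
    @pytest.fixture
    def clean_trials(self, design_plus):
        truth = sd.GroundTruth(params_true=model.ModelParams(0.5, 0.2, 1, 0.0))
        trials, _ = sd.simulate_participant(design_plus, truth, seed=0)
        return trials

    def test_zero_rates_identity(self, clean_trials):
        out = sd.inject_artifacts(clean_trials, {"blink": 0, "timeout": 0}, seed=1)
        for col in ("hor_amp", "vert_amp", "blink_in_window"):
            np.testing.assert_array_equal(out[col].to_numpy(), clean_trials[col].to_numpy())
        assert not out["artifact_blink"].any()

    def test_certain_blink_marks_every_trial(self, clean_trials):
        out = sd.inject_artifacts(clean_trials, {"blink": 1.0}, seed=1)
        assert out["blink_in_window"].all()

    def test_rate_within_binomial_bounds(self, design_plus):
        truth = sd.GroundTruth(params_true=model.ModelParams(0.5, 0.2, 1, 0.0))
        trials, _ = sd.simulate_participant(design_plus, truth, seed=0)
        big = pd.concat([trials] * 3, ignore_index=True)  # 1,050 trials
        out = sd.inject_artifacts(big, {"hypometric": 0.1}, seed=2)
        n = len(big)
        count = int(out["artifact_hypometric"].sum())
        assert abs(count - 0.1 * n) < 3 * np.sqrt(n * 0.1 * 0.9)

    def test_invalid_rate_rejected(self, clean_trials):
        with pytest.raises(ValueError):
            sd.inject_artifacts(clean_trials, {"blink": 1.5}, seed=0)


class TestSimulateParticipant:
    def test_side_flip_mirrors_all_signed_columns(self, design_plus, design_minus):
        truth = sd.GroundTruth(params_true=model.ModelParams(0.5, 0.2, 1, 0.0))
        plus, tp = sd.simulate_participant(design_plus, truth, seed=9, with_traces=True)
        minus, tm = sd.simulate_participant(design_minus, truth, seed=9, with_traces=True)
        for col in ("hor_amp", "acc_disp", "dec_disp", "loc_task_relevant"):
            np.testing.assert_allclose(
                plus[col].to_numpy(float), -minus[col].to_numpy(float), atol=1e-12
            )
        # unsigned columns unchanged
        np.testing.assert_array_equal(plus["vert_amp"], minus["vert_amp"])
        k = next(iter(tp))
        np.testing.assert_allclose(tp[k].x_deg, -tm[k].x_deg, atol=1e-12)
        np.testing.assert_array_equal(tp[k].y_deg, tm[k].y_deg)

    def test_responses_only_on_adaptation_trials(self, design_plus):
        truth = sd.GroundTruth(params_true=model.ModelParams(0.5, 0.2, 1, 0.0))
        trials, _ = sd.simulate_participant(design_plus, truth, seed=0)
        adapt = trials["phase"] == "adaptation"
        assert trials.loc[~adapt, "response_correct"].isna().all()
        assert trials.loc[adapt, "response_correct"].notna().all()
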