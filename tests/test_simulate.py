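import numpy as np
import pytest

from popcsf import (
    CSFParams,
    DistanceDrift,
    EffectModel,
    GameConfig,
    ObserverModel,
    Outcome,
    ParameterDomain,
    StimulusDomain,
    StopRule,
    ValidationError,
    aucsf,
    classify_severity,
    generate_cohort,
    init_posterior,
    simulate_session,
    simulate_trial,
    step_appearance,
    update_posterior,
)
from popcsf.engine import LikelihoodTable
from popcsf.geometry import SURFACE_PRO_4, cpp_to_cpd
from popcsf.model import PsychometricSpec


def _observer(gmax=100.0, fmax=3.0, beta=3.0, lapse=0.05, fa=2.0, drift_sd=4.0):
    return ObserverModel(
        true_csf=CSFParams(gmax, fmax, beta, lapse),
        false_alarm_rate_per_min=fa,
        drift=DistanceDrift(step_sd_mm=drift_sd),
    )


class TestAppearanceProcess:
    def test_zero_probability_at_concurrency_cap(self):
        cfg = GameConfig()
        rng = np.random.default_rng(0)
        assert not any(step_appearance(cfg.max_concurrent, cfg, rng) for _ in range(2000))

    def test_empty_screen_rate(self):
        # n=0 at 60 Hz -> per-frame probability 1/60
        cfg = GameConfig()
        rng = np.random.default_rng(1)
        n = 200_000
        frac = sum(step_appearance(0, cfg, rng) for _ in range(n)) / n
        p = 1 / 60
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_one_present_halves_rate(self):
        cfg = GameConfig()
        rng = np.random.default_rng(2)
        n = 400_000
        frac = sum(step_appearance(1, cfg, rng) for _ in range(n)) / n
        p = 1 / 120
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_literal_rule_switch(self):
        cfg = GameConfig(appearance_rate_rule="literal")
        rng = np.random.default_rng(3)
        n = 200_000
        frac = sum(step_appearance(1, cfg, rng) for _ in range(n)) / n
        p = 1 / 60
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se


class TestSimulateTrial:
    def test_suprathreshold_always_hit_without_lapse(self):
        obs = _observer(lapse=0.0)
        cfg = GameConfig()
        rng = np.random.default_rng(0)
        outcomes = {
            simulate_trial((1.0, 3.0), obs, cfg, rng).outcome for _ in range(200)
        }
        assert outcomes == {Outcome.HIT}

    def test_invisible_target_hits_at_guess_rate(self):
        # contrast at the grid floor, far below threshold: p ~ guess rate
        obs = _observer()
        cfg = GameConfig()
        rng = np.random.default_rng(1)
        n = 5000
        hits = sum(
            simulate_trial((1e-4, 3.0), obs, cfg, rng).outcome is Outcome.HIT
            for _ in range(n)
        )
        p = 0.05
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * se

    def test_deterministic_given_seed(self):
        obs = _observer()
        cfg = GameConfig()
        a = simulate_trial((0.1, 3.0), obs, cfg, np.random.default_rng(9))
        b = simulate_trial((0.1, 3.0), obs, cfg, np.random.default_rng(9))
        assert a == b

    def test_hit_latency_capped_by_response_window(self):
        obs = _observer(lapse=0.0)
        cfg = GameConfig()
        rng = np.random.default_rng(2)
        for _ in range(100):
            t = simulate_trial((1.0, 3.0), obs, cfg, rng, t_onset=5.0)
            assert t.t_offset - t.t_onset <= cfg.response_window_s + 1e-12


@pytest.fixture(scope="module")
def small_stop():
    return StopRule(max_hits=10, max_trials=40)


class TestSimulateSession:

    def test_no_false_alarms_when_rate_zero(self, small_stop):
        sess = simulate_session(
            _observer(fa=0.0), StimulusDomain.live(), ParameterDomain.live(),
            GameConfig(), small_stop, seed=4,
        )
        assert sess.counts()["false_alarm"] == 0

    def test_score_never_negative_and_floor_binds(self, small_stop):
        # a nearly blind observer with many false alarms exercises the floor
        sess = simulate_session(
            _observer(gmax=3.0, fmax=1.0, beta=1.0, fa=20.0),
            StimulusDomain.live(), ParameterDomain.live(),
            GameConfig(), small_stop, seed=5,
        )
        scores = [s for _, s in sess.score_trajectory]
        assert min(scores) >= 0
        assert sess.counts()["false_alarm"] > 0

    def test_hits_plus_misses_enter_posterior(self, small_stop):
        sess = simulate_session(
            _observer(), StimulusDomain.live(), ParameterDomain.live(),
            GameConfig(), small_stop, seed=6,
        )
        c = sess.counts()
        assert c["hit"] + c["miss"] == len(
            [t for t in sess.trials if t.outcome is not Outcome.FALSE_ALARM]
        )
        assert c["hit"] >= 10 or c["hit"] + c["miss"] >= 40

    def test_replay_equivalence(self, small_stop, psy):
        # replaying the Hit/Miss rows through update_posterior reproduces
        # the session's posterior exactly
        sess = simulate_session(
            _observer(), StimulusDomain.live(), ParameterDomain.live(),
            GameConfig(), small_stop, seed=7,
        )
        stim = StimulusDomain.live()
        stim_cpd = stim.with_frequencies_cpd(
            cpp_to_cpd(stim.frequencies, SURFACE_PRO_4, 500.0)
        )
        lik = LikelihoodTable.from_domains(stim_cpd, ParameterDomain.live(), psy)
        post = init_posterior(ParameterDomain.live())
        for t in sess.trials:
            if t.outcome is Outcome.FALSE_ALARM:
                continue
            post = update_posterior(post, (t.contrast, t.f_cpd_nominal), t.outcome, lik)
        assert np.array_equal(post.mass, sess.posterior.mass)

    def test_false_alarm_stream_does_not_touch_posterior(self, small_stop):
        # bitwise-identical posterior with the FA process on vs off
        on = simulate_session(
            _observer(fa=5.0), StimulusDomain.live(), ParameterDomain.live(),
            GameConfig(), small_stop, seed=8,
        )
        off = simulate_session(
            _observer(fa=0.0), StimulusDomain.live(), ParameterDomain.live(),
            GameConfig(), small_stop, seed=8,
        )
        assert np.array_equal(on.posterior.mass, off.posterior.mass)

    def test_hit_response_times_within_window(self, small_stop):
        cfg = GameConfig()
        sess = simulate_session(
            _observer(), StimulusDomain.live(), ParameterDomain.live(),
            cfg, small_stop, seed=9,
        )
        for t in sess.trials:
            if t.outcome is Outcome.HIT:
                assert t.t_offset - t.t_onset <= cfg.response_window_s + 1e-9

    def test_distance_trace_bounded(self, small_stop):
        sess = simulate_session(
            _observer(), StimulusDomain.live(), ParameterDomain.live(),
            GameConfig(), small_stop, seed=10,
        )
        zs = np.array([z for _, z in sess.trace.samples])
        assert zs.min() >= 300.0 and zs.max() <= 900.0


class TestCohortGeneration:
    def test_severity_classes_follow_cuts(self):
        assert classify_severity(0.25) == "mild"
        assert classify_severity(0.45) == "moderate"
        assert classify_severity(0.7) == "severe"
        cohort = generate_cohort(40, {"mild": 0, "moderate": 0, "severe": 1}, seed=0)
        assert all(s.severity_class == "severe" for s in cohort)
        assert all(s.logmar_amblyopic > 0.6 for s in cohort)

    def test_interocular_gap_invariant(self):
        for s in generate_cohort(60, seed=1):
            assert s.logmar_amblyopic - s.logmar_fellow >= 0.2 - 1e-9

    def test_null_model_centers_ratio_on_one(self):
        effect = EffectModel(gmax_slope=0.0, fmax_slope=0.0, noise_sd_log10=0.0)
        cohort = generate_cohort(50, None, effect, seed=2)
        ratios = [aucsf(s.amblyopic_csf) / aucsf(s.fellow_csf) for s in cohort]
        assert np.allclose(ratios, 1.0, atol=1e-12)

    def test_monotone_dose_response(self):
        # a larger attenuation slope lowers the median AUCSF ratio
        medians = []
        for slope in (0.0, 0.5, 1.0, 2.0):
            effect = EffectModel(gmax_slope=slope, fmax_slope=0.5 * slope)
            cohort = generate_cohort(120, None, effect, seed=3)
            medians.append(
                np.median([aucsf(s.amblyopic_csf) / aucsf(s.fellow_csf) for s in cohort])
            )
        assert all(b < a for a, b in zip(medians, medians[1:]))

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(5, {"mild": 0.5, "moderate": 0.2, "severe": 0.2}, seed=0)
        with pytest.raises(ValidationError):
            generate_cohort(5, {"mild": 0.5, "weird": 0.5}, seed=0)
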