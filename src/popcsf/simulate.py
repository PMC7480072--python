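"""Discrete-time simulator of the gamified test, plus synthetic cohorts.

The front end being emulated shows drifting Gabor patches on a tablet; the
child "pops" (presses) the ones they can see.  The simulator reproduces the
pieces of that loop that matter to the psychophysics:

* a per-frame appearance process — up to ``max_concurrent`` Gabors, a new
  one appearing with probability inversely proportional to the number
  already on screen;
* QUEST+ stimulus selection at each appearance;
* Bernoulli detection at the observer's true CSF, evaluated at the spatial
  frequency (cpd) implied by the observer's current simulated viewing
  distance — while the live engine only ever sees the nominal-distance
  frequency, exactly as in the real test;
* Hit latency, the 6 s visible duration plus 1 s grace timeout, false
  alarms as a Poisson process, and the score tally (floor at zero);
* a bounded-random-walk viewing-distance trace sampled at camera rate.

Gabor motion is not simulated: position only matters through the hit-radius
rule, so presses are reduced to detection events (an optional 2-D Gaussian
press-position error exercises the hit-radius check).

Random streams for the engine, observer, false alarms, and distance drift
are split from one seed, so switching the false-alarm process on or off
leaves the Hit/Miss stream — and hence the posterior — bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError, ValidationError
from .geometry import DistanceTrace, ScreenSpec, SURFACE_PRO_4, cpp_to_cpd, pixels_per_degree
from .model import CSFParams, ParameterDomain, PsychometricSpec, StimulusDomain, p_hit
from .engine import (
    LikelihoodTable,
    Outcome,
    Posterior,
    StopRule,
    TrialRecord,
    init_posterior,
    select_stimulus,
    update_posterior,
)

__all__ = [
    "GameConfig",
    "LatencyModel",
    "DistanceDrift",
    "ObserverModel",
    "SubjectSpec",
    "EffectModel",
    "GameSession",
    "step_appearance",
    "simulate_trial",
    "simulate_session",
    "generate_cohort",
    "classify_severity",
]


@dataclass(frozen=True)
class GameConfig:
    """Front-end timing and scoring constants.

    Defaults mirror the tablet game: 60 Hz refresh, at most five concurrent
    Gabors, 6 s visibility plus a 1 s grace period, 1 s cosine on/off ramps,
    a 221 px hit radius around a 52 px-SD envelope.
    """

    frame_rate: float = 60.0
    max_concurrent: int = 5
    visible_duration_s: float = 6.0
    grace_period_s: float = 1.0
    ramp_s: float = 1.0
    hit_radius_px: float = 221.0
    sd_px: float = 52.0
    appearance_rate_rule: str = "n_plus_one"  # or "literal"
    press_position_sd_px: float = 0.0
    max_session_s: float = 900.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.visible_duration_s <= 0 or self.ramp_s <= 0:
            raise DomainError("frame_rate, visible_duration_s, ramp_s must be > 0")
        if self.grace_period_s < 0:
            raise DomainError("grace_period_s must be >= 0")
        if self.max_concurrent < 1:
            raise DomainError("max_concurrent must be >= 1")
        if self.appearance_rate_rule not in ("n_plus_one", "literal"):
            raise DomainError(
                f"unknown appearance_rate_rule {self.appearance_rate_rule!r}"
            )

    @property
    def response_window_s(self) -> float:
        return self.visible_duration_s + self.grace_period_s


@dataclass(frozen=True)
class LatencyModel:
    """Log-normal press latency, truncated at the response window."""

    median_s: float = 0.8
    sigma_log: float = 0.5

    def draw(self, rng: np.random.Generator, cap_s: float) -> float:
        lat = float(rng.lognormal(mean=math.log(self.median_s), sigma=self.sigma_log))
        return min(lat, cap_s)


@dataclass(frozen=True)
class DistanceDrift:
    """Bounded Gaussian random walk around the nominal viewing distance.

    Reflects at ``bounds_mm`` so simulated children roam the 300-900 mm
    range without escaping it; sampled at camera rate (~29 Hz).
    """

    nominal_mm: float = 500.0
    step_sd_mm: float = 4.0
    bounds_mm: tuple[float, float] = (300.0, 900.0)
    sample_rate_hz: float = 29.0

    def make_trace(self, duration_s: float, rng: np.random.Generator) -> DistanceTrace:
        n = max(1, int(math.ceil(duration_s * self.sample_rate_hz)))
        steps = rng.normal(0.0, self.step_sd_mm, size=n)
        z = np.empty(n)
        lo, hi = self.bounds_mm
        cur = self.nominal_mm
        for i in range(n):
            cur += steps[i]
            if cur < lo:
                cur = 2 * lo - cur
            elif cur > hi:
                cur = 2 * hi - cur
            z[i] = cur
        t = np.arange(n) / self.sample_rate_hz
        return DistanceTrace(
            samples=list(zip(t.tolist(), z.tolist())),
            nominal_distance_mm=self.nominal_mm,
        )


@dataclass(frozen=True)
class ObserverModel:
    """A simulated child: true CSF, psychometric constants, false-alarm
    rate (presses/minute with no target), latency, and distance drift."""

    true_csf: CSFParams
    psychometric: PsychometricSpec = PsychometricSpec()
    false_alarm_rate_per_min: float = 2.0
    latency: LatencyModel = LatencyModel()
    drift: DistanceDrift = DistanceDrift()

    def __post_init__(self) -> None:
        if self.false_alarm_rate_per_min < 0:
            raise DomainError("false_alarm_rate_per_min must be >= 0")


def step_appearance(n_present: int, config: GameConfig, rng: np.random.Generator) -> bool:
    """Whether one new Gabor appears this frame.

    Per-frame probability 1/(frame_rate*(n_present+1)) under the default
    "n_plus_one" rule — inversely proportional to the number already
    present, finite on an empty screen — and exactly 0 at the concurrency
    cap.  The "literal" rule uses 1/(frame_rate*n_present), with the
    undefined n=0 case mapped to 1/frame_rate.
    """
    if not (0 <= n_present <= config.max_concurrent):
        raise DomainError(f"n_present must be in [0, {config.max_concurrent}]")
    if n_present >= config.max_concurrent:
        return False
    if config.appearance_rate_rule == "n_plus_one":
        p = 1.0 / (config.frame_rate * (n_present + 1))
    else:
        p = 1.0 / (config.frame_rate * max(n_present, 1))
    return bool(rng.random() < p)


def simulate_trial(
    stimulus: tuple[float, float],
    observer: ObserverModel,
    config: GameConfig,
    rng: np.random.Generator,
    t_onset: float = 0.0,
    distance_mm: Optional[float] = None,
    f_cpp: Optional[float] = None,
    screen: Optional[ScreenSpec] = None,
    index: int = 0,
) -> TrialRecord:
    """One Gabor presentation: Bernoulli detection, latency, timeout.

    ``stimulus`` is (contrast, f_cpd at nominal distance).  If ``f_cpp`` and
    ``screen`` are given the detection probability is evaluated at the cpd
    the observer actually experiences at ``distance_mm``; otherwise at the
    nominal cpd.
    """
    contrast, f_cpd_nominal = stimulus
    d = observer.drift.nominal_mm if distance_mm is None else distance_mm
    if f_cpp is not None and screen is not None:
        f_eff = cpp_to_cpd(f_cpp, screen, d)
    else:
        f_eff = f_cpd_nominal
    p = p_hit(contrast, f_eff, observer.true_csf, observer.psychometric)
    detected = rng.random() < p
    if detected:
        latency = observer.latency.draw(rng, config.response_window_s)
        t_offset = t_onset + latency
        outcome = Outcome.HIT
    else:
        rng.lognormal()  # burn the latency draw so hit/miss paths stay aligned
        t_offset = t_onset + config.response_window_s
        outcome = Outcome.MISS
    response_px = None
    if outcome is Outcome.HIT and config.press_position_sd_px > 0:
        response_px = tuple(rng.normal(0.0, config.press_position_sd_px, size=2))
    return TrialRecord(
        index=index,
        t_onset=t_onset,
        t_offset=t_offset,
        contrast=float(contrast),
        f_cpp=f_cpp,
        f_cpd_nominal=float(f_cpd_nominal),
        outcome=outcome,
        response_px=response_px,
        distance_mm=float(d),
    )


@dataclass
class GameSession:
    """Everything one simulated run produces."""

    trials: list[TrialRecord]
    trace: DistanceTrace
    score_trajectory: list[tuple[float, int]]
    posterior: Posterior
    seed: int
    nominal_distance_mm: float
    screen: ScreenSpec

    @property
    def duration_s(self) -> float:
        return max((t.t_offset for t in self.trials), default=0.0)

    def counts(self) -> dict[str, int]:
        c = {"hit": 0, "miss": 0, "false_alarm": 0}
        for t in self.trials:
            c[t.outcome.value] += 1
        return c


def simulate_session(
    observer: ObserverModel,
    stim_domain: StimulusDomain,
    param_domain: ParameterDomain,
    config: GameConfig = GameConfig(),
    stop_rule: StopRule = StopRule(),
    seed: int = 0,
    screen: ScreenSpec = SURFACE_PRO_4,
    nominal_distance_mm: float = 500.0,
) -> GameSession:
    """Run the full gamified loop for one eye.

    The engine works on the nominal-distance cpd grid (it never sees the
    drifting distance); the observer responds at the cpd implied by their
    distance at stimulus onset.  False alarms are logged and scored but
    never passed to the Bayesian update.  Trials are entered into the
    posterior in offset (scoring) order.
    """
    if stim_domain.freq_unit == "cpp":
        cpp_grid = stim_domain.frequencies
        stim_cpd = stim_domain.with_frequencies_cpd(
            cpp_to_cpd(cpp_grid, screen, nominal_distance_mm)
        )
    else:
        cpp_grid = None
        stim_cpd = stim_domain
    ppd_nominal = pixels_per_degree(screen, nominal_distance_mm)
    psy = observer.psychometric
    lik = LikelihoodTable.from_domains(stim_cpd, param_domain, psy)

    ss = np.random.SeedSequence(seed)
    rng_engine, rng_obs, rng_game, rng_fa, rng_drift = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    trace = observer.drift.make_trace(config.max_session_s, rng_drift)

    # false-alarm press times: homogeneous Poisson over the session
    fa_times: list[float] = []
    if observer.false_alarm_rate_per_min > 0:
        rate_per_s = observer.false_alarm_rate_per_min / 60.0
        t = 0.0
        while True:
            t += rng_fa.exponential(1.0 / rate_per_s)
            if t > config.max_session_s:
                break
            fa_times.append(t)

    dt = 1.0 / config.frame_rate
    active: list[TrialRecord] = []  # scheduled but not yet scored
    scored: list[TrialRecord] = []
    score = 0
    score_traj: list[tuple[float, int]] = [(0.0, 0)]
    post = init_posterior(param_domain)
    n_hits = 0
    n_trials = 0
    fa_idx = 0
    t = 0.0
    stopped = False
    while not stopped and t < config.max_session_s:
        # score any stimuli whose offset has arrived, in offset order
        due = sorted((a for a in active if a.t_offset <= t), key=lambda a: a.t_offset)
        for rec in due:
            active.remove(rec)
            rec.index = len(scored)
            scored.append(rec)
            post = update_posterior(
                post, (rec.contrast, rec.f_cpd_nominal), rec.outcome, lik
            )
            n_trials += 1
            if rec.outcome is Outcome.HIT:
                n_hits += 1
                score += 1
                score_traj.append((rec.t_offset, score))
            if stop_rule.satisfied(n_hits, n_trials, post.entropy_bits()):
                stopped = True
                break
        if stopped:
            break
        # false alarms up to now
        while fa_idx < len(fa_times) and fa_times[fa_idx] <= t:
            ft = fa_times[fa_idx]
            fa_idx += 1
            scored.append(
                TrialRecord(
                    index=len(scored),
                    t_onset=ft,
                    t_offset=ft,
                    contrast=None,
                    f_cpp=None,
                    f_cpd_nominal=None,
                    outcome=Outcome.FALSE_ALARM,
                    distance_mm=trace.distance_at(ft),
                )
            )
            score = max(0, score - 1)
            score_traj.append((ft, score))
        # new Gabor?
        if step_appearance(len(active), config, rng_game):
            contrast, f_cpd = select_stimulus(post, lik, rng_engine)
            f_cpp = f_cpd / ppd_nominal
            rec = simulate_trial(
                (contrast, f_cpd),
                observer,
                config,
                rng_obs,
                t_onset=t,
                distance_mm=trace.distance_at(t),
                f_cpp=f_cpp,
                screen=screen,
            )
            active.append(rec)
        t += dt
    # drop unresolved Gabors: the test ended before they were scored
    scored.sort(key=lambda r: (r.t_offset, r.t_onset))
    for i, rec in enumerate(scored):
        rec.index = i
    return GameSession(
        trials=scored,
        trace=trace,
        score_trajectory=score_traj,
        posterior=post,
        seed=seed,
        nominal_distance_mm=nominal_distance_mm,
        screen=screen,
    )


# --- synthetic paired-eye cohorts ----------------------------------------

SEVERITY_CLASSES = ("mild", "moderate", "severe")


def classify_severity(logmar_worse_eye: float) -> str:
    """Severity from worse-eye acuity: mild <= 0.3 < moderate <= 0.6 < severe."""
    if logmar_worse_eye > 0.6:
        return "severe"
    if logmar_worse_eye > 0.3:
        return "moderate"
    return "mild"


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic amblyope: paired-eye true CSFs and acuities."""

    subject_id: str
    age_years: float
    fellow_csf: CSFParams
    amblyopic_csf: CSFParams
    logmar_fellow: float
    logmar_amblyopic: float
    severity_class: str

    def __post_init__(self) -> None:
        errors = []
        if self.severity_class not in SEVERITY_CLASSES:
            errors.append(f"unknown severity class {self.severity_class!r}")
        elif classify_severity(self.logmar_amblyopic) != self.severity_class:
            errors.append(
                f"severity class {self.severity_class!r} inconsistent with "
                f"logMAR {self.logmar_amblyopic}"
            )
        if self.logmar_amblyopic - self.logmar_fellow < 0.2 - 1e-12:
            errors.append("interocular logMAR difference must be >= 0.2")
        if errors:
            raise ValidationError(errors)


@dataclass(frozen=True)
class EffectModel:
    """Generative model for paired-eye cohorts.

    Fellow-eye CSFs are drawn log-normally around a healthy-child profile;
    the amblyopic eye's gmax and fmax are attenuated in log10 space in
    proportion to the interocular logMAR difference (the dose), plus
    log-normal noise.  Slopes of zero give the null model (both eyes
    exchangeable).  All values are package defaults, exposed for
    sensitivity analyses.
    """

    gmax_slope: float = 1.0   # log10 units of gmax lost per logMAR of difference
    fmax_slope: float = 0.5   # log10 units of fmax lost per logMAR of difference
    noise_sd_log10: float = 0.05
    gmax_median: float = 80.0
    gmax_sd_log10: float = 0.15
    fmax_median: float = 3.0
    fmax_sd_log10: float = 0.12
    beta_mean: float = 3.0
    beta_sd: float = 0.8
    lapse: float = 0.05


_LOGMAR_RANGES = {"mild": (0.2, 0.3), "moderate": (0.3, 0.6), "severe": (0.6, 1.0)}


def generate_cohort(
    n_subjects: int,
    severity_mix: dict[str, float] | None = None,
    effect_model: EffectModel = EffectModel(),
    seed: int = 0,
) -> list[SubjectSpec]:
    """Draw a synthetic paired-eye cohort.

    ``severity_mix`` maps severity class to its proportion (defaults to
    equal thirds); proportions must sum to 1.  Ages are uniform over the
    4.0-9.2 year range of the target population.  Amblyopic-eye logMAR is
    drawn within its class's band; fellow-eye logMAR is near-normal,
    capped to keep the interocular gap >= 0.2 logMAR.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    if severity_mix is None:
        severity_mix = {"mild": 1 / 3, "moderate": 1 / 3, "severe": 1 / 3}
    if set(severity_mix) - set(SEVERITY_CLASSES):
        raise ValidationError(
            [f"unknown severity class {k!r}" for k in severity_mix if k not in SEVERITY_CLASSES]
        )
    probs = np.array([severity_mix.get(c, 0.0) for c in SEVERITY_CLASSES], float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("severity proportions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    em = effect_model
    ln10 = math.log(10.0)
    subjects = []
    for i in range(n_subjects):
        sev = SEVERITY_CLASSES[rng.choice(3, p=probs)]
        lo, hi = _LOGMAR_RANGES[sev]
        lm_amb = float(rng.uniform(lo, hi))
        # near-normal fellow eye, capped to keep the interocular gap >= 0.2
        lm_fel = float(min(rng.uniform(0.0, 0.1), lm_amb - 0.2))
        dose = lm_amb - lm_fel
        g_f = float(rng.lognormal(math.log(em.gmax_median), em.gmax_sd_log10 * ln10))
        f_f = float(rng.lognormal(math.log(em.fmax_median), em.fmax_sd_log10 * ln10))
        b = float(np.clip(rng.normal(em.beta_mean, em.beta_sd), 1.0, 9.0))
        g_a = 10.0 ** (
            math.log10(g_f) - em.gmax_slope * dose + rng.normal(0.0, em.noise_sd_log10)
        )
        f_a = 10.0 ** (
            math.log10(f_f) - em.fmax_slope * dose + rng.normal(0.0, em.noise_sd_log10)
        )
        subjects.append(
            SubjectSpec(
                subject_id=f"S{i:03d}",
                age_years=float(rng.uniform(4.0, 9.2)),
                fellow_csf=CSFParams(g_f, f_f, b, em.lapse),
                amblyopic_csf=CSFParams(g_a, f_a, b, em.lapse),
                logmar_fellow=lm_fel,
                logmar_amblyopic=lm_amb,
                severity_class=sev,
            )
        )
    return subjects
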