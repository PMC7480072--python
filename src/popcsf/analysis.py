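"""Post-hoc refitting, CSF summary measures, and cohort statistics.

After a session, the posterior is refitted on an enlarged hypothesis grid
(40x40x9x3 instead of the live 15x10x9x3) with each trial's spatial
frequency recomputed from its cycles/pixel value and the camera-estimated
viewing distance at stimulus offset.  Because the refit is a single Bayes
product over all Hit/Miss trials, trial order cannot affect it; the
computation runs in log space and is exponentiated once at the end.

Summary measures:

* ``aucsf`` — area under the CSF: the integral of max(log10 S(f), 0) over
  log10 f, by default across the 1-15 cpd analysis band.  Integrating in
  log-log space makes the area invariant to the frequency unit's scale;
  flooring at zero ignores frequencies where the eye is effectively blind.
* ``hf_cutoff_sensitivity`` — log10 sensitivity at the maximum analysis
  frequency, a scalar proxy for high-frequency loss.

Cohort statistics (paired signed-rank, rank-based one-way ANOVA, rank
correlation) are delegated to scipy.stats and applied to the AUCSF ratio
(amblyopic / fellow) and the acuity ratio (1+logMAR amblyopic)/(1+logMAR
fellow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateError, DomainError, ValidationError
from .geometry import DistanceTrace, ScreenSpec, cpp_to_cpd, distance_at
from .model import (
    CSFParams,
    ParameterDomain,
    PsychometricSpec,
    log10_sensitivity_grid,
    weibull_p_hit,
)
from .engine import Outcome, Posterior, TrialRecord, posterior_mean

__all__ = [
    "EyeEstimate",
    "CohortRecord",
    "refit_session",
    "aucsf",
    "hf_cutoff_sensitivity",
    "summarize_session",
    "analyze_cohort",
]

#: Default AUCSF / high-frequency analysis band, cpd (the refit stimulus domain).
F_LO_DEFAULT = 1.0
F_HI_DEFAULT = 15.0


def refit_session(
    trials: Sequence[TrialRecord],
    trace: Optional[DistanceTrace],
    screen: ScreenSpec,
    refit_domain: ParameterDomain | None = None,
    psy: PsychometricSpec = PsychometricSpec(),
    nominal_distance_mm: float = 500.0,
) -> Posterior:
    """Refit the posterior on an enlarged grid with distance-corrected
    frequencies.

    For every Hit/Miss trial the spatial frequency is recomputed as
    cpp_to_cpd(f_cpp, screen, distance at t_offset); false-alarm rows are
    skipped.  The result is order-invariant by construction.
    """
    if refit_domain is None:
        refit_domain = ParameterDomain.refit()
    informative = [t for t in trials if Outcome(t.outcome) is not Outcome.FALSE_ALARM]
    if not informative:
        raise ValidationError("no Hit/Miss trials to refit")
    missing = [t.index for t in informative if t.f_cpp is None]
    if missing:
        raise ValidationError(
            [f"trial {i} lacks a cycles/pixel frequency" for i in missing]
        )
    g, f, b, l = refit_domain.flat
    log_post = np.zeros(refit_domain.size)
    for t in informative:
        d = distance_at(trace, t.t_offset, nominal_distance_mm)
        f_cpd = cpp_to_cpd(t.f_cpp, screen, d)
        alpha = 1.0 / np.power(10.0, log10_sensitivity_grid(f_cpd, g, f, b))
        p = weibull_p_hit(t.contrast, alpha, psy.slope, psy.guess_rate, l)
        if Outcome(t.outcome) is Outcome.HIT:
            log_post += np.log(p)
        else:
            log_post += np.log1p(-p)
    log_post -= log_post.max()
    mass = np.exp(log_post)
    total = mass.sum()
    if not np.isfinite(total) or total <= 0:
        raise DegenerateError("refit posterior mass vanished")
    return Posterior(refit_domain, (mass / total).reshape(refit_domain.shape))


def aucsf(
    params: CSFParams,
    f_lo: float = F_LO_DEFAULT,
    f_hi: float = F_HI_DEFAULT,
    n_grid: int = 200,
) -> float:
    """Area under the CSF: trapezoidal integral of max(log10 S, 0) over
    log10 f on an ``n_grid``-point log-spaced abscissa."""
    if not (0 < f_lo < f_hi):
        raise DomainError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if n_grid < 2:
        raise DomainError("n_grid must be >= 2")
    logf = np.linspace(math.log10(f_lo), math.log10(f_hi), n_grid)
    logs = log10_sensitivity_grid(10.0 ** logf, params.gmax, params.fmax, params.beta)
    return float(np.trapezoid(np.maximum(logs, 0.0), logf))


def hf_cutoff_sensitivity(params: CSFParams, f_hi: float = F_HI_DEFAULT) -> float:
    """log10 sensitivity at the maximum analysis frequency."""
    if f_hi <= 0:
        raise DomainError("f_hi must be > 0")
    return float(log10_sensitivity_grid(f_hi, params.gmax, params.fmax, params.beta))


@dataclass
class EyeEstimate:
    """Fitted summary for one eye of one subject."""

    subject_id: str
    eye: str  # "amblyopic" | "fellow"
    params: CSFParams
    aucsf: float
    hf_cutoff: float
    fa_rate_per_min: float
    duration_s: float
    n_trials: int
    n_hits: int
    n_misses: int
    n_false_alarms: int

    def __post_init__(self) -> None:
        errors = []
        if self.eye not in ("amblyopic", "fellow"):
            errors.append(f"eye must be 'amblyopic' or 'fellow', got {self.eye!r}")
        if self.n_trials != self.n_hits + self.n_misses:
            errors.append("n_trials must equal n_hits + n_misses")
        if self.aucsf < 0:
            errors.append("aucsf must be >= 0")
        if errors:
            raise ValidationError(errors)


@dataclass
class CohortRecord:
    """Paired-eye summaries for one subject."""

    subject_id: str
    fellow: EyeEstimate
    amblyopic: EyeEstimate
    logmar_fellow: float
    logmar_amblyopic: float
    severity_class: str

    @property
    def aucsf_ratio(self) -> float:
        return self.amblyopic.aucsf / self.fellow.aucsf

    @property
    def logmar_ratio(self) -> float:
        # +1 keeps both acuities nonnegative before taking the ratio
        return (1.0 + self.logmar_amblyopic) / (1.0 + self.logmar_fellow)


def summarize_session(
    subject_id: str,
    eye: str,
    trials: Sequence[TrialRecord],
    trace: Optional[DistanceTrace],
    screen: ScreenSpec,
    refit_domain: ParameterDomain | None = None,
    psy: PsychometricSpec = PsychometricSpec(),
    nominal_distance_mm: float = 500.0,
    f_lo: float = F_LO_DEFAULT,
    f_hi: float = F_HI_DEFAULT,
) -> EyeEstimate:
    """Refit one session and summarize it into an :class:`EyeEstimate`."""
    post = refit_session(trials, trace, screen, refit_domain, psy, nominal_distance_mm)
    params = posterior_mean(post)
    n_hits = sum(1 for t in trials if Outcome(t.outcome) is Outcome.HIT)
    n_misses = sum(1 for t in trials if Outcome(t.outcome) is Outcome.MISS)
    n_fa = sum(1 for t in trials if Outcome(t.outcome) is Outcome.FALSE_ALARM)
    duration = max((t.t_offset for t in trials), default=0.0)
    fa_rate = n_fa / (duration / 60.0) if duration > 0 else 0.0
    return EyeEstimate(
        subject_id=subject_id,
        eye=eye,
        params=params,
        aucsf=max(aucsf(params, f_lo, f_hi), 0.0),
        hf_cutoff=hf_cutoff_sensitivity(params, f_hi),
        fa_rate_per_min=fa_rate,
        duration_s=duration,
        n_trials=n_hits + n_misses,
        n_hits=n_hits,
        n_misses=n_misses,
        n_false_alarms=n_fa,
    )


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str | None]:
    """Signed-rank p for paired samples; flags degenerate inputs."""
    diffs = x - y
    if len(diffs) < 2:
        return math.nan, math.nan, "fewer than 2 pairs"
    if np.allclose(diffs, 0.0):
        return math.nan, math.nan, "all paired differences are zero"
    try:
        res = stats.wilcoxon(x, y, method="auto")
        return float(res.statistic), float(res.pvalue), None
    except ValueError as exc:  # pragma: no cover - scipy edge cases
        return math.nan, math.nan, str(exc)


def analyze_cohort(records: Sequence[CohortRecord]) -> dict:
    """Case-control and dose-effect statistics for a paired-eye cohort.

    Returns a report dict with, per severity class and overall: the paired
    signed-rank p for amblyopic-vs-fellow AUCSF and the fraction of
    subjects whose AUCSF ratio is below 1; across classes: a Kruskal-Wallis
    rank test on the AUCSF ratio; the Spearman correlation of AUCSF ratio
    vs acuity ratio (the continuous dose effect); and a paired comparison
    of false-alarm rates between eyes.  Degenerate strata are flagged in
    ``report["flags"]`` rather than raising.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 cohort records")
    flags: list[str] = []
    report: dict = {"n_subjects": len(records), "flags": flags}

    def stratum(recs: Sequence[CohortRecord]) -> dict:
        amb = np.array([r.amblyopic.aucsf for r in recs])
        fel = np.array([r.fellow.aucsf for r in recs])
        ratios = np.array([r.aucsf_ratio for r in recs])
        stat, p, flag = _paired_wilcoxon(amb, fel)
        return {
            "n": len(recs),
            "wilcoxon_statistic": stat,
            "wilcoxon_p": p,
            "frac_ratio_lt_1": float(np.mean(ratios < 1.0)) if len(recs) else math.nan,
            "median_aucsf_ratio": float(np.median(ratios)) if len(recs) else math.nan,
            "flag": flag,
        }

    per_class = {}
    class_ratios = []
    for cls in ("mild", "moderate", "severe"):
        recs = [r for r in records if r.severity_class == cls]
        if recs:
            per_class[cls] = stratum(recs)
            if per_class[cls]["flag"]:
                flags.append(f"{cls}: {per_class[cls]['flag']}")
            class_ratios.append([r.aucsf_ratio for r in recs])
        else:
            per_class[cls] = {"n": 0, "flag": "empty stratum"}
            flags.append(f"{cls}: empty stratum")
    report["per_severity"] = per_class
    report["overall"] = stratum(list(records))
    if report["overall"]["flag"]:
        flags.append(f"overall: {report['overall']['flag']}")

    groups = [g for g in class_ratios if len(g) >= 2]
    if len(groups) >= 2:
        try:
            kw = stats.kruskal(*groups)
            report["across_severity"] = {
                "kruskal_statistic": float(kw.statistic),
                "kruskal_p": float(kw.pvalue),
            }
        except ValueError as exc:
            report["across_severity"] = {"kruskal_p": math.nan}
            flags.append(f"kruskal: {exc}")
    else:
        report["across_severity"] = {"kruskal_p": math.nan}
        flags.append("kruskal: fewer than 2 usable severity groups")

    ratios = np.array([r.aucsf_ratio for r in records])
    lm_ratios = np.array([r.logmar_ratio for r in records])
    if np.ptp(ratios) == 0 or np.ptp(lm_ratios) == 0:
        report["dose_effect"] = {"spearman_rho": math.nan, "spearman_p": math.nan}
        flags.append("dose effect: constant input, correlation undefined")
    else:
        rho = stats.spearmanr(lm_ratios, ratios)
        report["dose_effect"] = {
            "spearman_rho": float(rho.statistic),
            "spearman_p": float(rho.pvalue),
        }

    fa_amb = np.array([r.amblyopic.fa_rate_per_min for r in records])
    fa_fel = np.array([r.fellow.fa_rate_per_min for r in records])
    stat, p, flag = _paired_wilcoxon(fa_amb, fa_fel)
    report["fa_rate"] = {
        "median_amblyopic_per_min": float(np.median(fa_amb)),
        "median_fellow_per_min": float(np.median(fa_fel)),
        "wilcoxon_p": p,
        "flag": flag,
    }
    if flag:
        flags.append(f"fa_rate: {flag}")
    return report
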