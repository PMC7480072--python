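"""Grid-based QUEST+ inference.

The engine maintains a probability mass over the 4-D CSF hypothesis grid,
updates it by Bayes' rule after every Hit or Miss (false alarms carry no
stimulus information and are rejected), and selects each next stimulus to
minimize the expected posterior Shannon entropy over both possible outcomes
— the standard QUEST+ criterion.

All likelihoods for the discrete stimulus grid are precomputed once in a
:class:`LikelihoodTable`; a table is tied to one set of stimulus frequencies
(in cpd) and must be rebuilt if those frequencies change (the
distance-corrected refit path does exactly that, per trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.special import xlogy

from .errors import DegenerateError, DomainError, FalseAlarmUpdateError, ValidationError
from .model import (
    CSFParams,
    ParameterDomain,
    PsychometricSpec,
    StimulusDomain,
    log10_sensitivity_grid,
    p_hit,
    weibull_p_hit,
)

__all__ = [
    "Outcome",
    "TrialRecord",
    "Posterior",
    "LikelihoodTable",
    "StopRule",
    "SessionResult",
    "init_posterior",
    "update_posterior",
    "expected_posterior_entropy",
    "select_stimulus",
    "posterior_mean",
    "run_adaptive_session",
]

_LN2 = math.log(2.0)
_NORM_TOL = 1e-9
_TIE_RTOL = 1e-12


class Outcome(str, Enum):
    HIT = "hit"
    MISS = "miss"
    FALSE_ALARM = "false_alarm"


@dataclass
class TrialRecord:
    """One stimulus presentation (or false-alarm press) in the session log.

    Times are seconds from session start.  ``contrast`` is a Michelson
    fraction; ``f_cpp``/``f_cpd_nominal`` give the spatial frequency in
    cycles/pixel and in cycles/degree at the nominal viewing distance.
    False alarms have no stimulus, so those fields are None.
    """

    index: int
    t_onset: float
    t_offset: float
    contrast: Optional[float]
    f_cpp: Optional[float]
    f_cpd_nominal: Optional[float]
    outcome: Outcome
    response_px: Optional[tuple[float, float]] = None
    distance_mm: Optional[float] = None


@dataclass
class Posterior:
    """Probability mass over the (gmax, fmax, beta, lapse) grid."""

    domain: ParameterDomain
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != self.domain.shape:
            raise ValidationError(
                f"posterior shape {self.mass.shape} does not match domain "
                f"shape {self.domain.shape}"
            )
        if np.any(self.mass < 0) or not np.all(np.isfinite(self.mass)):
            raise ValidationError("posterior mass must be finite and nonnegative")
        total = float(self.mass.sum())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValidationError(f"posterior mass sums to {total}, not 1")

    @property
    def flat(self) -> np.ndarray:
        return self.mass.reshape(-1)

    def entropy_bits(self) -> float:
        """Shannon entropy of the posterior, in bits."""
        m = self.flat
        return float(-xlogy(m, m).sum() / _LN2)

    def copy(self) -> "Posterior":
        return Posterior(self.domain, self.mass.copy())


def init_posterior(domain: ParameterDomain, prior: Optional[np.ndarray] = None) -> Posterior:
    """Uniform posterior over the grid, or a validated, renormalized prior.

    A prior from a previous assessment may be injected; it must match the
    domain shape, be nonnegative, and have positive total mass.
    """
    if prior is None:
        k = domain.size
        return Posterior(domain, np.full(domain.shape, 1.0 / k))
    prior = np.asarray(prior, dtype=float)
    if prior.shape != domain.shape:
        raise ValidationError(
            f"prior shape {prior.shape} does not match domain shape {domain.shape}"
        )
    if np.any(prior < 0) or not np.all(np.isfinite(prior)):
        raise ValidationError("prior entries must be finite and nonnegative")
    total = prior.sum()
    if total <= 0:
        raise ValidationError("prior has zero total mass")
    return Posterior(domain, prior / total)


class LikelihoodTable:
    """Precomputed p(Hit) for every (stimulus, hypothesis) pair.

    Stimuli are the Cartesian product of the contrast and frequency grids
    (frequencies in cpd).  Row order is C-style over (contrast, frequency).
    """

    def __init__(
        self,
        contrasts: np.ndarray,
        frequencies_cpd: np.ndarray,
        domain: ParameterDomain,
        psy: PsychometricSpec,
    ) -> None:
        self.contrasts = np.asarray(contrasts, dtype=float)
        self.frequencies_cpd = np.asarray(frequencies_cpd, dtype=float)
        if np.any(self.frequencies_cpd <= 0):
            raise DomainError("stimulus frequencies must be positive (cpd)")
        self.domain = domain
        self.psy = psy
        g, f, b, l = domain.flat
        # threshold contrast for every (frequency, hypothesis) pair: (F, K)
        alpha = 1.0 / np.power(
            10.0,
            log10_sensitivity_grid(self.frequencies_cpd[:, None], g, f, b),
        )
        # (C, F, K) -> (S, K); p bounded in [guess, 1 - lapse]
        tab = weibull_p_hit(
            self.contrasts[:, None, None], alpha[None, :, :], psy.slope,
            psy.guess_rate, l,
        )
        self.table = tab.reshape(-1, domain.size)

    @classmethod
    def from_domains(
        cls, stim: StimulusDomain, domain: ParameterDomain, psy: PsychometricSpec
    ) -> "LikelihoodTable":
        if stim.freq_unit != "cpd":
            raise DomainError(
                "LikelihoodTable needs frequencies in cpd; convert the cpp "
                "grid with geometry.cpp_to_cpd first"
            )
        return cls(stim.contrasts, stim.frequencies, domain, psy)

    @property
    def n_stimuli(self) -> int:
        return self.table.shape[0]

    def stimulus(self, idx: int) -> tuple[float, float]:
        """(contrast, f_cpd) of stimulus row ``idx``."""
        nf = self.frequencies_cpd.size
        return float(self.contrasts[idx // nf]), float(self.frequencies_cpd[idx % nf])

    def index_of(self, contrast: float, f_cpd: float) -> int:
        ci = _grid_index(self.contrasts, contrast, "contrast")
        fi = _grid_index(self.frequencies_cpd, f_cpd, "frequency")
        return ci * self.frequencies_cpd.size + fi

    def row(self, contrast: float, f_cpd: float) -> np.ndarray:
        """p(Hit) over all hypotheses for one stimulus.

        Grid stimuli hit the precomputed table; off-grid ones are computed
        on the fly (the refit path recomputes frequencies per trial).
        """
        try:
            return self.table[self.index_of(contrast, f_cpd)]
        except DomainError:
            g, f, b, l = self.domain.flat
            alpha = 1.0 / np.power(10.0, log10_sensitivity_grid(f_cpd, g, f, b))
            return weibull_p_hit(contrast, alpha, self.psy.slope, self.psy.guess_rate, l)


def _grid_index(grid: np.ndarray, value: float, name: str) -> int:
    idx = int(np.argmin(np.abs(grid - value)))
    if not np.isclose(grid[idx], value, rtol=1e-9, atol=0):
        raise DomainError(f"{name} {value} is not on the stimulus grid")
    return idx


def update_posterior(
    post: Posterior,
    stimulus: tuple[float, float],
    outcome: Outcome,
    lik: LikelihoodTable,
) -> Posterior:
    """Bayes update after one Hit or Miss; returns a new Posterior.

    Raises :class:`FalseAlarmUpdateError` for a false alarm — false alarms
    are logged but never enter the model — and :class:`DegenerateError` if
    the updated mass vanishes.
    """
    outcome = Outcome(outcome)
    if outcome is Outcome.FALSE_ALARM:
        raise FalseAlarmUpdateError(
            "false alarms must not be passed to update_posterior"
        )
    contrast, f_cpd = stimulus
    p = lik.row(contrast, f_cpd).reshape(post.domain.shape)
    like = p if outcome is Outcome.HIT else 1.0 - p
    new_mass = post.mass * like
    total = float(new_mass.sum())
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateError("posterior mass vanished after update")
    return Posterior(post.domain, new_mass / total)


def _expected_entropies(mass_flat: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Expected posterior entropy (bits) for every stimulus row of ``table``.

    For joint weights w = p_hit * prior (per hypothesis) with predictive
    p = sum(w), the hit branch contributes p*H(w/p) = -sum(w log2 w)
    + p log2 p; likewise for the miss branch with weights prior - w.
    """
    w_hit = table * mass_flat
    p_hit_pred = w_hit.sum(axis=1)
    w_miss = mass_flat - w_hit
    p_miss_pred = 1.0 - p_hit_pred
    s_hit = -xlogy(w_hit, w_hit).sum(axis=1)
    s_miss = -xlogy(w_miss, w_miss).sum(axis=1)
    expected = (
        s_hit + xlogy(p_hit_pred, p_hit_pred)
        + s_miss + xlogy(p_miss_pred, p_miss_pred)
    ) / _LN2
    # tiny negative values are roundoff
    return np.maximum(expected, 0.0)


def expected_posterior_entropy(
    post: Posterior, stimulus: tuple[float, float], lik: LikelihoodTable
) -> float:
    """p(Hit)*H(post|Hit) + p(Miss)*H(post|Miss), in bits."""
    row = lik.row(*stimulus)
    return float(_expected_entropies(post.flat, row[None, :])[0])


def select_stimulus(
    post: Posterior, lik: LikelihoodTable, rng
) -> tuple[float, float]:
    """The stimulus minimizing expected posterior entropy.

    Ties (within 1e-12 relative tolerance) are broken by a seeded uniform
    choice, so selection is deterministic given the rng state.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    expected = _expected_entropies(post.flat, lik.table)
    lo = expected.min()
    ties = np.flatnonzero(expected <= lo + _TIE_RTOL * max(1.0, abs(lo)))
    idx = int(ties[rng.integers(ties.size)])
    return lik.stimulus(idx)


def posterior_mean(post: Posterior) -> CSFParams:
    """Posterior-mean CSF parameters.

    The expectation is taken in log10 space for the log-spaced gmax and fmax
    grids (then back-transformed) and in linear space for beta and lapse.
    """
    d = post.domain
    m = post.mass
    mg = m.sum(axis=(1, 2, 3))
    mf = m.sum(axis=(0, 2, 3))
    mb = m.sum(axis=(0, 1, 3))
    ml = m.sum(axis=(0, 1, 2))
    gmax = 10.0 ** float(np.dot(mg, np.log10(d.gmax_grid)))
    fmax = 10.0 ** float(np.dot(mf, np.log10(d.fmax_grid)))
    beta = float(np.dot(mb, d.beta_grid))
    lapse = float(np.dot(ml, d.lapse_grid))
    return CSFParams(gmax=gmax, fmax=fmax, beta=beta, lapse=lapse)


@dataclass(frozen=True)
class StopRule:
    """Session termination: stop at ``max_hits`` correct responses (the
    clinical default of ~30), or after ``max_trials`` Hit/Miss trials, or
    when posterior entropy falls below ``min_entropy_bits``."""

    max_hits: Optional[int] = 30
    max_trials: int = 100
    min_entropy_bits: Optional[float] = None

    def satisfied(self, n_hits: int, n_trials: int, entropy_bits: float) -> bool:
        if self.max_hits is not None and n_hits >= self.max_hits:
            return True
        if n_trials >= self.max_trials:
            return True
        if self.min_entropy_bits is not None and entropy_bits <= self.min_entropy_bits:
            return True
        return False


@dataclass
class SessionResult:
    posterior: Posterior
    trials: list[TrialRecord]
    checkpoints: dict[int, Posterior] = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return sum(1 for t in self.trials if t.outcome is Outcome.HIT)

    @property
    def n_misses(self) -> int:
        return sum(1 for t in self.trials if t.outcome is Outcome.MISS)


def run_adaptive_session(
    true_csf: CSFParams,
    stim_domain: StimulusDomain,
    param_domain: ParameterDomain,
    psy: PsychometricSpec,
    stop_rule: StopRule = StopRule(),
    seed: int | np.random.Generator = 0,
    checkpoints: Optional[Sequence[int]] = None,
    lik: Optional[LikelihoodTable] = None,
) -> SessionResult:
    """Closed-loop adaptive session against a simulated Weibull observer.

    Repeats select_stimulus -> Bernoulli response at the observer's true
    CSF -> update_posterior until the stop rule fires.  ``checkpoints``
    requests posterior snapshots after the given trial counts (used for
    convergence analyses without re-running sessions).  Reproducible given
    ``seed``; stimulus frequencies must already be in cpd.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lik is None:
        lik = LikelihoodTable.from_domains(stim_domain, param_domain, psy)
    post = init_posterior(param_domain)
    trials: list[TrialRecord] = []
    snaps: dict[int, Posterior] = {}
    want = set(int(c) for c in checkpoints) if checkpoints else set()
    n_hits = 0
    hard_cap = max(stop_rule.max_trials, max(want) if want else 0)
    while True:
        if stop_rule.satisfied(n_hits, len(trials), post.entropy_bits()) and (
            not want or len(trials) >= max(want)
        ):
            break
        if len(trials) >= hard_cap:
            break
        contrast, f_cpd = select_stimulus(post, lik, rng)
        p = p_hit(contrast, f_cpd, true_csf, psy)
        outcome = Outcome.HIT if rng.random() < p else Outcome.MISS
        t = float(len(trials))
        trials.append(
            TrialRecord(
                index=len(trials),
                t_onset=t,
                t_offset=t + 1.0,
                contrast=contrast,
                f_cpp=None,
                f_cpd_nominal=f_cpd,
                outcome=outcome,
            )
        )
        post = update_posterior(post, (contrast, f_cpd), outcome, lik)
        if outcome is Outcome.HIT:
            n_hits += 1
        if len(trials) in want:
            snaps[len(trials)] = post.copy()
    return SessionResult(posterior=post, trials=trials, checkpoints=snaps)
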