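"""Truncated log-parabola CSF and Weibull psychometric function.

The contrast sensitivity function (CSF) is parameterized by three numbers:
peak gain ``gmax`` (sensitivity = 1/threshold contrast, threshold as a
Michelson fraction), peak spatial frequency ``fmax`` (cycles/degree, cpd)
and bandwidth ``beta`` (full width at half maximum, in octaves).  Below the
peak the function is flat (no low-frequency fall-off); above the peak
log-sensitivity falls off as a parabola in log-frequency:

    log10 S(f) = log10 gmax                              f <= fmax
    log10 S(f) = log10 gmax
                 - log10(2) * ((log10 f - log10 fmax) / (log10(2**beta)/2))**2
                                                         f >  fmax

so that S(fmax * 2**(beta/2)) = gmax/2: ``beta`` octaves is the full width
of the (untruncated) parabola at half maximum.

Detection of a Gabor of contrast ``c`` at frequency ``f`` follows a Weibull
psychometric function on linear contrast with guess rate ``gamma``, lapse
rate ``lam`` and shape ``s``:

    p(hit) = gamma + (1 - gamma - lam) * (1 - exp(-(c / alpha)**s))

where ``alpha = 1 / S(f)`` is the threshold contrast.  ``alpha`` may exceed
1 for weak hypotheses at high frequency; the psychometric function then
simply stays near the guess rate for every presentable contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "CSFParams",
    "PsychometricSpec",
    "StimulusDomain",
    "ParameterDomain",
    "csf_sensitivity",
    "threshold_contrast",
    "p_hit",
]


@dataclass(frozen=True)
class CSFParams:
    """One CSF hypothesis: peak gain, peak frequency, bandwidth, lapse.

    Parameters
    ----------
    gmax : float
        Peak contrast sensitivity (dimensionless, = 1/threshold contrast).
    fmax : float
        Peak spatial frequency, cycles/degree.
    beta : float
        Bandwidth: full width at half maximum, in octaves.
    lapse : float
        Upper-asymptote miss probability, in [0, 1).
    """

    gmax: float
    fmax: float
    beta: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gmax > 0):
            raise DomainError(f"gmax must be > 0, got {self.gmax}")
        if not (self.fmax > 0):
            raise DomainError(f"fmax must be > 0, got {self.fmax}")
        if not (self.beta > 0):
            raise DomainError(f"beta must be > 0, got {self.beta}")
        if not (0 <= self.lapse < 1):
            raise DomainError(f"lapse must be in [0, 1), got {self.lapse}")


@dataclass(frozen=True)
class PsychometricSpec:
    """Weibull psychometric constants shared across CSF hypotheses.

    ``slope`` is the Weibull shape exponent on linear contrast; the default
    constants are a fixed slope of 3, a guess rate (lower asymptote) of 0.05
    and candidate lapse rates of 0.05, 0.1 and 0.2.
    """

    slope: float = 3.0
    guess_rate: float = 0.05
    lapse_values: tuple[float, ...] = (0.05, 0.1, 0.2)

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise DomainError(f"slope must be > 0, got {self.slope}")
        if not (0 <= self.guess_rate < 1):
            raise DomainError(f"guess_rate must be in [0, 1), got {self.guess_rate}")
        lv = tuple(float(v) for v in self.lapse_values)
        object.__setattr__(self, "lapse_values", lv)
        if not lv or any(not (0 <= v < 1) for v in lv):
            raise DomainError(f"every lapse value must be in [0, 1), got {lv}")
        if self.guess_rate + max(lv) >= 1:
            raise DomainError("guess_rate + max(lapse) must be < 1")


def _as_increasing(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DomainError(f"{name} must be a nonempty 1-D grid")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise DomainError(f"{name} must be strictly increasing")
    return arr


@dataclass(frozen=True)
class StimulusDomain:
    """The discrete stimulus grid: Michelson contrasts x spatial frequencies.

    ``freq_unit`` flags whether ``frequencies`` is in cycles/pixel ("cpp",
    the native unit of the rendered stimulus) or cycles/degree ("cpd", the
    unit the CSF model operates in).
    """

    contrasts: np.ndarray
    frequencies: np.ndarray
    freq_unit: str = "cpd"

    def __post_init__(self) -> None:
        c = _as_increasing("contrasts", self.contrasts)
        f = _as_increasing("frequencies", self.frequencies)
        if np.any(c <= 0) or np.any(c > 1):
            raise DomainError("contrasts must lie in (0, 1] (Michelson fractions)")
        if np.any(f <= 0):
            raise DomainError("frequencies must be > 0")
        if self.freq_unit not in ("cpp", "cpd"):
            raise DomainError(f"freq_unit must be 'cpp' or 'cpd', got {self.freq_unit!r}")
        object.__setattr__(self, "contrasts", c)
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def live(cls) -> "StimulusDomain":
        """The live test grid: 15 contrasts 0.01%-100%, 10 frequencies
        0.019-0.125 cycles/pixel."""
        return cls(
            contrasts=np.logspace(np.log10(1e-4), 0.0, 15),
            frequencies=np.logspace(np.log10(0.019), np.log10(0.125), 10),
            freq_unit="cpp",
        )

    @classmethod
    def refit(cls) -> "StimulusDomain":
        """The post-hoc analysis grid: 30 frequencies log-spaced 1-15 cpd."""
        return cls(
            contrasts=np.logspace(np.log10(1e-4), 0.0, 15),
            frequencies=np.logspace(0.0, np.log10(15.0), 30),
            freq_unit="cpd",
        )

    def with_frequencies_cpd(self, frequencies_cpd) -> "StimulusDomain":
        return StimulusDomain(self.contrasts, np.asarray(frequencies_cpd, float), "cpd")

    @property
    def n_stimuli(self) -> int:
        return self.contrasts.size * self.frequencies.size


@dataclass(frozen=True)
class ParameterDomain:
    """The 4-D CSF hypothesis grid: gmax x fmax x beta x lapse.

    gmax and fmax grids are log-spaced, beta linear, lapse a small discrete
    set.  Live default 15x10x9x3; refit default 40x40x9x3.
    """

    gmax_grid: np.ndarray
    fmax_grid: np.ndarray
    beta_grid: np.ndarray
    lapse_grid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gmax_grid", "fmax_grid", "beta_grid", "lapse_grid"):
            arr = _as_increasing(name, getattr(self, name))
            object.__setattr__(self, name, arr)
        if np.any(self.gmax_grid <= 0) or np.any(self.fmax_grid <= 0):
            raise DomainError("gmax and fmax grids must be positive")
        if np.any(self.beta_grid <= 0):
            raise DomainError("beta grid must be positive")
        if np.any(self.lapse_grid < 0) or np.any(self.lapse_grid >= 1):
            raise DomainError("lapse grid must lie in [0, 1)")

    @classmethod
    def live(cls) -> "ParameterDomain":
        return cls(
            gmax_grid=np.logspace(np.log10(3.0), np.log10(300.0), 15),
            fmax_grid=np.logspace(0.0, 1.0, 10),
            beta_grid=np.linspace(1.0, 9.0, 9),
            lapse_grid=np.array([0.05, 0.1, 0.2]),
        )

    @classmethod
    def refit(cls) -> "ParameterDomain":
        return cls(
            gmax_grid=np.logspace(np.log10(3.0), np.log10(300.0), 40),
            fmax_grid=np.logspace(0.0, 1.0, 40),
            beta_grid=np.linspace(1.0, 9.0, 9),
            lapse_grid=np.array([0.05, 0.1, 0.2]),
        )

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (
            self.gmax_grid.size,
            self.fmax_grid.size,
            self.beta_grid.size,
            self.lapse_grid.size,
        )

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    @cached_property
    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (gmax, fmax, beta, lapse) arrays of length ``size``,
        in C order over the (gmax, fmax, beta, lapse) axes."""
        g, f, b, l = np.meshgrid(
            self.gmax_grid, self.fmax_grid, self.beta_grid, self.lapse_grid,
            indexing="ij",
        )
        return g.ravel(), f.ravel(), b.ravel(), l.ravel()


# --- vectorized internals (no per-call validation; used by the engine) ----

def log10_sensitivity_grid(f, gmax, fmax, beta):
    """log10 of the truncated log-parabola; broadcasts over all arguments."""
    f = np.asarray(f, dtype=float)
    log_gmax = np.log10(gmax)
    half_width = np.log10(2.0) * np.asarray(beta, float) / 2.0  # log10(2**beta)/2
    dist = (np.log10(f) - np.log10(fmax)) / half_width
    falloff = log_gmax - np.log10(2.0) * dist * dist
    return np.where(f <= fmax, log_gmax, falloff)


def weibull_p_hit(contrast, alpha, slope, guess_rate, lapse):
    """gamma + (1-gamma-lambda)(1 - exp(-(c/alpha)^s)); broadcasts."""
    c = np.asarray(contrast, dtype=float)
    return guess_rate + (1.0 - guess_rate - lapse) * (
        1.0 - np.exp(-np.power(c / alpha, slope))
    )


# --- public scalar/array operations --------------------------------------

def csf_sensitivity(f, params: CSFParams):
    """Contrast sensitivity S(f) at spatial frequency ``f`` (cpd).

    Flat at ``gmax`` for f <= fmax; log-parabolic fall-off above.  Accepts a
    scalar or array ``f``; raises :class:`DomainError` on nonpositive f.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0) or not np.all(np.isfinite(f_arr)):
        raise DomainError("spatial frequency must be positive and finite")
    out = np.power(10.0, log10_sensitivity_grid(f_arr, params.gmax, params.fmax, params.beta))
    return float(out) if np.isscalar(f) or np.ndim(f) == 0 else out


def threshold_contrast(f, params: CSFParams):
    """Threshold Michelson contrast alpha(f) = 1 / S(f).

    May exceed 1 (a physically unreachable contrast) for weak hypotheses at
    high frequency; the psychometric function handles that gracefully.
    """
    return 1.0 / csf_sensitivity(f, params)


def p_hit(contrast, f, params: CSFParams, psy: PsychometricSpec):
    """Probability of a Hit for a Gabor of ``contrast`` at frequency ``f``.

    Monotone nondecreasing in contrast, bounded in
    [guess_rate, 1 - params.lapse].
    """
    c_arr = np.asarray(contrast, dtype=float)
    if np.any(c_arr < 0):
        raise DomainError("contrast must be >= 0")
    alpha = threshold_contrast(f, params)
    out = weibull_p_hit(c_arr, alpha, psy.slope, psy.guess_rate, params.lapse)
    scalar = (np.isscalar(contrast) or np.ndim(contrast) == 0) and (
        np.isscalar(f) or np.ndim(f) == 0
    )
    return float(out) if scalar else out
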