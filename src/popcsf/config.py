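"""Configuration: canonical grids and constants, resolvable from YAML/JSON.

The config file is optional — every field has the canonical default — and
shallow: top-level sections ``screen``, ``stimulus``, ``parameters``,
``refit_parameters``, ``psychometric``, ``game``, ``geometry``.  Grids are
given as bounds + count (log- or linearly spaced per the field's
convention), not as explicit lists.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .geometry import SURFACE_PRO_4, ScreenSpec
from .model import ParameterDomain, PsychometricSpec, StimulusDomain
from .simulate import GameConfig

__all__ = ["Config", "load_config", "config_hash"]


@dataclass(frozen=True)
class Config:
    screen: ScreenSpec = SURFACE_PRO_4
    nominal_distance_mm: float = 500.0
    ppd_convention: str = "full_width"
    stimulus: StimulusDomain = field(default_factory=StimulusDomain.live)
    parameters: ParameterDomain = field(default_factory=ParameterDomain.live)
    refit_parameters: ParameterDomain = field(default_factory=ParameterDomain.refit)
    refit_stimulus: StimulusDomain = field(default_factory=StimulusDomain.refit)
    psychometric: PsychometricSpec = field(default_factory=PsychometricSpec)
    game: GameConfig = field(default_factory=GameConfig)

    def to_dict(self) -> dict:
        return {
            "screen": {
                "width_px": self.screen.width_px,
                "height_px": self.screen.height_px,
                "diagonal_mm": self.screen.diagonal_mm,
            },
            "geometry": {
                "nominal_distance_mm": self.nominal_distance_mm,
                "ppd_convention": self.ppd_convention,
            },
            "stimulus": _domain_2d_dict(self.stimulus),
            "refit_stimulus": _domain_2d_dict(self.refit_stimulus),
            "parameters": _param_dict(self.parameters),
            "refit_parameters": _param_dict(self.refit_parameters),
            "psychometric": {
                "slope": self.psychometric.slope,
                "guess_rate": self.psychometric.guess_rate,
                "lapse_values": list(self.psychometric.lapse_values),
            },
            "game": {
                "frame_rate": self.game.frame_rate,
                "max_concurrent": self.game.max_concurrent,
                "visible_duration_s": self.game.visible_duration_s,
                "grace_period_s": self.game.grace_period_s,
                "ramp_s": self.game.ramp_s,
                "hit_radius_px": self.game.hit_radius_px,
                "sd_px": self.game.sd_px,
                "appearance_rate_rule": self.game.appearance_rate_rule,
            },
        }


def _domain_2d_dict(dom: StimulusDomain) -> dict:
    return {
        "contrast_lo": float(dom.contrasts[0]),
        "contrast_hi": float(dom.contrasts[-1]),
        "n_contrasts": int(dom.contrasts.size),
        "freq_lo": float(dom.frequencies[0]),
        "freq_hi": float(dom.frequencies[-1]),
        "n_freqs": int(dom.frequencies.size),
        "freq_unit": dom.freq_unit,
    }


def _param_dict(dom: ParameterDomain) -> dict:
    return {
        "gmax_lo": float(dom.gmax_grid[0]),
        "gmax_hi": float(dom.gmax_grid[-1]),
        "n_gmax": int(dom.gmax_grid.size),
        "fmax_lo": float(dom.fmax_grid[0]),
        "fmax_hi": float(dom.fmax_grid[-1]),
        "n_fmax": int(dom.fmax_grid.size),
        "beta_lo": float(dom.beta_grid[0]),
        "beta_hi": float(dom.beta_grid[-1]),
        "n_beta": int(dom.beta_grid.size),
        "lapse_values": [float(v) for v in dom.lapse_grid],
    }


def _domain_from_dict(d: dict, default: StimulusDomain) -> StimulusDomain:
    base = _domain_2d_dict(default)
    base.update(d)
    return StimulusDomain(
        contrasts=np.logspace(
            np.log10(base["contrast_lo"]), np.log10(base["contrast_hi"]),
            base["n_contrasts"],
        ),
        frequencies=np.logspace(
            np.log10(base["freq_lo"]), np.log10(base["freq_hi"]), base["n_freqs"]
        ),
        freq_unit=base["freq_unit"],
    )


def _params_from_dict(d: dict, default: ParameterDomain) -> ParameterDomain:
    base = _param_dict(default)
    base.update(d)
    return ParameterDomain(
        gmax_grid=np.logspace(
            np.log10(base["gmax_lo"]), np.log10(base["gmax_hi"]), base["n_gmax"]
        ),
        fmax_grid=np.logspace(
            np.log10(base["fmax_lo"]), np.log10(base["fmax_hi"]), base["n_fmax"]
        ),
        beta_grid=np.linspace(base["beta_lo"], base["beta_hi"], base["n_beta"]),
        lapse_grid=np.array(base["lapse_values"], float),
    )


def load_config(path: str | Path | None = None) -> Config:
    """Resolve a Config from a YAML/JSON file; None gives the defaults."""
    default = Config()
    if path is None:
        return default
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return default
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    screen = default.screen
    if "screen" in raw:
        s = raw["screen"]
        if "diagonal_in" in s:
            screen = ScreenSpec.from_diagonal_inches(
                s["width_px"], s["height_px"], s["diagonal_in"]
            )
        else:
            screen = ScreenSpec(s["width_px"], s["height_px"], s["diagonal_mm"])
    geom = raw.get("geometry", {})
    psy = default.psychometric
    if "psychometric" in raw:
        p = raw["psychometric"]
        psy = PsychometricSpec(
            slope=p.get("slope", psy.slope),
            guess_rate=p.get("guess_rate", psy.guess_rate),
            lapse_values=tuple(p.get("lapse_values", psy.lapse_values)),
        )
    game = default.game
    if "game" in raw:
        g = dict(raw["game"])
        game = GameConfig(**g)
    return Config(
        screen=screen,
        nominal_distance_mm=geom.get("nominal_distance_mm", default.nominal_distance_mm),
        ppd_convention=geom.get("ppd_convention", default.ppd_convention),
        stimulus=_domain_from_dict(raw.get("stimulus", {}), default.stimulus),
        refit_stimulus=_domain_from_dict(
            raw.get("refit_stimulus", {}), default.refit_stimulus
        ),
        parameters=_params_from_dict(raw.get("parameters", {}), default.parameters),
        refit_parameters=_params_from_dict(
            raw.get("refit_parameters", {}), default.refit_parameters
        ),
        psychometric=psy,
        game=game,
    )


def config_hash(cfg: Config) -> str:
    """Stable short hash of the resolved configuration (for provenance)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
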