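"""Session, trace, and fixture input/output.

A session travels as two files: a JSON *envelope* (screen spec, eye label,
domains, seed, provenance, and the trials inline) and, for analyst
convenience, a flat trials CSV written alongside.  Distance traces are
2-column CSV (timestamp_s, z_mm).  All timestamps are seconds from session
start.

Validation is strict by default and collects *all* failures into one
:class:`~popcsf.errors.ValidationError`; ``lenient=True`` downgrades
unknown-field errors to warnings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import Config, config_hash
from .errors import ValidationError
from .geometry import DistanceTrace, ScreenSpec
from .engine import Outcome, TrialRecord

__all__ = [
    "SessionEnvelope",
    "read_session",
    "write_session",
    "read_trace",
    "write_trace",
    "make_fixture",
    "FIXTURE_KINDS",
]

SCHEMA_VERSION = "1"

_TRIAL_COLUMNS = [
    "index",
    "t_onset_s",
    "t_offset_s",
    "contrast",
    "f_cpp",
    "f_cpd_nominal",
    "outcome",
    "response_x_px",
    "response_y_px",
    "distance_mm",
]

_KNOWN_FIELDS = {
    "schema_version",
    "subject_id",
    "eye",
    "screen",
    "nominal_distance_mm",
    "domains",
    "seed",
    "trials",
    "trace_path",
    "provenance",
}


@dataclass
class SessionEnvelope:
    """One eye's session: metadata plus the full trial log."""

    subject_id: str
    eye: str
    screen: ScreenSpec
    nominal_distance_mm: float
    domains: dict
    seed: int
    trials: list[TrialRecord]
    trace_path: Optional[str] = None
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION
    extra: dict = field(default_factory=dict)


def _trial_to_row(t: TrialRecord) -> dict:
    return {
        "index": t.index,
        "t_onset_s": t.t_onset,
        "t_offset_s": t.t_offset,
        "contrast": t.contrast,
        "f_cpp": t.f_cpp,
        "f_cpd_nominal": t.f_cpd_nominal,
        "outcome": Outcome(t.outcome).value,
        "response_x_px": None if t.response_px is None else t.response_px[0],
        "response_y_px": None if t.response_px is None else t.response_px[1],
        "distance_mm": t.distance_mm,
    }


def _row_to_trial(row: dict, line: int, errors: list[str]) -> Optional[TrialRecord]:
    outcome_raw = row.get("outcome")
    try:
        outcome = Outcome(outcome_raw)
    except ValueError:
        errors.append(f"trial row {line}: unknown outcome {outcome_raw!r}")
        return None

    def opt(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)

    contrast = opt("contrast")
    if outcome is not Outcome.FALSE_ALARM:
        if contrast is None:
            errors.append(f"trial row {line}: missing contrast")
            return None
        if not (0 < contrast <= 1):
            errors.append(
                f"trial row {line}: contrast {contrast} outside (0, 1]"
            )
            return None
    rx, ry = opt("response_x_px"), opt("response_y_px")
    return TrialRecord(
        index=int(row["index"]),
        t_onset=float(row["t_onset_s"]),
        t_offset=float(row["t_offset_s"]),
        contrast=contrast,
        f_cpp=opt("f_cpp"),
        f_cpd_nominal=opt("f_cpd_nominal"),
        outcome=outcome,
        response_px=None if rx is None else (rx, ry),
        distance_mm=opt("distance_mm"),
    )


def write_session(env: SessionEnvelope, path: str | Path) -> Path:
    """Write the JSON envelope (trials inline) plus a sibling trials CSV."""
    path = Path(path)
    doc = {
        "schema_version": env.schema_version,
        "subject_id": env.subject_id,
        "eye": env.eye,
        "screen": {
            "width_px": env.screen.width_px,
            "height_px": env.screen.height_px,
            "diagonal_mm": env.screen.diagonal_mm,
        },
        "nominal_distance_mm": env.nominal_distance_mm,
        "domains": env.domains,
        "seed": env.seed,
        "trials": [_trial_to_row(t) for t in env.trials],
        "trace_path": env.trace_path,
        "provenance": env.provenance,
        **env.extra,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    csv_path = path.with_suffix(".trials.csv")
    pd.DataFrame(
        [_trial_to_row(t) for t in env.trials], columns=_TRIAL_COLUMNS
    ).to_csv(csv_path, index=False)
    return path


def read_session(path: str | Path, lenient: bool = False) -> SessionEnvelope:
    """Read and validate a session envelope.

    Every failure is collected; the raised :class:`ValidationError` lists
    them all.  Unknown top-level fields are errors unless ``lenient``.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    errors: list[str] = []
    if doc.get("schema_version") != SCHEMA_VERSION:
        errors.append(
            f"unrecognized schema_version {doc.get('schema_version')!r}"
        )
    unknown = set(doc) - _KNOWN_FIELDS
    if unknown:
        msg = f"unknown fields: {sorted(unknown)}"
        if lenient:
            warnings.warn(msg)
        else:
            errors.append(msg)
    trials: list[TrialRecord] = []
    for i, row in enumerate(doc.get("trials", [])):
        t = _row_to_trial(row, i, errors)
        if t is not None:
            trials.append(t)
    dom = doc.get("domains", {})
    stim = dom.get("stimulus", {})
    if stim:
        lo, hi = stim.get("freq_lo"), stim.get("freq_hi")
        if lo is not None and hi is not None:
            for t in trials:
                if t.f_cpp is not None and not (
                    lo * (1 - 1e-9) <= t.f_cpp <= hi * (1 + 1e-9)
                ):
                    errors.append(
                        f"trial {t.index}: f_cpp {t.f_cpp} outside declared "
                        f"stimulus domain [{lo}, {hi}]"
                    )
    if errors:
        raise ValidationError(errors)
    scr = doc["screen"]
    return SessionEnvelope(
        subject_id=doc["subject_id"],
        eye=doc["eye"],
        screen=ScreenSpec(scr["width_px"], scr["height_px"], scr["diagonal_mm"]),
        nominal_distance_mm=doc["nominal_distance_mm"],
        domains=dom,
        seed=doc["seed"],
        trials=trials,
        trace_path=doc.get("trace_path"),
        provenance=doc.get("provenance", {}),
        schema_version=doc["schema_version"],
        extra={k: doc[k] for k in unknown} if lenient else {},
    )


def write_trace(trace: DistanceTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(trace.samples, columns=["timestamp_s", "z_mm"])
    df.to_csv(path, index=False)
    return path


def read_trace(path: str | Path, nominal_distance_mm: float = 500.0) -> DistanceTrace:
    df = pd.read_csv(path)
    missing = {"timestamp_s", "z_mm"} - set(df.columns)
    if missing:
        raise ValidationError([f"trace missing column {c!r}" for c in sorted(missing)])
    return DistanceTrace(
        samples=list(zip(df["timestamp_s"], df["z_mm"])),
        nominal_distance_mm=nominal_distance_mm,
    )


def provenance_block(cfg: Config, seed: int) -> dict:
    return {
        "software": "popcsf",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": int(seed),
    }


# --- deterministic test fixtures -----------------------------------------

FIXTURE_KINDS = ("tiny_session", "null_cohort", "dose_cohort", "worked_geometry")


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write a small deterministic fixture; returns the created paths.

    Kinds: ``tiny_session`` (a short simulated session on the canonical
    grids), ``null_cohort`` / ``dose_cohort`` (6-subject synthetic cohorts
    with zero / default attenuation), ``worked_geometry`` (the tablet
    screen spec plus its derived conversion constants).
    """
    from .analysis import aucsf  # local import to avoid cycles
    from .config import Config
    from .geometry import (
        SURFACE_PRO_4,
        cpp_to_cpd,
        gabor_energy_diameter,
        pixels_per_degree,
        px_extent_to_deg,
    )
    from .model import ParameterDomain, StimulusDomain
    from .simulate import EffectModel, GameConfig, ObserverModel, generate_cohort, simulate_session
    from .engine import StopRule
    from .model import CSFParams

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = Config()
    if kind == "worked_geometry":
        ppd = pixels_per_degree(SURFACE_PRO_4, 500.0)
        doc = {
            "screen": {
                "width_px": 2736,
                "height_px": 1824,
                "diagonal_in": 12.3,
            },
            "nominal_distance_mm": 500.0,
            "derived": {
                "pixels_per_degree": ppd,
                "cpd_at_0.019_cpp": cpp_to_cpd(0.019, SURFACE_PRO_4, 500.0),
                "cpd_at_0.125_cpp": cpp_to_cpd(0.125, SURFACE_PRO_4, 500.0),
                "deg_at_52_px": px_extent_to_deg(52, SURFACE_PRO_4, 500.0),
                "energy_diameter_deg_sd_0.55": gabor_energy_diameter(0.55, 0.99),
            },
        }
        p = out_dir / "worked_geometry.json"
        p.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
        return [p]
    if kind == "tiny_session":
        obs = ObserverModel(
            true_csf=CSFParams(gmax=100.0, fmax=3.0, beta=3.0, lapse=0.05),
            false_alarm_rate_per_min=2.0,
        )
        sess = simulate_session(
            obs,
            StimulusDomain.live(),
            ParameterDomain.live(),
            GameConfig(),
            StopRule(max_hits=8, max_trials=20),
            seed=seed,
        )
        env = SessionEnvelope(
            subject_id="FIXTURE",
            eye="fellow",
            screen=sess.screen,
            nominal_distance_mm=sess.nominal_distance_mm,
            domains={"stimulus": {"freq_lo": 0.019, "freq_hi": 0.125, "unit": "cpp"}},
            seed=seed,
            trials=sess.trials,
            trace_path="tiny_session.trace.csv",
            provenance=provenance_block(cfg, seed),
        )
        p1 = write_session(env, out_dir / "tiny_session.json")
        p2 = write_trace(sess.trace, out_dir / "tiny_session.trace.csv")
        return [p1, p1.with_suffix(".trials.csv"), p2]
    if kind in ("null_cohort", "dose_cohort"):
        effect = (
            EffectModel(gmax_slope=0.0, fmax_slope=0.0, noise_sd_log10=0.0)
            if kind == "null_cohort"
            else EffectModel()
        )
        cohort = generate_cohort(6, None, effect, seed=seed)
        rows = []
        for s in cohort:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "age_years": round(s.age_years, 2),
                    "severity_class": s.severity_class,
                    "logmar_fellow": round(s.logmar_fellow, 4),
                    "logmar_amblyopic": round(s.logmar_amblyopic, 4),
                    "fellow_gmax": round(s.fellow_csf.gmax, 4),
                    "fellow_fmax": round(s.fellow_csf.fmax, 4),
                    "fellow_beta": round(s.fellow_csf.beta, 4),
                    "amblyopic_gmax": round(s.amblyopic_csf.gmax, 4),
                    "amblyopic_fmax": round(s.amblyopic_csf.fmax, 4),
                    "amblyopic_beta": round(s.amblyopic_csf.beta, 4),
                    "fellow_aucsf_true": round(aucsf(s.fellow_csf), 6),
                    "amblyopic_aucsf_true": round(aucsf(s.amblyopic_csf), 6),
                }
            )
        manifest = out_dir / f"{kind}.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        prov = out_dir / f"{kind}.provenance.json"
        prov.write_text(
            json.dumps(
                {
                    "kind": kind,
                    "seed": seed,
                    "effect_model": {
                        "gmax_slope": effect.gmax_slope,
                        "fmax_slope": effect.fmax_slope,
                        "noise_sd_log10": effect.noise_sd_log10,
                    },
                    **provenance_block(cfg, seed),
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )
        return [manifest, prov]
    raise ValidationError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
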