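"""Delimited-text gaze and event file dialects, geometry, and run config.

Gaze files are UTF-8 delimited text with a header row.  Recognised column
layouts (angles in degrees visual angle, time in seconds):

* monocular:  ``time_s, x_deg, y_deg``
* binocular:  ``time_s, xl_deg, yl_deg, xr_deg, yr_deg``
* pixel variants (``x_px`` etc.) require a :class:`ScreenGeometry` and are
  converted to degrees from screen centre via the exact small-target
  relation ``θ = 2·atan(d / 2D)`` with ``d`` the on-screen offset and
  ``D`` the viewing distance (at 57 cm, 1 cm subtends ≈ 1.005°).

Missing samples are empty fields (NaN in memory).  Timestamps must be
strictly increasing; violations are rejected with the offending row.
Event tables carry ``kind, trial_id, onset_s, offset_s, duration_s,
amplitude_deg, peak_velocity_degps`` and round-trip losslessly (floats
written with 17 significant digits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from mainseq.detection import DetectionParams, GazeRecording, OculomotorEvent
from mainseq.errors import ValidationError
from mainseq.fitting import FitResult, ModelComparison

__all__ = [
    "ScreenGeometry",
    "read_gaze",
    "write_gaze",
    "read_events",
    "write_events",
    "write_fit_report",
    "read_fit_report",
    "load_config",
    "detection_params_from_config",
]

_MONO_DEG = ["time_s", "x_deg", "y_deg"]
_BINO_DEG = ["time_s", "xl_deg", "yl_deg", "xr_deg", "yr_deg"]
_MONO_PX = ["time_s", "x_px", "y_px"]
_BINO_PX = ["time_s", "xl_px", "yl_px", "xr_px", "yr_px"]

EVENT_COLUMNS = [
    "kind", "trial_id", "onset_s", "offset_s",
    "duration_s", "amplitude_deg", "peak_velocity_degps",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen description for pixel-to-degree conversion."""

    width_px: float
    height_px: float
    width_cm: float
    height_cm: float
    distance_cm: float

    def __post_init__(self):
        for f in ("width_px", "height_px", "width_cm", "height_cm", "distance_cm"):
            if not getattr(self, f) > 0:
                raise ValidationError(f"geometry field {f} must be > 0")

    def px_to_deg_x(self, px: np.ndarray) -> np.ndarray:
        cm = (np.asarray(px, dtype=float) - self.width_px / 2.0) * (self.width_cm / self.width_px)
        return np.degrees(2.0 * np.arctan(cm / (2.0 * self.distance_cm)))

    def px_to_deg_y(self, px: np.ndarray) -> np.ndarray:
        cm = (np.asarray(px, dtype=float) - self.height_px / 2.0) * (self.height_cm / self.height_px)
        return np.degrees(2.0 * np.arctan(cm / (2.0 * self.distance_cm)))


def read_gaze(
    path,
    geometry: Optional[ScreenGeometry] = None,
    nominal_rate: Optional[float] = None,
    trial_id: Optional[str] = None,
    sep: str = ",",
) -> GazeRecording:
    """Read one trial's gaze recording from a delimited text file."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = list(df.columns)
    pixel = False
    if cols[: len(_MONO_DEG)] == _MONO_DEG:
        layout = _MONO_DEG
    elif cols[: len(_BINO_DEG)] == _BINO_DEG:
        layout = _BINO_DEG
    elif cols[: len(_MONO_PX)] == _MONO_PX:
        layout, pixel = _MONO_PX, True
    elif cols[: len(_BINO_PX)] == _BINO_PX:
        layout, pixel = _BINO_PX, True
    else:
        raise ValidationError(
            f"{path.name}: malformed header {cols}; expected one of "
            f"{_MONO_DEG}, {_BINO_DEG}, {_MONO_PX}, {_BINO_PX}"
        )
    if pixel and geometry is None:
        raise ValidationError(f"{path.name}: pixel columns require a screen geometry")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # offending sample is bad[0]+1; +2 more for the header row and 1-based lines
        raise ValidationError(
            f"{path.name}: timestamps not strictly increasing at data row {int(bad[0]) + 3}"
        )
    kwargs = dict(
        t=t,
        nominal_rate=nominal_rate or _infer_rate(t),
        trial_id=trial_id if trial_id is not None else path.stem,
    )
    if layout in (_MONO_DEG, _MONO_PX):
        x = df[layout[1]].to_numpy(dtype=float)
        y = df[layout[2]].to_numpy(dtype=float)
        if pixel:
            x, y = geometry.px_to_deg_x(x), geometry.px_to_deg_y(y)
        kwargs.update(x=x, y=y)
    else:
        arrs = {c: df[c].to_numpy(dtype=float) for c in layout[1:]}
        if pixel:
            kwargs.update(
                xl=geometry.px_to_deg_x(arrs["xl_px"]), yl=geometry.px_to_deg_y(arrs["yl_px"]),
                xr=geometry.px_to_deg_x(arrs["xr_px"]), yr=geometry.px_to_deg_y(arrs["yr_px"]),
            )
        else:
            kwargs.update(xl=arrs["xl_deg"], yl=arrs["yl_deg"], xr=arrs["xr_deg"], yr=arrs["yr_deg"])
    return GazeRecording(**kwargs)


def _infer_rate(t: np.ndarray) -> float:
    if t.size < 2:
        return 500.0
    return 1.0 / float(np.median(np.diff(t)))


def write_gaze(rec: GazeRecording, path, sep: str = ",") -> None:
    """Write a recording in the monocular or binocular degree dialect."""
    if rec.monocular:
        df = pd.DataFrame({"time_s": rec.t, "x_deg": rec.x, "y_deg": rec.y})
    else:
        df = pd.DataFrame({
            "time_s": rec.t, "xl_deg": rec.xl, "yl_deg": rec.yl,
            "xr_deg": rec.xr, "yr_deg": rec.yr,
        })
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_events(events: Sequence[OculomotorEvent], path, sep: str = ",") -> None:
    """Write an event table; an empty list produces a header-only file."""
    rows = [
        {
            "kind": e.kind, "trial_id": e.trial_id, "onset_s": e.onset, "offset_s": e.offset,
            "duration_s": e.duration, "amplitude_deg": e.amplitude,
            "peak_velocity_degps": e.peak_velocity,
        }
        for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_events(path, sep: str = ",") -> List[OculomotorEvent]:
    df = pd.read_csv(Path(path), sep=sep, float_precision="round_trip")
    if list(df.columns) != EVENT_COLUMNS:
        raise ValidationError(f"malformed event table header {list(df.columns)}")
    return [
        OculomotorEvent(
            kind=r.kind, trial_id=str(r.trial_id), onset=r.onset_s, offset=r.offset_s,
            duration=r.duration_s, amplitude=r.amplitude_deg, peak_velocity=r.peak_velocity_degps,
        )
        for r in df.itertuples(index=False)
    ]


def write_fit_report(comparison: ModelComparison, path, sep: str = ",") -> None:
    """Two-section delimited report: model comparison, then parameter table.

    Section rows are tagged in a leading ``section`` column so a single
    flat file carries both the family-level statistics (residual SE, model
    df, AIC, ΔAIC, Vuong z and p; one ΔAIC row per family) and the
    per-parameter estimates (estimate, SE, t).
    """
    rows = []
    for r in comparison.rows:
        rows.append({
            "section": "comparison", "family": r["family"], "parameter": "",
            "residual_se": r["residual_se"], "model_df": r["model_df"],
            "aic": r["aic"], "delta_aic": r["delta_aic"],
            "vuong_z": r["vuong_z"], "vuong_p": r["vuong_p"],
            "estimate": "", "se": "", "t": "",
        })
    for fam, fit in comparison.fits.items():
        for name, est, se, tval in zip(fit.param_names, fit.estimates, fit.standard_errors, fit.t_stats):
            rows.append({
                "section": "parameters", "family": fam, "parameter": name,
                "residual_se": "", "model_df": "", "aic": "", "delta_aic": "",
                "vuong_z": "", "vuong_p": "",
                "estimate": est, "se": se, "t": tval,
            })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_fit_report(path, sep: str = ","):
    """Read back a fit report as (comparison frame, parameters frame)."""
    df = pd.read_csv(Path(path), sep=sep)
    comp = df[df["section"] == "comparison"].drop(columns=["section", "parameter", "estimate", "se", "t"])
    pars = df[df["section"] == "parameters"][["family", "parameter", "estimate", "se", "t"]]
    return comp.reset_index(drop=True), pars.reset_index(drop=True)


def load_config(path) -> dict:
    """Load the shared YAML run configuration (flat sections per module)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping of sections")
    return cfg


def detection_params_from_config(cfg: dict, **overrides) -> DetectionParams:
    """Build DetectionParams from the ``detection`` config section.

    Keyword overrides (e.g. CLI flags) take precedence over the file.
    """
    section = dict(cfg.get("detection", {}))
    section.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f for f in DetectionParams.__dataclass_fields__}
    unknown = set(section) - valid
    if unknown:
        raise ValidationError(f"unknown detection parameters {sorted(unknown)}")
    return DetectionParams(**section)
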