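"""Descriptive statistics of detected oculomotor events.

Summaries follow the layout conventional in microsaccade studies: one row
per measure (amplitude in deg, peak velocity in deg/s, duration in s, and
rate in events/s) with mean, SD, minimum, maximum, skewness and kurtosis.
Skewness is the adjusted Fisher–Pearson (bias-corrected) coefficient and
kurtosis is *excess* kurtosis (0 for a Gaussian).  Rate is computed per
trial (event count over trial duration) and then summarised across trials,
so short trials can contribute extreme maxima.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from mainseq.detection import OculomotorEvent
from mainseq.errors import ValidationError

__all__ = ["describe_events", "MEASURES", "COLUMNS"]

MEASURES = ("amplitude", "peak_velocity", "duration", "rate")
COLUMNS = ("mean", "sd", "minimum", "maximum", "skewness", "kurtosis")


def _moments(x: np.ndarray) -> dict:
    out = dict.fromkeys(COLUMNS, float("nan"))
    if x.size == 0:
        return out
    out["mean"] = float(np.mean(x))
    out["minimum"] = float(np.min(x))
    out["maximum"] = float(np.max(x))
    if x.size < 2:
        return out
    sd = float(np.std(x, ddof=1))
    out["sd"] = sd
    if sd <= 1e-12 * max(abs(out["mean"]), 1.0):
        # degenerate dispersion (allowing for mean-subtraction roundoff):
        # shape statistics are undefined
        out["sd"] = 0.0
        return out
    out["skewness"] = float(sps.skew(x, bias=False))
    out["kurtosis"] = float(sps.kurtosis(x, fisher=True, bias=False))
    return out


def describe_events(
    events: Sequence[OculomotorEvent],
    trial_durations: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Summarise event kinematics, one row per measure.

    Parameters
    ----------
    events : sequence of OculomotorEvent
        Typically pre-filtered to one kind (microsaccades or saccades).
    trial_durations : mapping trial_id -> duration (s), optional
        Enables the per-trial rate row; trials present in the mapping but
        absent from ``events`` contribute a rate of 0.

    Returns
    -------
    pandas.DataFrame indexed by measure with columns
    ``mean, sd, minimum, maximum, skewness, kurtosis``.  Empty input gives
    an all-NaN frame (explicit NA semantics).
    """
    events = list(events)
    rows = {}
    amp = np.array([e.amplitude for e in events])
    pv = np.array([e.peak_velocity for e in events])
    dur = np.array([e.duration for e in events])
    rows["amplitude"] = _moments(amp)
    rows["peak_velocity"] = _moments(pv)
    rows["duration"] = _moments(dur)
    if trial_durations is not None:
        counts: Dict[str, int] = {trial: 0 for trial in trial_durations}
        for e in events:
            if e.trial_id not in trial_durations:
                raise ValidationError(f"no duration supplied for trial {e.trial_id!r}")
            counts[e.trial_id] += 1
        for trial, d in trial_durations.items():
            if not d > 0:
                raise ValidationError(f"trial {trial!r} has non-positive duration")
        rates = np.array([counts[trial] / trial_durations[trial] for trial in trial_durations])
        rows["rate"] = _moments(rates)
    else:
        rows["rate"] = dict.fromkeys(COLUMNS, float("nan"))
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(COLUMNS)).loc[list(MEASURES)]
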