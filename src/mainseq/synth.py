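"""Seeded synthetic main-sequence scatter and gaze-stream generation.

Two generators make the rest of the package testable without recorded
eye-tracking data:

* :func:`gen_scatter` draws (amplitude, peak velocity) pairs: amplitudes
  from a truncated normal or truncated log-normal matched to published
  sample moments, velocities from any main-sequence model plus Gaussian
  residual noise.  This emulates the aggregate event scatter that the
  fitting module consumes.
* :func:`gen_stream` builds a full gaze recording: white Gaussian velocity
  noise per component emulates fixational drift (velocity vectors with
  random orientations), and scheduled ballistic events with gamma-shaped
  velocity profiles are integrated on top, each normalised so its
  displacement equals the scheduled amplitude exactly.  The ground-truth
  event list is returned alongside.

All randomness flows through explicit integer seeds; there is no global
RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from mainseq.detection import GazeRecording, OculomotorEvent
from mainseq.errors import ValidationError
from mainseq.models import GammaProfile, VelocityModelParams, eval_velocity

__all__ = [
    "AmplitudeDist",
    "AmplitudeMixture",
    "ScatterSpec",
    "ScatterSample",
    "ScheduledEvent",
    "StreamSpec",
    "gen_scatter",
    "gen_stream",
]


@dataclass(frozen=True)
class AmplitudeDist:
    """Truncated amplitude distribution matched to sample moments.

    ``kind="truncnorm"`` truncates a normal with the given mean/sd to
    [min, max]; ``kind="lognormal"`` moment-matches a log-normal to the
    mean/sd (right-skewed, the natural shape for saccade amplitudes) and
    truncates by rejection.
    """

    kind: str
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if self.kind not in ("truncnorm", "lognormal"):
            raise ValidationError(f"unknown amplitude distribution {self.kind!r}")
        if not self.sd > 0:
            raise ValidationError("sd must be > 0")
        if not self.min < self.max:
            raise ValidationError("min must be < max")
        if self.kind == "lognormal" and not self.mean > 0:
            raise ValidationError("lognormal mean must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "truncnorm":
            a = (self.min - self.mean) / self.sd
            b = (self.max - self.mean) / self.sd
            return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        # moment-matched log-normal, truncated by rejection
        s2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - s2 / 2.0
        sigma = math.sqrt(s2)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.lognormal(mu, sigma, size=max(n - filled, 1024))
            keep = draw[(draw >= self.min) & (draw <= self.max)]
            take = min(keep.size, n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        return out


@dataclass(frozen=True)
class AmplitudeMixture:
    """Finite mixture of amplitude distributions with fixed count weights.

    Used to superpose event populations (e.g. microsaccades plus saccades)
    in their observed proportions: each draw of size ``n`` allocates
    component counts proportionally (largest remainder) rather than
    multinomially, so the mixture composition is exact.
    """

    components: Tuple[Tuple[float, AmplitudeDist], ...]

    def __post_init__(self):
        object.__setattr__(self, "components", tuple((float(w), d) for w, d in self.components))
        if not self.components:
            raise ValidationError("mixture needs at least one component")
        if any(w <= 0 for w, _ in self.components):
            raise ValidationError("mixture weights must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([w for w, _ in self.components])
        shares = weights / weights.sum() * n
        counts = np.floor(shares).astype(int)
        remainder = n - counts.sum()
        order = np.argsort(-(shares - counts))
        counts[order[:remainder]] += 1
        parts = [d.sample(int(c), rng) for (_, d), c in zip(self.components, counts) if c > 0]
        out = np.concatenate(parts)
        return out[rng.permutation(n)]


@dataclass(frozen=True)
class ScatterSpec:
    """Recipe for one seeded (amplitude, peak velocity) scatter sample."""

    n: int
    generator: VelocityModelParams
    noise_sd: float
    amplitude_dist: AmplitudeDist
    seed: int

    def __post_init__(self):
        if not self.n > 0:
            raise ValidationError("n must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ScatterSample:
    """Generated scatter plus its ground truth."""

    A: np.ndarray
    Vp: np.ndarray
    spec: ScatterSpec

    @property
    def truth(self) -> VelocityModelParams:
        return self.spec.generator


def gen_scatter(spec: ScatterSpec) -> ScatterSample:
    """Draw amplitudes, evaluate the generating model, add Gaussian noise.

    Bit-identical under a fixed seed.  With ``noise_sd = 0`` every point
    lies exactly on the generating curve.
    """
    rng = np.random.default_rng(spec.seed)
    A = spec.amplitude_dist.sample(spec.n, rng)
    Vp = np.asarray(eval_velocity(spec.generator, A), dtype=float)
    if spec.noise_sd > 0:
        Vp = Vp + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return ScatterSample(A=A, Vp=Vp, spec=spec)


@dataclass(frozen=True)
class ScheduledEvent:
    """One ballistic event to inject into a gaze stream.

    The gamma profile starts at ``onset`` (s); ``direction_deg`` is the
    movement direction in screen coordinates (0 = rightward).  The
    profile's event window is its 1%-of-peak support.
    """

    onset: float
    amplitude: float
    direction_deg: float
    profile: GammaProfile

    @classmethod
    def create(
        cls, onset: float, amplitude: float, direction_deg: float,
        peak_velocity: float, gamma: float = 30.0,
    ) -> "ScheduledEvent":
        """Build the event with a profile whose displacement matches ``amplitude``."""
        profile = GammaProfile.from_amplitude(alpha=peak_velocity, gamma=gamma, amplitude=amplitude)
        return cls(onset=onset, amplitude=amplitude, direction_deg=direction_deg, profile=profile)

    def window(self) -> Tuple[float, float]:
        """Absolute (start, end) of the event's support."""
        t_on, t_off = self.profile.support()
        return (self.onset + t_on, self.onset + t_off)


@dataclass(frozen=True)
class StreamSpec:
    """Recipe for one seeded gaze recording with ground-truth events."""

    duration: float
    rate: float
    drift_sd: float
    event_schedule: Tuple[ScheduledEvent, ...] = ()
    seed: int = 0
    trial_id: str = "synthetic"
    #: event kind recorded in the ground truth for amplitudes below/above 1.5 deg
    microsaccade_cutoff: float = 1.5

    def __post_init__(self):
        if not self.duration > 0:
            raise ValidationError("duration must be > 0")
        if not self.rate > 0:
            raise ValidationError("rate must be > 0")
        if self.drift_sd < 0:
            raise ValidationError("drift_sd must be >= 0")
        object.__setattr__(self, "event_schedule", tuple(self.event_schedule))
        windows = sorted(ev.window() for ev in self.event_schedule)
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            if s2 < e1:
                raise ValidationError(f"scheduled events overlap: [{s1:.4f},{e1:.4f}] and [{s2:.4f},{e2:.4f}]")
        for s, e in windows:
            if s < 0 or e > self.duration:
                raise ValidationError("event support extends outside the recording")


def random_schedule(
    duration: float,
    n_events: int,
    amplitude_dist: AmplitudeDist,
    velocity_model: VelocityModelParams,
    seed: int,
    gamma: float = 30.0,
    margin: float = 0.1,
    jitter: float = 0.25,
) -> Tuple[ScheduledEvent, ...]:
    """Evenly spaced, jittered event schedule with main-sequence kinematics.

    Amplitudes come from ``amplitude_dist``; each event's peak velocity is
    the model prediction at its amplitude.  Onsets are spread over
    ``[margin, duration − margin]`` with relative jitter, keeping supports
    disjoint.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    amps = amplitude_dist.sample(n_events, rng)
    slots = np.linspace(margin, duration - margin, n_events + 1)
    pitch = slots[1] - slots[0]
    events = []
    for i, amp in enumerate(amps):
        onset = float(slots[i] + pitch * (0.5 + jitter * (rng.random() - 0.5)))
        alpha = float(eval_velocity(velocity_model, amp))
        if alpha <= 0:
            raise ValidationError("velocity model predicts non-positive peak velocity")
        events.append(ScheduledEvent.create(onset, float(amp), float(rng.uniform(0, 360)), alpha, gamma))
    return tuple(events)


def gen_stream(spec: StreamSpec) -> Tuple[GazeRecording, List[OculomotorEvent]]:
    """Integrate drift noise plus scheduled event profiles into gaze positions.

    Drift is white Gaussian velocity noise per component (``drift_sd``
    deg/s).  Each event's sampled velocity profile is rescaled so its
    discrete displacement integral equals the scheduled amplitude to
    machine precision.  Ground-truth events carry the support window, the
    scheduled amplitude and the profile's peak velocity.
    """
    dt = 1.0 / spec.rate
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) * dt
    rng = np.random.default_rng(spec.seed)
    v = rng.normal(0.0, spec.drift_sd, size=(n, 2)) if spec.drift_sd > 0 else np.zeros((n, 2))

    truth: List[OculomotorEvent] = []
    for ev in spec.event_schedule:
        t_on, t_off = ev.profile.support()
        i0 = int(np.searchsorted(t, ev.onset))
        i1 = int(np.searchsorted(t, ev.onset + t_off, side="right"))
        tau = t[i0:i1] - ev.onset
        speed = np.asarray(ev.profile(np.maximum(tau, 0.0)), dtype=float)
        total = float(np.sum(speed) * dt)
        if total <= 0:
            raise ValidationError("event too short for the sampling rate")
        speed *= ev.amplitude / total  # exact discrete displacement
        theta = math.radians(ev.direction_deg)
        v[i0:i1, 0] += speed * math.cos(theta)
        v[i0:i1, 1] += speed * math.sin(theta)
        kind = "microsaccade" if ev.amplitude < spec.microsaccade_cutoff else "saccade"
        truth.append(
            OculomotorEvent(
                kind=kind,
                onset=ev.onset + t_on,
                offset=ev.onset + t_off,
                duration=t_off - t_on,
                amplitude=ev.amplitude,
                peak_velocity=float(np.max(speed)),
                trial_id=spec.trial_id,
            )
        )

    pos = np.cumsum(v * dt, axis=0)
    rec = GazeRecording(t=t, x=pos[:, 0], y=pos[:, 1], nominal_rate=spec.rate, trial_id=spec.trial_id)
    return rec, truth
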