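"""Closed-form main-sequence model families and their algebraic conversions.

The saccadic *main sequence* links the amplitude ``A`` of a rapid eye
movement (degrees visual angle) to its peak velocity ``Vp`` (deg/s) and to
its duration ``MT`` (s).  Five peak-velocity families are implemented:

``inverse_linear``
    Michaelis–Menten saturation, ``V(A) = Va·A/(A + A0)``; ``A0`` is the
    half-maximum amplitude.
``exponential``
    ``V(A) = Va·(1 − exp(−A/A0))``; ``A0`` is the amplitude at which the
    curve reaches 63% (``1 − 1/e``) of its saturation velocity.
``power_law``
    ``V(A) = Va·A**A0``; ``A0`` is the exponent (``A0 = 1/2`` gives the
    classical square-root model).
``logistic``
    ``V(A) = Va / (1 + exp(−A2·(A − A0)))``; sigmoid with midpoint ``A0``
    and steepness ``A2``.
``il_logistic``
    The inverse-linear logistic S-curve,

        ``V(A) = Va · A/(A + A1) · 1/(1 + exp(−A2·(A + A0)))``,

    an inverse-linear factor (shift ``A1``) multiplied by a logistic factor
    whose midpoint sits at ``−A0`` (fitted ``A0`` values are negative, so
    the inflection lands at a small positive amplitude).  Flat at both
    amplitude extremes, which neither the inverse-linear nor the
    exponential family can express.

Durations follow either the classical affine law ``MT = a + b·A`` or the
duration form of the inverse-linear logistic model,

    ``MT(A) = (K/Va) · (A + k0 − A0) / (1 + k1·A1·exp(−k2·A2·A))``,

obtained from the mean-velocity identity ``Vm = A/MT`` and the scaling
``Vp = K·Vm``.  For large ``A`` the correction term vanishes and the curve
becomes exactly affine with slope ``K/Va`` — the mechanism by which one
model fits both the saturating velocity relation and the linear duration
relation.  ``MT`` is returned in the time unit implied by ``K/Va``
(seconds when ``K`` is chosen on the second scale).

All evaluators accept scalars or numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from mainseq.errors import ValidationError

__all__ = [
    "FAMILIES",
    "VelocityModelParams",
    "LinearDurationModel",
    "PowerDurationModel",
    "DurationILLogisticModel",
    "GammaProfile",
    "eval_velocity",
    "eval_duration",
    "invert_linear_duration",
    "invert_power_duration",
    "peak_from_mean",
    "duration_from_velocity_model",
    "gamma_velocity_profile",
]

FAMILIES = ("inverse_linear", "exponential", "power_law", "logistic", "il_logistic")

#: parameters each family actually uses, in fitting/reporting order
FAMILY_PARAMS = {
    "inverse_linear": ("Va", "A0"),
    "exponential": ("Va", "A0"),
    "power_law": ("Va", "A0"),
    "logistic": ("Va", "A0", "A2"),
    "il_logistic": ("Va", "A1", "A2", "A0"),
}

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class VelocityModelParams:
    """Parameters of one peak-velocity–amplitude model family.

    Fields not used by the family must be left ``None``.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    Va : float
        Asymptotic peak velocity, deg/s (the scale for ``power_law``).
    A0 : float
        Location parameter, deg: half-maximum amplitude (inverse_linear),
        63%-saturation amplitude (exponential), exponent (power_law),
        sigmoid midpoint (logistic) or negated sigmoid midpoint
        (il_logistic).
    A1 : float, optional
        Inverse-linear shift of the il_logistic family, deg; ≥ 0.
    A2 : float, optional
        Sigmoid steepness, 1/deg; > 0.  logistic and il_logistic only.
    """

    family: str
    Va: float
    A0: float
    A1: Optional[float] = None
    A2: Optional[float] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if not (self.Va > 0 and math.isfinite(self.Va)):
            raise ValidationError(f"Va must be positive and finite, got {self.Va}")
        if not math.isfinite(self.A0):
            raise ValidationError(f"A0 must be finite, got {self.A0}")
        used = FAMILY_PARAMS[self.family]
        for name in ("A1", "A2"):
            value = getattr(self, name)
            if name in used:
                if value is None:
                    raise ValidationError(f"family {self.family!r} requires parameter {name}")
                if not math.isfinite(value):
                    raise ValidationError(f"{name} must be finite, got {value}")
            elif value is not None:
                raise ValidationError(f"family {self.family!r} does not use parameter {name}")
        if self.A1 is not None and self.A1 < 0:
            raise ValidationError(f"A1 must be >= 0, got {self.A1}")
        if self.A2 is not None and self.A2 <= 0:
            raise ValidationError(f"A2 must be > 0, got {self.A2}")
        if self.family == "exponential" and self.A0 <= 0:
            raise ValidationError("exponential family requires A0 > 0")
        if self.family == "inverse_linear" and self.A0 < 0:
            raise ValidationError("inverse_linear family requires A0 >= 0")

    @property
    def values(self) -> np.ndarray:
        """Used parameters as a vector, ordered per :data:`FAMILY_PARAMS`."""
        return np.array([getattr(self, p) for p in FAMILY_PARAMS[self.family]], dtype=float)

    @property
    def param_names(self) -> tuple:
        return FAMILY_PARAMS[self.family]

    def to_dict(self) -> dict:
        d = {"family": self.family}
        for p in FAMILY_PARAMS[self.family]:
            d[p] = float(getattr(self, p))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VelocityModelParams":
        family = d["family"]
        if family not in FAMILIES:
            raise ValidationError(f"unknown model family {family!r}")
        kwargs = {p: float(d[p]) for p in FAMILY_PARAMS[family]}
        return cls(family=family, **kwargs)

    @classmethod
    def from_vector(cls, family: str, theta) -> "VelocityModelParams":
        if family not in FAMILIES:
            raise ValidationError(f"unknown model family {family!r}")
        names = FAMILY_PARAMS[family]
        if len(theta) != len(names):
            raise ValidationError(f"family {family!r} takes {len(names)} parameters, got {len(theta)}")
        return cls(family=family, **{n: float(v) for n, v in zip(names, theta)})


@dataclass(frozen=True)
class LinearDurationModel:
    """Affine duration law ``MT = a + b·A`` with ``a`` in s, ``b`` in s/deg."""

    a: float
    b: float

    def __post_init__(self):
        if not self.b > 0:
            raise ValidationError(f"slope b must be > 0, got {self.b}")
        if self.a < 0:
            raise ValidationError(f"intercept a must be >= 0, got {self.a}")


@dataclass(frozen=True)
class PowerDurationModel:
    """Power duration law ``MT = a·A**b`` with ``a`` in s, exponent ``0 < b < 1``."""

    a: float
    b: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValidationError(f"scale a must be > 0, got {self.a}")
        if not 0 < self.b < 1:
            raise ValidationError(f"exponent b must lie in (0, 1), got {self.b}")


@dataclass(frozen=True)
class DurationILLogisticModel:
    """Duration–amplitude form of the inverse-linear logistic model.

    ``MT(A) = (K/Va)·(A + k0 − A0) / (1 + k1·A1·exp(−k2·A2·A))``

    ``Va, A0, A1, A2`` come from a fitted velocity model; ``k0`` (deg)
    adjusts the intercept, ``k1``/``k2`` (unitless) rescale the logistic
    shift and steepness, and ``K`` (deg/s, conventionally quoted as a
    multiple of ``Va``) is the peak-to-mean velocity scale.  Durations come
    out in the time unit of ``K/Va``: published coefficient sets on the
    second scale have ``K/Va`` near 0.01–0.02 s/deg, while the classical
    illustration uses ``K/Va = 2.5`` on the millisecond scale.
    """

    Va: float
    A0: float
    A1: float
    A2: float
    k0: float
    k1: float
    k2: float
    K: float

    def __post_init__(self):
        if not self.K > 0:
            raise ValidationError(f"K must be > 0, got {self.K}")
        if not self.Va > 0:
            raise ValidationError(f"Va must be > 0, got {self.Va}")
        if self.A1 < 0:
            raise ValidationError(f"A1 must be >= 0, got {self.A1}")
        if self.A2 <= 0:
            raise ValidationError(f"A2 must be > 0, got {self.A2}")

    # derived constants of the affine/logistic rearrangement
    @property
    def slope(self) -> float:
        """a = 1/Va (times K gives the asymptotic duration slope)."""
        return 1.0 / self.Va

    @property
    def intercept_shift(self) -> float:
        """b = k0 − A0, deg."""
        return self.k0 - self.A0

    @property
    def steepness(self) -> float:
        """c = k2·A2, 1/deg."""
        return self.k2 * self.A2

    @property
    def shift(self) -> float:
        """d = k1·A1, unitless."""
        return self.k1 * self.A1

    def velocity_params(self) -> VelocityModelParams:
        return VelocityModelParams("il_logistic", Va=self.Va, A0=self.A0, A1=self.A1, A2=self.A2)


def _as_amplitude(A: ArrayLike) -> np.ndarray:
    arr = np.asarray(A, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("amplitude must be >= 0")
    return arr


def eval_velocity(params: VelocityModelParams, A: ArrayLike) -> ArrayLike:
    """Peak velocity (deg/s) predicted by ``params`` at amplitude ``A`` (deg).

    ``power_law`` maps ``A = 0`` to 0 by continuity (positive exponent).
    """
    arr = _as_amplitude(A)
    f = params.family
    if f == "inverse_linear":
        with np.errstate(invalid="ignore"):
            out = np.where(arr > 0, params.Va * arr / (arr + params.A0), 0.0)
    elif f == "exponential":
        out = params.Va * -np.expm1(-arr / params.A0)
    elif f == "power_law":
        with np.errstate(divide="ignore"):
            out = np.where(arr > 0, params.Va * np.power(arr, params.A0), 0.0)
    elif f == "logistic":
        out = params.Va * _expit(params.A2 * (arr - params.A0))
    elif f == "il_logistic":
        with np.errstate(invalid="ignore"):
            inv = np.where(arr > 0, arr / (arr + params.A1), 0.0)
        out = params.Va * inv * _expit(params.A2 * (arr + params.A0))
    else:  # pragma: no cover - guarded by the dataclass
        raise ValidationError(f"unknown family {f!r}")
    if np.ndim(A) == 0:
        return float(out)
    return out


def _expit(z: np.ndarray) -> np.ndarray:
    # overflow-safe logistic
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def eval_duration(model, A: ArrayLike) -> ArrayLike:
    """Saccade duration predicted at amplitude ``A`` (deg).

    Accepts a :class:`LinearDurationModel` (s), :class:`PowerDurationModel`
    (s) or :class:`DurationILLogisticModel` (unit set by ``K/Va``; see the
    class docstring).
    """
    arr = _as_amplitude(A)
    if isinstance(model, LinearDurationModel):
        out = model.a + model.b * arr
    elif isinstance(model, PowerDurationModel):
        out = np.where(arr > 0, model.a * np.power(arr, model.b), 0.0)
    elif isinstance(model, DurationILLogisticModel):
        numer = (model.K / model.Va) * (arr + model.k0 - model.A0)
        denom = 1.0 + model.k1 * model.A1 * np.exp(-model.k2 * model.A2 * arr)
        out = numer / denom
    else:
        raise ValidationError(f"unsupported duration model type {type(model).__name__}")
    if np.ndim(A) == 0:
        return float(out)
    return out


def invert_linear_duration(model: LinearDurationModel) -> VelocityModelParams:
    """Mean-velocity Michaelis–Menten curve implied by an affine duration law.

    From ``Vm = A/MT = A/(a + b·A)`` the mean velocity follows
    ``Vm(A) = (1/b)·A/(A + a/b)``: an inverse-linear curve with asymptote
    ``1/b`` (deg/s when ``a`` is in s and ``b`` in s/deg) and half-maximum
    amplitude ``A0 = a/b`` (deg).  The classical line ``MT = 37 + 2.7A``
    (ms) inverts to ``A0 = 13.70``.  A zero intercept gives ``A0 = 0``:
    duration purely proportional to amplitude, i.e. constant mean velocity.
    """
    if model.b <= 0:
        raise ValidationError("cannot invert a duration law with non-positive slope")
    return VelocityModelParams("inverse_linear", Va=1.0 / model.b, A0=model.a / model.b)


def invert_power_duration(model: PowerDurationModel) -> VelocityModelParams:
    """Mean-velocity power law implied by a power duration law.

    ``Vm = A/(a·A**b) = (1/a)·A**(1−b)``: scale ``1/a``, exponent ``1 − b``.
    Requires ``b < 1`` so mean velocity still increases with amplitude.
    """
    if not model.b < 1:
        raise ValidationError("power duration exponent must be < 1 for an increasing velocity law")
    return VelocityModelParams("power_law", Va=1.0 / model.a, A0=1.0 - model.b)


def peak_from_mean(Vm: ArrayLike, K: float) -> ArrayLike:
    """Peak velocity from mean velocity via the linear scaling ``Vp = K·Vm``."""
    if not K > 0:
        raise ValidationError(f"K must be > 0, got {K}")
    out = K * np.asarray(Vm, dtype=float)
    if np.ndim(Vm) == 0:
        return float(out)
    return out


def duration_from_velocity_model(params: VelocityModelParams, K: float, A: ArrayLike) -> ArrayLike:
    """Duration implied by a peak-velocity model and the scaling ``Vp = K·Vm``.

    ``MT = A/Vm = K·A/Vp(A)``.  Exact algebraic inverse of
    :func:`peak_from_mean` composed with the mean-velocity identity:
    recomputing ``A/MT`` recovers ``Vp/K`` to machine precision.
    """
    if not K > 0:
        raise ValidationError(f"K must be > 0, got {K}")
    arr = _as_amplitude(A)
    if np.any(arr == 0):
        raise ValidationError("duration is undefined at zero amplitude")
    out = K * arr / eval_velocity(params, arr)
    if np.ndim(A) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GammaProfile:
    """Gamma-shaped saccadic velocity waveform.

    ``v(t) = α · (t/β)^(γ−1)·exp(−t/β) / N``  with ``N`` the maximum of the
    unnormalised shape, so the peak velocity equals ``α`` (deg/s) exactly at
    ``t = (γ−1)·β``.  ``β`` (s) sets the time scale and ``γ`` (> 1,
    unitless) the asymmetry: small ``γ`` gives a positively skewed profile
    (fast rise, slow decay — large saccades), and as ``γ → ∞`` the shape
    tends to a symmetric Gaussian; the normalised-shape skewness is
    ``2/√γ``.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValidationError(f"beta must be > 0, got {self.beta}")
        if not self.gamma > 1:
            raise ValidationError(
                f"gamma must be > 1 for a unimodal profile starting at rest, got {self.gamma}"
            )

    @property
    def t_peak(self) -> float:
        return (self.gamma - 1.0) * self.beta

    def _log_rel(self, t: np.ndarray) -> np.ndarray:
        # log of profile/alpha; -inf at t = 0
        g1 = self.gamma - 1.0
        tp = self.t_peak
        with np.errstate(divide="ignore", invalid="ignore"):
            return g1 * np.log(t / tp) - (t - tp) / self.beta

    def __call__(self, t: ArrayLike) -> ArrayLike:
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise ValidationError("profile time must be >= 0")
        out = np.where(arr > 0, self.alpha * np.exp(self._log_rel(np.maximum(arr, 1e-300))), 0.0)
        if np.ndim(t) == 0:
            return float(out)
        return out

    @property
    def displacement(self) -> float:
        """Time integral of the full profile, deg (the event amplitude)."""
        g = self.gamma
        log_norm = (g - 1.0) * (math.log(g - 1.0) - 1.0)  # log of the shape maximum
        return math.exp(math.log(self.alpha) + math.log(self.beta) + gammaln(g) - log_norm)

    @property
    def skewness(self) -> float:
        """Skewness of the profile treated as a shape over time: ``2/√γ``."""
        return 2.0 / math.sqrt(self.gamma)

    def support(self, rel_cutoff: float = 0.01) -> tuple:
        """Interval ``(t_on, t_off)`` where the profile exceeds ``rel_cutoff·α``.

        The gamma waveform has an infinite decay tail; the event is deemed
        to last while the profile stays above this fraction of its peak
        (default 1%).
        """
        if not 0 < rel_cutoff < 1:
            raise ValidationError("rel_cutoff must lie in (0, 1)")
        target = math.log(rel_cutoff)
        tp = self.t_peak
        f = lambda t: float(self._log_rel(np.asarray(t, dtype=float))) - target
        t_on = brentq(f, tp * 1e-12, tp)
        hi = tp
        while f(hi) > 0:
            hi *= 2.0
        t_off = brentq(f, tp, hi)
        return (t_on, t_off)

    @classmethod
    def from_amplitude(cls, alpha: float, gamma: float, amplitude: float) -> "GammaProfile":
        """Profile with peak velocity ``alpha`` whose time integral is ``amplitude``."""
        if not amplitude > 0:
            raise ValidationError(f"amplitude must be > 0, got {amplitude}")
        if not alpha > 0 or not gamma > 1:
            raise ValidationError("need alpha > 0 and gamma > 1")
        log_norm = (gamma - 1.0) * (math.log(gamma - 1.0) - 1.0)
        log_beta = math.log(amplitude) + log_norm - math.log(alpha) - gammaln(gamma)
        return cls(alpha=alpha, beta=math.exp(log_beta), gamma=gamma)


def gamma_velocity_profile(p: GammaProfile, t: ArrayLike) -> ArrayLike:
    """Evaluate a :class:`GammaProfile` at time ``t`` (s); deg/s."""
    return p(t)
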