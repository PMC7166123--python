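"""Nonlinear least-squares fitting and model comparison for main-sequence data.

Velocity models are fit by trust-region-reflective least squares with
analytic Jacobians, scale-free starting heuristics, and a small budget of
seeded jittered restarts.  Goodness of fit is compared with AIC computed
from the full Gaussian likelihood at the MLE noise variance ``rss/n``
(one extra parameter for the variance), so only AIC *differences* are
meaningful, and with Vuong's likelihood-ratio z-test for non-nested models
using the AIC-type correction (the parameter-count difference subtracted
from the summed pointwise log-likelihood ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from mainseq.errors import ConvergenceError, DegenerateLikelihoodError, ValidationError
from mainseq.models import (
    FAMILIES,
    FAMILY_PARAMS,
    DurationILLogisticModel,
    VelocityModelParams,
    eval_duration,
    eval_velocity,
)

__all__ = [
    "FitResult",
    "LinearFitResult",
    "ModelComparison",
    "fit_velocity_model",
    "fit_duration_models",
    "fit_linear",
    "compute_aic",
    "gaussian_loglik",
    "vuong_test",
    "compare_models",
]


@dataclass
class FitResult:
    """Outcome of one nonlinear least-squares fit.

    ``model_df = n − k`` with ``k`` the number of curve parameters;
    ``residual_se = sqrt(rss/model_df)``; ``loglik`` and ``aic`` use the
    Gaussian likelihood at the MLE variance ``rss/n`` and are ``None``
    for a zero-residual (degenerate-likelihood) fit.
    """

    family: str
    param_names: Tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    t_stats: np.ndarray
    n: int
    model_df: int
    rss: float
    residual_se: float
    loglik: Optional[float]
    aic: Optional[float]
    model: object
    success: bool = True
    singular_jacobian: bool = False

    @property
    def k(self) -> int:
        return len(self.estimates)

    def predict(self, A) -> np.ndarray:
        if isinstance(self.model, VelocityModelParams):
            return np.asarray(eval_velocity(self.model, A), dtype=float)
        return np.asarray(eval_duration(self.model, A), dtype=float)


@dataclass
class LinearFitResult:
    """Ordinary least-squares fit of ``y = a + b·A``."""

    a: float
    b: float
    se_a: float
    se_b: float
    f_stat: float
    f_pvalue: float
    r_squared: float
    aic: float
    n: int
    rss: float
    residual_se: float

    def predict(self, A) -> np.ndarray:
        return self.a + self.b * np.asarray(A, dtype=float)


@dataclass
class ModelComparison:
    """AIC ranking plus pairwise Vuong tests against the base family.

    ``rows`` are sorted by AIC; the base family (smallest AIC, ties broken
    toward fewer parameters) has ``delta_aic = 0`` and no Vuong entry.
    Positive ``vuong_z`` favours the base family.
    """

    base_family: str
    rows: List[dict]
    fits: Dict[str, FitResult]


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood at the MLE variance ``rss/n``."""
    if rss <= 0:
        raise DegenerateLikelihoodError("zero residual sum of squares: likelihood is unbounded")
    return -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)


def compute_aic(fit) -> float:
    """``AIC = −2·loglik + 2·(k + 1)``; the +1 counts the noise variance.

    Accepts a :class:`FitResult` or :class:`LinearFitResult` (k = 2).
    Matches the closed form ``n·(ln 2π + ln(rss/n) + 1) + 2(k+1)``.
    """
    if isinstance(fit, LinearFitResult):
        k, rss, n = 2, fit.rss, fit.n
    else:
        k, rss, n = fit.k, fit.rss, fit.n
    return -2.0 * gaussian_loglik(rss, n) + 2.0 * (k + 1)


# ---------------------------------------------------------------------------
# residuals and Jacobians per velocity family (parameter order FAMILY_PARAMS)

def _vel_predict(family: str, theta: np.ndarray, A: np.ndarray) -> np.ndarray:
    Va = theta[0]
    if family == "inverse_linear":
        return Va * A / (A + theta[1])
    if family == "exponential":
        return Va * -np.expm1(-A / theta[1])
    if family == "power_law":
        with np.errstate(divide="ignore"):
            return np.where(A > 0, Va * np.power(A, theta[1]), 0.0)
    if family == "logistic":
        _, A0, A2 = theta
        return Va * _expit(A2 * (A - A0))
    if family == "il_logistic":
        _, A1, A2, A0 = theta
        return Va * (A / (A + A1)) * _expit(A2 * (A + A0))
    raise ValidationError(f"unknown family {family!r}")


def _expit(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _vel_jacobian(family: str, theta: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Jacobian of the model prediction wrt theta (n × k)."""
    Va = theta[0]
    if family == "inverse_linear":
        A0 = theta[1]
        d = A + A0
        return np.column_stack([A / d, -Va * A / d**2])
    if family == "exponential":
        A0 = theta[1]
        e = np.exp(-A / A0)
        return np.column_stack([1.0 - e, -Va * e * A / A0**2])
    if family == "power_law":
        p = theta[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            Ap = np.where(A > 0, np.power(A, p), 0.0)
            dlog = np.where(A > 0, np.log(np.maximum(A, 1e-300)), 0.0)
        return np.column_stack([Ap, Va * Ap * dlog])
    if family == "logistic":
        _, A0, A2 = theta
        L = _expit(A2 * (A - A0))
        LL = L * (1.0 - L)
        return np.column_stack([L, -Va * A2 * LL, Va * (A - A0) * LL])
    if family == "il_logistic":
        _, A1, A2, A0 = theta
        R = A / (A + A1)
        L = _expit(A2 * (A + A0))
        LL = L * (1.0 - L)
        return np.column_stack([
            R * L,
            -Va * L * A / (A + A1) ** 2,
            Va * R * (A + A0) * LL,
            Va * R * A2 * LL,
        ])
    raise ValidationError(f"unknown family {family!r}")


_TINY = 1e-8


def _vel_bounds(family: str) -> Tuple[np.ndarray, np.ndarray]:
    inf = np.inf
    if family in ("inverse_linear", "exponential"):
        return np.array([_TINY, _TINY]), np.array([inf, inf])
    if family == "power_law":
        # exponent confined to (0, 1]: decelerating growth
        return np.array([_TINY, _TINY]), np.array([inf, 1.0])
    if family == "logistic":
        return np.array([_TINY, -inf, _TINY]), np.array([inf, inf, inf])
    if family == "il_logistic":
        return np.array([_TINY, 0.0, _TINY, -inf]), np.array([inf, inf, inf, inf])
    raise ValidationError(f"unknown family {family!r}")


def _vel_init(family: str, A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Scale-free starting values from data quantiles."""
    med_A = float(np.median(A))
    iqr = float(np.subtract(*np.percentile(A, [75, 25]))) or med_A or 1.0
    vmax = float(np.max(y))
    Va0 = 1.1 * vmax if vmax > 0 else 1.0
    if family == "inverse_linear":
        return np.array([Va0, med_A])
    if family == "exponential":
        return np.array([Va0, med_A])
    if family == "power_law":
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = float(np.median(y / np.sqrt(np.maximum(A, _TINY))))
        return np.array([max(scale, _TINY), 0.5])
    if family == "logistic":
        return np.array([Va0, med_A, 2.0 / iqr])
    if family == "il_logistic":
        return np.array([Va0, med_A / 2.0, 2.0 / iqr, -med_A])
    raise ValidationError(f"unknown family {family!r}")


def _finalize(family, names, res, A, y, model) -> FitResult:
    n = y.size
    k = res.x.size
    rss = float(2.0 * res.cost)
    model_df = n - k
    residual_se = math.sqrt(rss / model_df) if model_df > 0 else float("nan")
    J = res.jac
    s2 = rss / model_df if model_df > 0 else float("nan")
    JTJ = J.T @ J
    singular = False
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JTJ) * s2
        singular = True
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        tstats = np.where(se > 0, res.x / se, np.nan)
    if rss > 0:
        ll = gaussian_loglik(rss, n)
        aic = -2.0 * ll + 2.0 * (k + 1)
    else:
        ll = None
        aic = None
    return FitResult(
        family=family,
        param_names=tuple(names),
        estimates=res.x.copy(),
        standard_errors=se,
        t_stats=tstats,
        n=n,
        model_df=model_df,
        rss=rss,
        residual_se=residual_se,
        loglik=ll,
        aic=aic,
        model=model,
        success=bool(res.success),
        singular_jacobian=singular,
    )


def _least_squares_with_restarts(fun, jac, x0, bounds, seed, max_restarts, jitter_scale=0.3):
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    best = None
    x_start = np.clip(x0, lo + 0.0, hi)
    for attempt in range(max_restarts + 1):
        try:
            res = optimize.least_squares(
                fun, x_start, jac=jac, bounds=(lo, hi), method="trf",
                ftol=1e-10, xtol=1e-12, max_nfev=10_000,
            )
        except Exception:
            res = None
        if res is not None and (best is None or res.cost < best.cost):
            best = res
        if best is not None and best.success:
            # one extra jittered probe would only re-find the optimum on
            # well-posed problems; stop at first convergence
            break
        x_start = x0 * np.exp(rng.normal(0.0, jitter_scale, size=x0.size))
        x_start = x_start + rng.normal(0.0, jitter_scale * (np.abs(x0) + 1e-3))
        x_start = np.clip(x_start, np.where(np.isfinite(lo), lo + _TINY, x_start), np.where(np.isfinite(hi), hi, x_start))
    return best


def fit_velocity_model(
    A,
    Vp,
    family: str = "il_logistic",
    init: Optional[Sequence[float]] = None,
    seed: int = 0,
    max_restarts: int = 10,
) -> FitResult:
    """Fit one peak-velocity family to (amplitude, peak velocity) samples.

    Parameters
    ----------
    A, Vp : array-like
        Amplitudes (deg, > 0) and peak velocities (deg/s).
    family : str
        One of :data:`mainseq.models.FAMILIES`.
    init : sequence, optional
        Starting values in the family's parameter order; quantile-based
        heuristics are used when omitted.
    seed : int
        Seeds the jittered restarts used if the first start fails.
    max_restarts : int
        Restart budget before :class:`ConvergenceError` is raised (the
        error carries the best iterate found).
    """
    A = np.asarray(A, dtype=float).ravel()
    y = np.asarray(Vp, dtype=float).ravel()
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    names = FAMILY_PARAMS[family]
    if A.size != y.size:
        raise ValidationError("amplitude and velocity arrays differ in length")
    if A.size <= len(names):
        raise ValidationError(f"need more than {len(names)} samples to fit {family}")
    if np.any(A <= 0):
        raise ValidationError("amplitudes must be > 0 for fitting")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValidationError("samples must be finite")

    x0 = np.asarray(init, dtype=float) if init is not None else _vel_init(family, A, y)
    if x0.size != len(names):
        raise ValidationError(f"init must have {len(names)} entries for {family}")

    fun = lambda th: _vel_predict(family, th, A) - y
    jac = lambda th: _vel_jacobian(family, th, A)
    best = _least_squares_with_restarts(fun, jac, x0, _vel_bounds(family), seed, max_restarts)
    if best is None:
        raise ConvergenceError(f"{family} fit failed on every start", best_result=None)
    model = VelocityModelParams.from_vector(family, best.x)
    result = _finalize(family, names, best, A, y, model)
    if not best.success:
        raise ConvergenceError(
            f"{family} fit did not converge after {max_restarts} restarts", best_result=result
        )
    return result


def fit_linear(A, y) -> LinearFitResult:
    """Ordinary least squares ``y = a + b·A`` with F test, R² and AIC."""
    A = np.asarray(A, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = A.size
    if n < 3:
        raise ValidationError("need at least 3 samples for a linear fit")
    xbar, ybar = A.mean(), y.mean()
    sxx = float(np.sum((A - xbar) ** 2))
    if sxx == 0:
        raise ValidationError("degenerate design: all amplitudes identical")
    b = float(np.sum((A - xbar) * (y - ybar)) / sxx)
    a = ybar - b * xbar
    resid = y - (a + b * A)
    rss = float(resid @ resid)
    tss = float(np.sum((y - ybar) ** 2))
    df = n - 2
    s2 = rss / df if df > 0 else float("nan")
    se_b = math.sqrt(s2 / sxx)
    se_a = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    if rss > 0:
        f = (tss - rss) / s2
        fp = float(stats.f.sf(f, 1, df))
        aic = n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0) + 2 * 3
    else:
        f, fp, aic = math.inf, 0.0, -math.inf
    return LinearFitResult(
        a=a, b=b, se_a=se_a, se_b=se_b, f_stat=f, f_pvalue=fp,
        r_squared=r2, aic=aic, n=n, rss=rss,
        residual_se=math.sqrt(s2) if df > 0 else float("nan"),
    )


def fit_duration_models(
    A,
    MT,
    velocity_fit: FitResult,
    seed: int = 0,
    max_restarts: int = 10,
) -> Tuple[LinearFitResult, FitResult]:
    """Fit the affine and the inverse-linear logistic duration laws.

    The shape parameters ``Va, A0, A1, A2`` are frozen at the values of
    ``velocity_fit`` (which must be an il_logistic result); only the
    duration coefficients ``k0, k1, k2, K`` are optimized.  The linear fit
    is plain OLS.  Over the fitted amplitude range the logistic correction
    of the il_logistic form is usually negligible, so the two fits are
    expected to be nearly indistinguishable — that agreement is the point.
    """
    if velocity_fit.family != "il_logistic":
        raise ValidationError("duration fitting requires an il_logistic velocity fit")
    A = np.asarray(A, dtype=float).ravel()
    y = np.asarray(MT, dtype=float).ravel()
    if A.size != y.size:
        raise ValidationError("amplitude and duration arrays differ in length")
    if A.size <= 4:
        raise ValidationError("need more than 4 samples")
    vp: VelocityModelParams = velocity_fit.model
    Va, A0, A1, A2 = vp.Va, vp.A0, vp.A1, vp.A2

    linear = fit_linear(A, y)

    E = lambda th: np.exp(-th[2] * A2 * A)

    def predict(th):
        k0, k1, k2, K = th
        return (K / Va) * (A + k0 - A0) / (1.0 + k1 * A1 * np.exp(-k2 * A2 * A))

    def jacobian(th):
        k0, k1, k2, K = th
        e = np.exp(-k2 * A2 * A)
        D = 1.0 + k1 * A1 * e
        N = A + k0 - A0
        base = (K / Va)
        mt = base * N / D
        return np.column_stack([
            base / D,
            -base * N * A1 * e / D**2,
            base * N * k1 * A1 * e * A2 * A / D**2,
            mt / K,
        ])

    # start from the affine law: slope K/Va, intercept (K/Va)(k0 - A0)
    K0 = max(linear.b * Va, _TINY)
    k0_0 = linear.a / max(linear.b, _TINY) + A0
    x0 = np.array([k0_0, 1.0, 1.0, K0])
    lo = np.array([-np.inf, 0.0, _TINY, _TINY])
    hi = np.array([np.inf, np.inf, np.inf, np.inf])
    best = _least_squares_with_restarts(lambda th: predict(th) - y, jacobian, x0, (lo, hi), seed, max_restarts)
    if best is None:
        raise ConvergenceError("duration fit failed on every start", best_result=None)
    k0, k1, k2, K = best.x
    model = DurationILLogisticModel(Va=Va, A0=A0, A1=A1, A2=A2, k0=k0, k1=k1, k2=k2, K=K)
    result = _finalize("il_logistic_duration", ("k0", "k1", "k2", "K"), best, A, y, model)
    if not best.success:
        raise ConvergenceError("duration fit did not converge", best_result=result)
    return linear, result


def vuong_test(fit1, fit2, A, y) -> Tuple[float, float]:
    """Vuong's non-nested model comparison with the AIC-type correction.

    Pointwise log-likelihood ratios ``m_i`` are formed under Gaussian
    densities with each model's MLE variance ``rss/n``;

        ``z = (Σ m_i − (k1 − k2)) / (√n · sd(m_i))``

    Positive ``z`` favours ``fit1``; the p-value is two-sided normal.
    Identical pointwise likelihoods (``sd = 0``) mean the models are
    indistinguishable on these data and raise ``ValidationError``.
    """
    A = np.asarray(A, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValidationError("need at least 3 samples for Vuong's test")
    m = _pointwise_loglik(fit1, A, y) - _pointwise_loglik(fit2, A, y)
    sd = float(np.std(m, ddof=1))
    if sd == 0.0:
        if np.allclose(m, 0.0) and fit1.k == fit2.k:
            # identical fits (e.g. the same family refit on the same data)
            return 0.0, 1.0
        raise ValidationError("models are indistinguishable: identical pointwise likelihoods")
    z = (float(np.sum(m)) - (fit1.k - fit2.k)) / (math.sqrt(n) * sd)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def _pointwise_loglik(fit, A: np.ndarray, y: np.ndarray) -> np.ndarray:
    resid = y - fit.predict(A)
    s2 = fit.rss / fit.n
    if s2 <= 0:
        raise DegenerateLikelihoodError("zero-variance fit has no proper likelihood")
    return -0.5 * (math.log(2 * math.pi * s2) + resid**2 / s2)


def compare_models(
    A,
    Vp,
    families: Sequence[str] = FAMILIES[:3] + ("il_logistic",),
    seed: int = 0,
) -> ModelComparison:
    """Fit several families to the same samples and rank them.

    The base is the family with the smallest AIC (ties broken toward
    fewer parameters); each other row carries its ΔAIC and the Vuong test
    of base vs. that family (positive z favours the base).
    """
    A = np.asarray(A, dtype=float).ravel()
    y = np.asarray(Vp, dtype=float).ravel()
    fits: Dict[str, FitResult] = {}
    for fam in families:
        fits[fam] = fit_velocity_model(A, y, family=fam, seed=seed)
    for fam, fr in fits.items():
        if fr.aic is None:
            raise DegenerateLikelihoodError(f"{fam} fit has zero residuals; AIC undefined")
    base = min(fits, key=lambda f: (fits[f].aic, fits[f].k))
    base_aic = fits[base].aic
    rows = []
    for fam in sorted(fits, key=lambda f: (fits[f].aic, fits[f].k)):
        fr = fits[fam]
        row = {
            "family": fam,
            "residual_se": fr.residual_se,
            "model_df": fr.model_df,
            "aic": fr.aic,
            "delta_aic": fr.aic - base_aic,
            "vuong_z": float("nan"),
            "vuong_p": float("nan"),
        }
        if fam != base:
            z, p = vuong_test(fits[base], fr, A, y)
            row["vuong_z"] = z
            row["vuong_p"] = p
        rows.append(row)
    return ModelComparison(base_family=base, rows=rows, fits=fits)
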