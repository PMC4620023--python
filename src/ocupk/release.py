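"""Drug-release kinetics: model evaluation, fitting and mechanism classification.

Five classical dissolution models are supported, all expressed on the
*cumulative released* axis (percent of dose) so they are directly comparable
on one plot:

=====================  ==========================================================
``first_order``        Q(t) = Q0 * (1 - exp(-k1 t))          (released form; the
                       remaining form Q0 * exp(-k1 t) is also evaluable)
``higuchi``            Q(t) = kH * sqrt(t)
``baker_lonsdale``     Q(t) = Qinf * (1 - (6/pi^2) * exp(-kBL t)), the lumped
                       single-exponential matrix-diffusion form with
                       kBL = pi^2 D / r^2 (D and r are not separately
                       identifiable from release data)
``korsmeyer_peppas``   Q(t) = K * t^n, the one-term power law whose exponent n
                       diagnoses the release mechanism
``hixson_crowell``     Q(t) = Q0 - (Q0^(1/3) - kHC t)^3, the cube-root
                       erosion law (remaining clipped at zero)
=====================  ==========================================================

Two explicitly named alternatives are available but not part of the default
candidate set: ``baker_lonsdale_classical`` (the implicit form
3/2 [1-(1-Q/Qinf)^(2/3)] - Q/Qinf = k t, inverted numerically) and
``korsmeyer_peppas_two_term`` (Q = Q0 + a' t^n + b' t^(2n) with lumped
constants absorbing the particle radius).

Fitting is bounded nonlinear least squares with a deterministic linearised
initial guess plus a small fixed set of multiplicative multi-start
perturbations; goodness of fit is the plain coefficient of determination
R^2 = 1 - SSE/SST (no degrees-of-freedom correction), and candidate models
are ranked by descending R^2 with ties broken by fewer parameters.

The Korsmeyer-Peppas exponent classifies the mechanism for spherical
matrices: n < 0.45 Fickian diffusion, 0.45 <= n < 0.89 anomalous transport,
n ~= 0.89 case-II (relaxation-controlled), n > 0.89 super case-II.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .profiles import ReleaseProfile

__all__ = [
    "MODEL_PARAM_NAMES",
    "DEFAULT_MODELS",
    "MechanismThresholds",
    "MechanismLabel",
    "ReleaseFitResult",
    "ReleaseKinetics",
    "eval_model",
    "fit_model",
    "select_best_model",
    "classify_mechanism",
    "r_squared",
]

_PI2 = np.pi**2

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "first_order": ("q0", "k1"),
    "higuchi": ("k_h",),
    "baker_lonsdale": ("k_bl", "q_inf"),
    "baker_lonsdale_classical": ("k_bl", "q_inf"),
    "korsmeyer_peppas": ("k_kp", "n"),
    "korsmeyer_peppas_two_term": ("q0", "a", "b", "n"),
    "hixson_crowell": ("q0", "k_hc"),
}

#: candidate set used by default in model selection
DEFAULT_MODELS: tuple[str, ...] = (
    "first_order",
    "higuchi",
    "baker_lonsdale",
    "korsmeyer_peppas",
    "hixson_crowell",
)


def _check_params(model_name: str, params: dict) -> np.ndarray:
    if model_name not in MODEL_PARAM_NAMES:
        raise ValueError(f"unknown release model {model_name!r}")
    names = MODEL_PARAM_NAMES[model_name]
    missing = [p for p in names if p not in params]
    if missing:
        raise ValueError(f"{model_name}: missing constants {missing}")
    theta = np.array([float(params[p]) for p in names])
    if np.any(theta < 0):
        raise ValueError(f"{model_name}: constants must be >= 0")
    return theta


def _bl_classical_released(k: float, q_inf: float, t: np.ndarray) -> np.ndarray:
    # invert 3/2 [1-(1-x)^(2/3)] - x = k t for x = Q/Qinf on each t
    out = np.empty_like(t, dtype=float)
    for i, ti in enumerate(t):
        rhs = k * ti
        if rhs <= 0:
            out[i] = 0.0
            continue
        g = lambda x: 1.5 * (1.0 - (1.0 - x) ** (2.0 / 3.0)) - x - rhs
        if g(1.0 - 1e-12) <= 0:  # beyond complete release
            out[i] = 1.0
        else:
            out[i] = optimize.brentq(g, 0.0, 1.0 - 1e-12, xtol=1e-12)
    return q_inf * out


def eval_model(
    model_name: str,
    params: dict,
    times,
    *,
    form: str = "released",
) -> np.ndarray:
    """Evaluate a release model at the given times.

    Parameters
    ----------
    model_name : str
        One of :data:`MODEL_PARAM_NAMES`.
    params : dict
        Named constants for the model (see module docstring for names).
    times : array-like
        Times in hours, all >= 0.
    form : {"released", "remaining"}
        ``"released"`` (default) returns cumulative percent released.
        ``"remaining"`` returns percent remaining where meaningful
        (first-order and Hixson-Crowell laws are classically written on
        the remaining axis).
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    theta = _check_params(model_name, params)
    if form not in ("released", "remaining"):
        raise ValueError("form must be 'released' or 'remaining'")

    if model_name == "first_order":
        q0, k1 = theta
        remaining = q0 * np.exp(-k1 * t)
        released = q0 - remaining
    elif model_name == "higuchi":
        (k_h,) = theta
        released = k_h * np.sqrt(t)
        remaining = None
    elif model_name == "baker_lonsdale":
        k_bl, q_inf = theta
        released = q_inf * (1.0 - (6.0 / _PI2) * np.exp(-k_bl * t))
        remaining = None
    elif model_name == "baker_lonsdale_classical":
        k_bl, q_inf = theta
        released = _bl_classical_released(k_bl, q_inf, np.atleast_1d(t))
        released = released.reshape(np.shape(t))
        remaining = None
    elif model_name == "korsmeyer_peppas":
        k_kp, n = theta
        released = k_kp * np.power(t, n)
    elif model_name == "korsmeyer_peppas_two_term":
        q0, a, b, n = theta
        released = q0 + a * np.power(t, n) + b * np.power(t, 2.0 * n)
    else:  # hixson_crowell
        q0, k_hc = theta
        root = np.clip(np.cbrt(q0) - k_hc * t, 0.0, None)
        remaining = root**3
        released = q0 - remaining
    if form == "remaining":
        if model_name in ("first_order", "hixson_crowell"):
            return remaining
        raise ValueError(f"{model_name} has no 'remaining' form")
    return released


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, R^2 = 1 - SSE/SST (no dof correction)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("degenerate profile: all released values identical")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# mechanism classification


@dataclass(frozen=True)
class MechanismThresholds:
    """Cutoffs applied to the Korsmeyer-Peppas exponent (spheres)."""

    fickian_max: float = 0.45
    case_ii: float = 0.89
    tol: float = 1e-6


@dataclass(frozen=True)
class MechanismLabel:
    label: str
    n_value: float
    threshold_set: MechanismThresholds


def classify_mechanism(
    n_value: float, threshold_set: MechanismThresholds | None = None
) -> MechanismLabel:
    """Classify the release mechanism from the power-law exponent.

    Boundary handling is half-open: n in [fickian_max, case_ii) is
    anomalous, except for the narrow band |n - case_ii| <= tol which is
    labelled case-II transport.
    """
    ts = threshold_set or MechanismThresholds()
    n = float(n_value)
    if n <= 0:
        raise ValueError("release exponent must be positive")
    if abs(n - ts.case_ii) <= ts.tol:
        label = "case_II"
    elif n < ts.fickian_max:
        label = "fickian"
    elif n < ts.case_ii:
        label = "anomalous"
    else:
        label = "super_case_II"
    return MechanismLabel(label=label, n_value=n, threshold_set=ts)


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class ReleaseFitResult:
    """Outcome of fitting one model to one release profile."""

    model_name: str
    params: dict
    r_squared: float
    fit_window: tuple
    n_value: Optional[float] = None
    mechanism: Optional[MechanismLabel] = None
    converged: bool = True
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(MODEL_PARAM_NAMES[self.model_name])


def _initial_guess(model_name: str, t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Deterministic starting values from the model's classical linearisation."""
    qmax = float(np.max(q))
    if model_name == "first_order":
        q0 = min(max(qmax * 1.05, 1e-6), 110.0)
        frac = np.clip(1.0 - q / q0, 1e-9, None)
        slope = np.polyfit(t, np.log(frac), 1)[0]
        return np.array([q0, max(-slope, 1e-6)])
    if model_name == "higuchi":
        st = np.sqrt(t)
        denom = float(np.dot(st, st))
        k = float(np.dot(q, st)) / denom if denom > 0 else 1.0
        return np.array([max(k, 1e-6)])
    if model_name in ("baker_lonsdale", "baker_lonsdale_classical"):
        q_inf = max(qmax * 1.05, 1e-6)
        frac = np.clip((q_inf - q) / (q_inf * 6.0 / _PI2), 1e-9, None)
        slope = np.polyfit(t, np.log(frac), 1)[0]
        return np.array([max(-slope, 1e-6), q_inf])
    if model_name == "korsmeyer_peppas":
        mask = (t > 0) & (q > 0)
        if mask.sum() >= 2:
            n, logk = np.polyfit(np.log(t[mask]), np.log(q[mask]), 1)
            return np.array([max(np.exp(logk), 1e-6), max(n, 1e-3)])
        return np.array([max(qmax, 1.0), 0.5])
    if model_name == "korsmeyer_peppas_two_term":
        base = _initial_guess("korsmeyer_peppas", t, q)
        return np.array([max(q[0], 1e-3), base[0], 1e-3, base[1]])
    # hixson_crowell
    q0 = min(max(qmax * 1.05, 1e-6), 110.0)
    y = np.cbrt(q0) - np.cbrt(np.clip(q0 - q, 0.0, None))
    denom = float(np.dot(t, t))
    k = float(np.dot(y, t)) / denom if denom > 0 else 1e-3
    return np.array([q0, max(k, 1e-6)])


# fixed multiplicative multi-start perturbations (deterministic)
_START_FACTORS = np.array(
    [1.0, 0.5, 2.0, 0.25, 4.0]
)


class ReleaseKinetics(BaseEstimator, RegressorMixin):
    """Least-squares fit of one dissolution model to cumulative-release data.

    scikit-learn style estimator: ``fit(X, y)`` takes times in hours as
    ``X`` (shape ``(n,)`` or ``(n, 1)``) and cumulative percent released as
    ``y``; ``predict(X)`` evaluates the fitted curve.

    Parameters
    ----------
    model : str, default="korsmeyer_peppas"
        Model name; one of :data:`MODEL_PARAM_NAMES`.
    fit_window : tuple of (float, float), optional
        ``(t_min, t_max)`` restriction applied before fitting. For the
        power-law exponent the field convention is either the first 10 h of
        the dissolution run or the portion below 60 % release; the window
        expresses the first, the caller enforces the second.
    n_starts : int, default=5
        Number of multi-start perturbations around the linearised initial
        guess (deterministic multiplicative factors).

    Attributes
    ----------
    params_ : dict
        Fitted constants, named per model.
    r_squared_ : float
        1 - SSE/SST on the fitted window.
    n_value_ : float or None
        Release exponent (Korsmeyer-Peppas family only).
    mechanism_ : MechanismLabel or None
        Exponent-based mechanism classification, when ``n_value_`` exists.
    fit_window_ : tuple
        The (t_min, t_max) actually used.
    """

    def __init__(
        self,
        model: str = "korsmeyer_peppas",
        fit_window: Optional[tuple] = None,
        n_starts: int = 5,
        thresholds: Optional[MechanismThresholds] = None,
    ):
        self.model = model
        self.fit_window = fit_window
        self.n_starts = n_starts
        self.thresholds = thresholds

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _coerce_times(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be a 1-d array of times (or column vector)")
        return t

    def fit(self, X, y):
        if self.model not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown release model {self.model!r}")
        t = self._coerce_times(X)
        q = np.asarray(y, dtype=float).ravel()
        if t.size != q.size:
            raise ValueError("X and y length mismatch")
        names = MODEL_PARAM_NAMES[self.model]
        if self.fit_window is not None:
            lo, hi = self.fit_window
            mask = (t >= lo) & (t <= hi)
            t, q = t[mask], q[mask]
        window = (float(t.min()), float(t.max())) if t.size else (np.nan, np.nan)
        if t.size < max(3, len(names) + 1):
            raise ValueError(
                f"need at least {max(3, len(names) + 1)} points in the fit window"
            )
        if np.ptp(q) == 0:
            raise ValueError("degenerate profile: all released values identical")

        theta0 = _initial_guess(self.model, t, q)

        def resid(theta):
            pred = eval_model(self.model, dict(zip(names, theta)), t)
            return pred - q

        best = None
        errors = []
        for factor in _START_FACTORS[: max(1, self.n_starts)]:
            start = np.clip(theta0 * factor, 1e-9, None)
            try:
                sol = optimize.least_squares(
                    resid,
                    start,
                    bounds=(np.zeros_like(start), np.full_like(start, np.inf)),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception as exc:  # pragma: no cover - scipy internal
                errors.append(str(exc))
                continue
            if not sol.success:
                errors.append(sol.message)
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(
                f"{self.model}: no optimizer start converged ({'; '.join(errors)})"
            )

        self.params_ = dict(zip(names, best.x))
        self.r_squared_ = r_squared(q, eval_model(self.model, self.params_, t))
        self.fit_window_ = window
        self.n_value_ = (
            float(self.params_["n"]) if "n" in self.params_ else None
        )
        self.mechanism_ = (
            classify_mechanism(self.n_value_, self.thresholds)
            if self.n_value_ and self.n_value_ > 0
            else None
        )
        return self

    def predict(self, X):
        t = self._coerce_times(X)
        return eval_model(self.model, self.params_, t)

    def result_(self) -> ReleaseFitResult:
        """Package the fitted state as an immutable result record."""
        return ReleaseFitResult(
            model_name=self.model,
            params=dict(self.params_),
            r_squared=self.r_squared_,
            fit_window=self.fit_window_,
            n_value=self.n_value_,
            mechanism=self.mechanism_,
        )


def fit_model(
    profile: ReleaseProfile,
    model_name: str,
    fit_window: Optional[tuple] = None,
    **kwargs,
) -> ReleaseFitResult:
    """Fit one named model to a release profile; thin estimator wrapper."""
    est = ReleaseKinetics(model=model_name, fit_window=fit_window, **kwargs)
    est.fit(profile.times, profile.released)
    return est.result_()


def select_best_model(
    profile: ReleaseProfile,
    model_names: Sequence[str] = DEFAULT_MODELS,
    fit_window: Optional[tuple] = None,
    **kwargs,
) -> list[ReleaseFitResult]:
    """Fit every candidate model and rank by descending R^2.

    Ties (within 1e-12) are broken in favour of fewer parameters. Models
    whose fit fails are returned at the end of the list as non-converged
    entries carrying the failure reason.
    """
    if len(model_names) < 1:
        raise ValueError("need at least one candidate model")
    fitted, failed = [], []
    for name in model_names:
        try:
            fitted.append(fit_model(profile, name, fit_window, **kwargs))
        except Exception as exc:
            failed.append(
                ReleaseFitResult(
                    model_name=name,
                    params={},
                    r_squared=float("-inf"),
                    fit_window=fit_window or (np.nan, np.nan),
                    converged=False,
                    message=str(exc),
                )
            )
    fitted.sort(key=lambda r: (-round(r.r_squared, 12), r.n_params))
    return fitted + failed
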