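"""One-compartment open model with first-order absorption (Bateman curve).

The concentration-time course after a single topical instillation is

    C(t) = A * (exp(-Ke * t) - exp(-Ka * t)),     Ka != Ke,

with apparent absorption rate Ka (1/h), terminal elimination rate Ke (1/h)
and amplitude A (ug/mL).  Closed forms used throughout:

    Tmax  = ln(Ka/Ke) / (Ka - Ke)
    Cmax  = C(Tmax)
    t1/2  = ln 2 / Ke
    AUC0-inf = A * (1/Ke - 1/Ka)

When Ka == Ke the curve degenerates to the limit A' * t * exp(-Ke t); we use
the reparameterisation C(t) = A * Ke * t * exp(-Ke t) (so A keeps
concentration units) and Tmax = 1/Ke.

Estimation mirrors the standard two-stage approach for sparse ocular data:
the terminal slope of ln C vs t over the last few positive samples gives Ke,
the method of residuals ("feathering") on pre-peak points seeds Ka, and a
bounded nonlinear least-squares fit refines (A, Ka, Ke) jointly.  A fitted
Ka < Ke is flip-flop kinetics; it is flagged, never silently swapped.

``calibrate_from_summary`` reconstructs the full curve from a published
(Ka, Ke, Cmax) triple, which is what lets MIC-anchored indices and dosing
simulations be recomputed when only summary tables are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .profiles import ConcProfile

__all__ = [
    "OneCompartmentFit",
    "BatemanPK",
    "bateman_conc",
    "tmax_cmax",
    "calibrate_from_summary",
    "fit_terminal_ke",
    "fit_bateman",
    "bateman_auc",
]

_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class OneCompartmentFit:
    """Fitted (or reconstructed) Bateman parameter set with derived PK."""

    ka: float
    ke: float
    amplitude: float
    terminal_points_used: int = 0
    terminal_r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0 or self.amplitude < 0:
            raise ValueError("ka, ke must be > 0 and amplitude >= 0")

    @property
    def flip_flop(self) -> bool:
        """True when absorption is slower than elimination (Ka < Ke)."""
        return self.ka < self.ke

    @property
    def degenerate(self) -> bool:
        return math.isclose(self.ka, self.ke, rel_tol=_DEGENERATE_RTOL)

    @property
    def tmax(self) -> float:
        if self.degenerate:
            return 1.0 / self.ke
        return math.log(self.ka / self.ke) / (self.ka - self.ke)

    @property
    def cmax(self) -> float:
        return float(bateman_conc(self, self.tmax))

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.ke

    @property
    def auc_inf(self) -> float:
        """Analytic AUC from zero to infinity."""
        if self.degenerate:
            return self.amplitude / self.ke
        return self.amplitude * (1.0 / self.ke - 1.0 / self.ka)


def bateman_conc(fit: OneCompartmentFit, t) -> np.ndarray:
    """Concentration at time(s) ``t`` (hours) for a single dose at t=0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if fit.degenerate:
        return fit.amplitude * fit.ke * t * np.exp(-fit.ke * t)
    return fit.amplitude * (np.exp(-fit.ke * t) - np.exp(-fit.ka * t))


def tmax_cmax(ka: float, ke: float, amplitude: float) -> tuple[float, float]:
    """Peak time and peak concentration of the Bateman curve."""
    fit = OneCompartmentFit(ka=ka, ke=ke, amplitude=amplitude)
    return fit.tmax, fit.cmax


def calibrate_from_summary(ka: float, ke: float, cmax: float) -> OneCompartmentFit:
    """Reconstruct the Bateman curve behind a published (Ka, Ke, Cmax) triple.

    Solves for the amplitude A such that the curve's analytic peak equals
    ``cmax`` exactly:  A = Cmax / (exp(-Ke*Tmax) - exp(-Ka*Tmax)).
    """
    if ka <= 0 or ke <= 0 or cmax < 0:
        raise ValueError("ka, ke must be > 0 and cmax >= 0")
    probe = OneCompartmentFit(ka=ka, ke=ke, amplitude=1.0)
    shape_peak = probe.cmax  # peak of the unit-amplitude curve
    return OneCompartmentFit(ka=ka, ke=ke, amplitude=cmax / shape_peak)


def bateman_auc(fit: OneCompartmentFit, t0: float, t1: float) -> float:
    """Analytic area under the single-dose curve on [t0, t1]."""
    if t1 < t0 or t0 < 0:
        raise ValueError("need 0 <= t0 <= t1")
    if fit.degenerate:
        ke = fit.ke

        def F(t):  # antiderivative of ke*t*exp(-ke t)
            return -(t + 1.0 / ke) * math.exp(-ke * t)

        return fit.amplitude * (F(t1) - F(t0))
    ka, ke, A = fit.ka, fit.ke, fit.amplitude
    return A * (
        (math.exp(-ke * t0) - math.exp(-ke * t1)) / ke
        - (math.exp(-ka * t0) - math.exp(-ka * t1)) / ka
    )


def fit_terminal_ke(
    profile: ConcProfile, n_terminal: int = 3
) -> tuple[float, float, int]:
    """Elimination rate from the terminal log-linear slope.

    Regresses ln(C) on t over the last ``n_terminal`` strictly positive
    concentrations. Returns ``(ke, r_squared, n_used)``. A non-negative
    slope (concentrations not declining) raises, since the window then does
    not represent a terminal phase.
    """
    if n_terminal < 2:
        raise ValueError("n_terminal must be >= 2")
    mask = profile.concentrations > 0
    t = profile.times[mask]
    c = profile.concentrations[mask]
    if t.size < 2:
        raise ValueError("need >= 2 strictly positive terminal concentrations")
    n_used = min(n_terminal, t.size)
    t, c = t[-n_used:], c[-n_used:]
    logc = np.log(c)
    slope, intercept = np.polyfit(t, logc, 1)
    pred = slope * t + intercept
    sst = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum((logc - pred) ** 2)) / sst
    if slope >= 0:
        raise ValueError("non-terminal phase: terminal concentrations not declining")
    return -slope, r2, n_used


def _feather_ka(profile: ConcProfile, ke: float, a0: float) -> float | None:
    """Method-of-residuals Ka seed from pre-peak points; None when it fails."""
    i_peak = int(np.argmax(profile.concentrations))
    t = profile.times[:i_peak]
    c = profile.concentrations[:i_peak]
    resid = a0 * np.exp(-ke * t) - c
    mask = resid > 0
    if mask.sum() < 2:
        return None
    slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
    return -slope if slope < 0 else None


class BatemanPK(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares Bateman fit to a concentration-time profile.

    ``fit(X, y)`` takes times (hours) and concentrations (ug/mL); replicate
    measurements should be averaged per time point beforehand (see
    :func:`ocupk.synthetic.pool_replicates`), matching the naive pooled-mean
    analysis level of destructive-sampling designs.

    Parameters
    ----------
    n_terminal : int, default=3
        Points in the terminal log-linear window seeding Ke (the last
        ``n_terminal`` positive concentrations).

    Attributes
    ----------
    ka_, ke_, amplitude_ : float
        Fitted Bateman parameters.
    tmax_, cmax_, t_half_ : float
        Derived peak time, peak concentration and terminal half-life.
    flip_flop_ : bool
        True when the fitted Ka < Ke.
    fit_ : OneCompartmentFit
        The full fitted record.
    """

    def __init__(self, n_terminal: int = 3):
        self.n_terminal = n_terminal

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        c = np.asarray(y, dtype=float).ravel()
        if t.size != c.size:
            raise ValueError("X and y length mismatch")
        if t.size < 4:
            raise ValueError("need >= 4 time points spanning both phases")
        if np.all(c <= 0):
            raise ValueError("all-zero profile")
        order = np.argsort(t)
        t, c = t[order], c[order]
        profile = ConcProfile(times=t, concentrations=np.clip(c, 0, None))

        ke0, term_r2, n_used = fit_terminal_ke(profile, self.n_terminal)
        # back-extrapolated terminal intercept seeds the amplitude
        pos = profile.concentrations > 0
        tp, cp = t[pos][-n_used:], c[pos][-n_used:]
        a0 = float(np.exp(np.polyfit(tp, np.log(cp), 1)[1]))
        ka0 = _feather_ka(profile, ke0, a0)
        if ka0 is None or ka0 <= ke0:
            ka0 = 5.0 * ke0  # feathering fallback

        def resid(theta):
            a, ka, ke = theta
            return a * (np.exp(-ke * t) - np.exp(-ka * t)) - c

        sol = optimize.least_squares(
            resid,
            np.array([max(a0, c.max()), ka0, ke0]),
            bounds=([0.0, 1e-9, 1e-9], [np.inf] * 3),
            xtol=1e-13,
            ftol=1e-13,
            gtol=1e-13,
        )
        if not sol.success:
            raise RuntimeError(f"Bateman fit did not converge: {sol.message}")
        a, ka, ke = sol.x
        self.fit_ = OneCompartmentFit(
            ka=ka,
            ke=ke,
            amplitude=a,
            terminal_points_used=n_used,
            terminal_r_squared=term_r2,
        )
        self.ka_, self.ke_, self.amplitude_ = ka, ke, a
        self.tmax_ = self.fit_.tmax
        self.cmax_ = self.fit_.cmax
        self.t_half_ = self.fit_.t_half
        self.flip_flop_ = self.fit_.flip_flop
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return bateman_conc(self.fit_, t)


def fit_bateman(profile: ConcProfile, n_terminal: int = 3) -> OneCompartmentFit:
    """Fit the Bateman curve to a pooled-mean profile; estimator wrapper."""
    est = BatemanPK(n_terminal=n_terminal)
    est.fit(profile.times, profile.concentrations)
    return est.fit_
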