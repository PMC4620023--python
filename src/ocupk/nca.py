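"""Non-compartmental analysis: trapezoidal AUC, tail extrapolation, Frel.

The exposure metrics follow the conventional sparse-sampling workflow:
AUC over the observed window by the linear trapezoidal rule (with linear
interpolation at window cut points), extrapolation to infinity by adding
Clast/Ke, and relative bioavailability as the dose-normalised AUC ratio of
a test formulation against a reference solution.

For topically instilled drug a virtual (0 h, 0 ug/mL) anchor is prepended
by default — no drug is present in aqueous humor before the drop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import ConcProfile

__all__ = [
    "NCAResult",
    "trapezoidal_auc",
    "extrapolate_auc_inf",
    "relative_bioavailability",
    "run_nca",
]


@dataclass(frozen=True)
class NCAResult:
    auc_0_tlast: float
    auc_0_inf: float
    clast: float
    tlast: float
    cmax_obs: float
    tmax_obs: float
    extrapolated_fraction: float

    def __post_init__(self) -> None:
        if not (self.auc_0_inf >= self.auc_0_tlast >= 0):
            raise ValueError("require auc_0_inf >= auc_0_tlast >= 0")
        if not (0 <= self.extrapolated_fraction < 1):
            raise ValueError("extrapolated fraction must be in [0, 1)")


def _anchored(profile: ConcProfile, anchor_zero: bool) -> tuple[np.ndarray, np.ndarray]:
    t, c = profile.times, profile.concentrations
    if anchor_zero and t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    return t, c


def trapezoidal_auc(
    profile: ConcProfile,
    t_start: float,
    t_end: float,
    *,
    anchor_zero: bool = True,
) -> float:
    """Linear trapezoidal AUC of the observed profile on [t_start, t_end].

    The window must lie within the observed range (after the optional
    virtual zero anchor); cut points interior to a sampling interval are
    handled by linear interpolation, which makes the rule additive over
    adjacent windows.
    """
    if t_end < t_start:
        raise ValueError("empty window: t_end < t_start")
    t, c = _anchored(profile, anchor_zero)
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError(
            f"window [{t_start}, {t_end}] outside observed range [{t[0]}, {t[-1]}]"
        )
    # close the window with interpolated cut points
    grid = np.unique(np.concatenate([t[(t > t_start) & (t < t_end)], [t_start, t_end]]))
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def extrapolate_auc_inf(auc_0_tlast: float, clast: float, ke: float) -> float:
    """AUC to infinity: observed area plus the log-linear tail Clast/Ke."""
    if ke <= 0:
        raise ValueError("ke must be > 0")
    if clast < 0 or auc_0_tlast < 0:
        raise ValueError("clast and auc_0_tlast must be >= 0")
    return auc_0_tlast + clast / ke


def relative_bioavailability(
    auc_test: float, dose_test: float, auc_ref: float, dose_ref: float
) -> float:
    """Dose-normalised AUC ratio (AUC_test x Dose_ref)/(AUC_ref x Dose_test)."""
    if min(auc_test, dose_test, auc_ref, dose_ref) <= 0:
        raise ValueError("all AUCs and doses must be > 0")
    return (auc_test * dose_ref) / (auc_ref * dose_test)


def run_nca(
    profile: ConcProfile,
    ke: float,
    *,
    clast: float | None = None,
    anchor_zero: bool = True,
) -> NCAResult:
    """Full NCA of one observed profile.

    ``clast`` defaults to the last observed positive concentration; passing
    a model-predicted value instead reproduces summary-table extrapolations
    when the observed tail concentration is unavailable.
    """
    t, c = _anchored(profile, anchor_zero)
    pos = np.nonzero(c > 0)[0]
    if pos.size == 0:
        raise ValueError("profile has no positive concentrations")
    tlast = float(t[pos[-1]])
    auc_tlast = trapezoidal_auc(profile, t[0], tlast, anchor_zero=anchor_zero)
    c_last = float(c[pos[-1]]) if clast is None else float(clast)
    auc_inf = extrapolate_auc_inf(auc_tlast, c_last, ke)
    i_max = int(np.argmax(c))
    frac = 0.0 if auc_inf == 0 else (auc_inf - auc_tlast) / auc_inf
    return NCAResult(
        auc_0_tlast=auc_tlast,
        auc_0_inf=auc_inf,
        clast=c_last,
        tlast=tlast,
        cmax_obs=float(c[i_max]),
        tmax_obs=float(t[i_max]),
        extrapolated_fraction=frac,
    )
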