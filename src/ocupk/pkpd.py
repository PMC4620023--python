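"""MIC-anchored PK/PD indices and the dosing-interval rule.

For a concentration-dependent antiviral the clinically used indices are
Cmax/MIC90, AUC0-24/MIC90, the area of the curve above the MIC, and the
time the curve stays above the MIC.  The dosing interval tau is chosen as
the post-peak time at which the single-dose curve falls to k x MIC90
(default k = 2, i.e. redose while the aqueous-humor level is still held at
twice the MIC90); under linear PK, redosing every tau then keeps the
multi-dose trough at or above that threshold.

The Bateman curve is unimodal, so any level below Cmax is crossed exactly
once on the way up and once on the way down; crossings are located by
bracketing + bisection (scipy brentq) to 1e-6 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .bateman import OneCompartmentFit, bateman_auc, bateman_conc

__all__ = [
    "PkPdReport",
    "mic_ratios",
    "crossing_times",
    "time_above_threshold",
    "auc_above_threshold",
    "dosing_interval",
    "build_report",
]

_XTOL = 1e-6  # h, bisection tolerance for level crossings

# conventional efficacy breakpoints for concentration-dependent agents
CMAX_MIC_BREAKPOINT = 10.0
AUC_MIC_BREAKPOINT = 125.0


@dataclass(frozen=True)
class PkPdReport:
    """Table of MIC-anchored indices for one treatment arm.

    ``provenance`` records, per index, whether it came from printed summary
    arithmetic ("summary") or from the reconstructed/fitted curve ("curve").
    """

    arm: str
    mic90: float
    threshold_multiplier: float
    cmax_over_mic: float
    auc24_over_mic: float
    auc_above_mic: float
    t_above_mic: float
    t_above_k_mic: float
    dosing_interval_tau: Optional[float]
    cmax_mic_breakpoint_met: bool
    auc_mic_breakpoint_met: bool
    provenance: dict


def mic_ratios(cmax: float, auc_0_24: float, mic90: float) -> tuple[float, float]:
    """(Cmax/MIC90, AUC0-24/MIC90); plain arithmetic on summary values."""
    if mic90 <= 0:
        raise ValueError("mic90 must be > 0")
    return cmax / mic90, auc_0_24 / mic90


def crossing_times(
    fit: OneCompartmentFit, threshold: float
) -> tuple[float, float] | None:
    """Up- and down-crossing times of a level on the single-dose curve.

    Returns ``None`` when the level is never reached (threshold >= Cmax).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    tmax, cmax = fit.tmax, fit.cmax
    if threshold >= cmax:
        return None
    f = lambda t: float(bateman_conc(fit, t)) - threshold
    t_up = optimize.brentq(f, 0.0, tmax, xtol=_XTOL) if f(0.0) < 0 else 0.0
    hi = tmax
    step = max(fit.t_half, 1.0)
    while f(hi + step) > 0:  # expand bracket past the down-crossing
        hi += step
        step *= 2.0
    t_down = optimize.brentq(f, hi, hi + step, xtol=_XTOL)
    return t_up, t_down


def time_above_threshold(
    fit: OneCompartmentFit, threshold: float, window: tuple[float, float] = (0.0, 24.0)
) -> float:
    """Total time within ``window`` that C(t) exceeds ``threshold`` (hours).

    Returns 0 when the threshold is never reached.
    """
    t0, t1 = window
    if t1 < t0 or t0 < 0:
        raise ValueError("invalid window")
    cross = crossing_times(fit, threshold)
    if cross is None:
        return 0.0
    t_up, t_down = cross
    return max(0.0, min(t_down, t1) - max(t_up, t0))


def auc_above_threshold(
    fit: OneCompartmentFit,
    threshold: float,
    window: tuple[float, float] = (0.0, 24.0),
    *,
    rtol: float = 1e-6,
) -> float:
    """Area of the curve above ``threshold`` within ``window`` (h*ug/mL).

    Integrates max(C(t) - threshold, 0) by composite trapezoid on a grid
    doubled until two successive estimates agree to ``rtol`` relative.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    t0, t1 = window
    if t1 < t0 or t0 < 0:
        raise ValueError("invalid window")
    if t1 == t0:
        return 0.0
    prev = None
    n = 1024
    for _ in range(14):
        grid = np.linspace(t0, t1, n + 1)
        vals = np.clip(bateman_conc(fit, grid) - threshold, 0.0, None)
        est = float(np.trapezoid(vals, grid))
        if prev is not None and abs(est - prev) <= rtol * max(abs(est), 1e-30):
            return est
        prev = est
        n *= 2
    return est


def dosing_interval(
    fit: OneCompartmentFit, mic90: float, k: float = 2.0, t_min: float = 0.0
) -> float:
    """Dosing interval tau: post-peak down-crossing time of k x MIC90.

    Raises when the threshold is never reached (k*mic90 >= Cmax).  ``t_min``
    lets the caller impose a floor on the interval (e.g. a practical minimum
    between instillations); the returned tau is max(down-crossing, t_min).
    """
    if mic90 <= 0 or k <= 0:
        raise ValueError("mic90 and k must be > 0")
    cross = crossing_times(fit, k * mic90)
    if cross is None:
        raise ValueError(
            f"threshold {k * mic90:g} never reached (Cmax = {fit.cmax:g})"
        )
    return max(cross[1], t_min)


def build_report(
    arm: str,
    fit: OneCompartmentFit,
    mic90: float,
    *,
    k: float = 2.0,
    window: tuple[float, float] = (0.0, 24.0),
    cmax: float | None = None,
    auc_0_24: float | None = None,
) -> PkPdReport:
    """Assemble the full index table for one arm.

    When printed summary values ``cmax``/``auc_0_24`` are given, the ratio
    rows use them directly (pure arithmetic) and are labelled "summary";
    otherwise the reconstructed curve supplies them and rows are labelled
    "curve".  Curve-dependent indices (areas/times above threshold, tau)
    always come from ``fit``.
    """
    prov = {}
    if cmax is None:
        cmax = fit.cmax
        prov["cmax_over_mic"] = "curve"
    else:
        prov["cmax_over_mic"] = "summary"
    if auc_0_24 is None:
        auc_0_24 = bateman_auc(fit, window[0], window[1])
        prov["auc24_over_mic"] = "curve"
    else:
        prov["auc24_over_mic"] = "summary"
    cm_ratio, auc_ratio = mic_ratios(cmax, auc_0_24, mic90)
    prov.update(
        auc_above_mic="curve", t_above_mic="curve", dosing_interval_tau="curve"
    )
    try:
        tau = dosing_interval(fit, mic90, k)
    except ValueError:
        tau = None
    # duration indices are not clipped to the 24-h AUC window: the curve can
    # stay above the MIC past the last sampling time
    open_window = (0.0, max(window[1], 10.0 * fit.t_half))
    return PkPdReport(
        arm=arm,
        mic90=mic90,
        threshold_multiplier=k,
        cmax_over_mic=cm_ratio,
        auc24_over_mic=auc_ratio,
        auc_above_mic=auc_above_threshold(fit, mic90, window),
        t_above_mic=time_above_threshold(fit, mic90, window=open_window),
        t_above_k_mic=time_above_threshold(fit, k * mic90, window=open_window),
        dosing_interval_tau=tau,
        cmax_mic_breakpoint_met=cm_ratio > CMAX_MIC_BREAKPOINT,
        auc_mic_breakpoint_met=auc_ratio > AUC_MIC_BREAKPOINT,
        provenance=prov,
    )
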