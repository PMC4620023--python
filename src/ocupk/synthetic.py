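"""Synthetic data with the statistical structure the analysis assumes.

No raw measurements accompany the study this package re-analyses, so every
pipeline stage is exercised on generated data:

* concentration-time data emulating destructive ocular sampling — at each
  scheduled time a few independent eyes are measured once, so replicates
  are cross-sectional and independent across time points.  Noise is
  multiplicative lognormal (assay coefficients of variation are
  proportional to the level), mean-preserving, with values below the assay
  LLOQ censored to zero;
* cumulative-release data — additive Gaussian noise in percent units on a
  chosen truth model, clipped to [0, 100] and projected onto the
  non-decreasing cone (isotonic regression), since cumulative release
  cannot decrease.

The default in vivo schedule is the ten-point post-instillation design
0.5, 1, 1.5, 2, 3, 4, 5, 6, 12, 24 h with three eyes per point; the default
in vitro schedule is hourly sampling over 12 h.  A "biphasic_burst" release
preset mimics the characteristic microsphere profile: a fast burst of
about half the dose within minutes, then a slow power-law rise towards a
~90 % plateau at 12 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .bateman import OneCompartmentFit, bateman_conc
from .profiles import ConcProfile, ReleaseProfile
from .release import eval_model

__all__ = [
    "IN_VIVO_SAMPLE_TIMES",
    "IN_VITRO_SAMPLE_TIMES",
    "SyntheticConfig",
    "gen_conc_data",
    "gen_release_data",
    "biphasic_burst",
    "pool_replicates",
]

#: post-instillation aqueous-humor sampling schedule (hours)
IN_VIVO_SAMPLE_TIMES: tuple[float, ...] = (0.5, 1, 1.5, 2, 3, 4, 5, 6, 12, 24)
#: hourly Franz-cell sampling schedule (hours)
IN_VITRO_SAMPLE_TIMES: tuple[float, ...] = tuple(float(h) for h in range(1, 13))


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to generate one dataset reproducibly.

    ``truth_model`` is either ``"bateman"`` (concentration data; params
    ka, ke, amplitude), one of the release model names, or
    ``"biphasic_burst"`` (params burst_pct, plateau_pct, burst_tau_h,
    tail_exponent).  ``noise_model`` is ``"multiplicative_lognormal"``
    (parameter ``cv``) or ``"additive_gaussian"`` (parameter ``sd`` in
    profile units).  The seed fixes all randomness end to end.
    """

    seed: int
    truth_model: str
    truth_params: dict
    sample_times: tuple = IN_VIVO_SAMPLE_TIMES
    n_replicates: int = 3
    noise_model: str = "multiplicative_lognormal"
    cv: float = 0.10
    sd: float = 2.0
    lloq: float = 0.05  # ug/mL, assay lower limit of quantification
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.sample_times) == 0:
            raise ValueError("sample_times must be non-empty")
        if self.cv < 0 or self.sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def pool_replicates(times, replicate_matrix, *, arm: str = "", lloq: float = 0.0) -> ConcProfile:
    """Average replicate eyes per time point into a mean profile."""
    reps = np.asarray(replicate_matrix, dtype=float)
    means = reps.mean(axis=1)
    return ConcProfile(
        times=np.asarray(times, dtype=float),
        concentrations=means,
        n_per_point=reps.shape[1],
        arm=arm,
        replicates=tuple(map(tuple, reps)),
        lloq_censored=np.any(reps <= lloq, axis=1) if lloq > 0 else None,
    )


def gen_conc_data(config: SyntheticConfig) -> ConcProfile:
    """Destructive-sampling concentration data around a Bateman truth curve.

    Each scheduled time receives ``n_replicates`` independent noisy draws.
    With the lognormal model the noise is mean-preserving:
    C_obs = C_true * exp(sigma Z - sigma^2/2), sigma^2 = ln(1 + CV^2).
    Draws below the LLOQ are censored to zero and flagged.  Returns the
    pooled-mean :class:`ConcProfile` with the raw replicates attached.
    """
    if config.truth_model != "bateman":
        raise ValueError("gen_conc_data needs truth_model='bateman'")
    try:
        fit = OneCompartmentFit(**config.truth_params)
    except TypeError as exc:
        raise ValueError(f"invalid Bateman truth parameters: {exc}") from exc
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times, dtype=float)
    truth = bateman_conc(fit, times)
    n = config.n_replicates
    if config.noise_model == "multiplicative_lognormal":
        if config.cv == 0:
            reps = np.repeat(truth[:, None], n, axis=1)
        else:
            sigma = np.sqrt(np.log1p(config.cv**2))
            z = rng.standard_normal((times.size, n))
            reps = truth[:, None] * np.exp(sigma * z - 0.5 * sigma**2)
    elif config.noise_model == "additive_gaussian":
        reps = truth[:, None] + config.sd * rng.standard_normal((times.size, n))
        reps = np.clip(reps, 0.0, None)
    else:
        raise ValueError(f"unknown noise model {config.noise_model!r}")
    reps[reps < config.lloq] = 0.0
    return pool_replicates(times, reps, arm=config.label, lloq=config.lloq)


def biphasic_burst(
    times,
    burst_pct: float = 50.0,
    plateau_pct: float = 90.0,
    burst_tau_h: float = 0.05,
    tail_exponent: float = 0.8,
    t_end: float = 12.0,
) -> np.ndarray:
    """Burst-then-slow-rise release truth curve.

    A saturating burst of ``burst_pct`` with time constant ``burst_tau_h``
    (minutes-scale) plus a power-law tail reaching ``plateau_pct`` at
    ``t_end``.
    """
    t = np.asarray(times, dtype=float)
    tail = (plateau_pct - burst_pct) * np.power(np.clip(t / t_end, 0, None), tail_exponent)
    return burst_pct * (1.0 - np.exp(-t / burst_tau_h)) + tail


def gen_release_data(config: SyntheticConfig) -> ReleaseProfile:
    """Noisy cumulative-release profile from a truth model or preset.

    Additive Gaussian noise (sd in percent units) on the truth curve,
    clipped to [0, 100], then projected onto the closest non-decreasing
    sequence by isotonic regression so the output is a valid cumulative
    profile.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times, dtype=float)
    if config.truth_model == "biphasic_burst":
        truth = biphasic_burst(times, **config.truth_params)
    else:
        truth = eval_model(config.truth_model, config.truth_params, times)
    if config.noise_model == "additive_gaussian":
        noisy = truth + config.sd * rng.standard_normal(times.size)
    elif config.noise_model == "multiplicative_lognormal":
        if config.cv == 0:
            noisy = truth.copy()
        else:
            sigma = np.sqrt(np.log1p(config.cv**2))
            noisy = truth * np.exp(
                sigma * rng.standard_normal(times.size) - 0.5 * sigma**2
            )
    else:
        raise ValueError(f"unknown noise model {config.noise_model!r}")
    noisy = np.clip(noisy, 0.0, 100.0)
    iso = IsotonicRegression(y_min=0.0, y_max=100.0, increasing=True)
    projected = iso.fit_transform(times, noisy)
    return ReleaseProfile(times=times, released=projected, label=config.label)
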