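"""Superposition simulation of repeated instillation.

Linear pharmacokinetics means the multi-dose concentration profile is the
pointwise sum of time-shifted copies of the single-dose Bateman curve:

    C_total(t) = sum over dose times d <= t of C_single(t - d).

Doses fall at {0, tau, 2*tau, ...} intersected with the half-open horizon
[0, horizon): an instillation scheduled exactly at the horizon is not
counted.  Equal dose amounts are assumed at every instillation (the same
drop volume and strength is re-instilled); per-dose scale factors are
available for sensitivity exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bateman import OneCompartmentFit, bateman_conc

__all__ = [
    "DosingRegimen",
    "DosingSimulation",
    "count_instillations",
    "dose_times",
    "superpose",
]


def count_instillations(tau: float, horizon: float) -> int:
    """Number of doses at {0, tau, 2 tau, ...} strictly before ``horizon``."""
    if tau <= 0 or horizon <= 0:
        raise ValueError("tau and horizon must be > 0")
    # guard float noise so an exact multiple stays excluded (half-open window)
    return int(math.ceil(round(horizon / tau, 9)))


def dose_times(tau: float, horizon: float) -> np.ndarray:
    return tau * np.arange(count_instillations(tau, horizon), dtype=float)


@dataclass(frozen=True)
class DosingRegimen:
    """Evenly spaced instillations over a simulation horizon."""

    tau: float
    horizon: float
    dose_scale: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.horizon <= 0:
            raise ValueError("tau and horizon must be > 0")
        n = count_instillations(self.tau, self.horizon)
        if self.dose_scale is not None and len(self.dose_scale) != n:
            raise ValueError(f"dose_scale must have {n} entries")

    @property
    def dose_times(self) -> np.ndarray:
        return dose_times(self.tau, self.horizon)

    @property
    def n_instillations(self) -> int:
        return self.dose_times.size


@dataclass(frozen=True)
class DosingSimulation:
    grid_times: np.ndarray
    total_conc: np.ndarray
    n_instillations: int
    trough_concs: np.ndarray  # concentration just before each redose
    time_above_mic_total: float
    mic_threshold: float


def superpose(
    fit: OneCompartmentFit,
    regimen: DosingRegimen,
    grid_step: float = 0.01,
    *,
    mic_threshold: float = 0.0,
) -> DosingSimulation:
    """Build the multi-dose profile by superposition on a uniform grid.

    ``trough_concs`` holds the total concentration at ``d - grid_step`` for
    every dose time ``d > 0`` (the level just before each re-instillation).
    ``time_above_mic_total`` is the grid measure of
    {t : C_total(t) > mic_threshold} (0 when no threshold is given).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    grid = np.arange(0.0, regimen.horizon + 0.5 * grid_step, grid_step)
    total = np.zeros_like(grid)
    scales = (
        np.ones(regimen.n_instillations)
        if regimen.dose_scale is None
        else np.asarray(regimen.dose_scale, dtype=float)
    )
    for d, s in zip(regimen.dose_times, scales):
        mask = grid >= d
        total[mask] += s * bateman_conc(fit, grid[mask] - d)
    troughs = np.array(
        [
            np.interp(d - grid_step, grid, total)
            for d in regimen.dose_times[1:]
        ]
    )
    t_above = (
        float(np.count_nonzero(total > mic_threshold)) * grid_step
        if mic_threshold > 0
        else 0.0
    )
    return DosingSimulation(
        grid_times=grid,
        total_conc=total,
        n_instillations=regimen.n_instillations,
        trough_concs=troughs,
        time_above_mic_total=t_above,
        mic_threshold=mic_threshold,
    )
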