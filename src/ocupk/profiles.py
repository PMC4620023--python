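"""Validated in-memory containers for release and concentration data.

Two kinds of raw measurement flow through the pipeline:

* in vitro dissolution data — cumulative percent of dose released vs time
  (Franz-cell sampling, one profile per formulation), and
* in vivo concentration data — drug concentration in aqueous humor vs time,
  with a handful of replicate eyes per time point (destructive sampling:
  each animal contributes a single time point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReleaseProfile", "ConcProfile"]


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ReleaseProfile:
    """Cumulative in vitro release of one formulation.

    Parameters
    ----------
    times : array-like
        Sampling times in hours, strictly increasing, all >= 0.
    released : array-like
        Cumulative percent of dose released at each time. Values must lie
        in [0, ``overshoot_cap``]; the default cap of 110 tolerates small
        assay overshoot above 100 %.
    label : str
        Free-text formulation identifier.
    """

    times: np.ndarray
    released: np.ndarray
    label: str = ""
    overshoot_cap: float = 110.0

    def __post_init__(self) -> None:
        t = _as_1d_float(self.times, "times")
        q = _as_1d_float(self.released, "released")
        if t.size != q.size:
            raise ValueError("times and released must have equal length")
        if t.size < 3:
            raise ValueError("a release profile needs at least 3 points")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(q < 0) or np.any(q > self.overshoot_cap):
            raise ValueError(
                f"released values must lie in [0, {self.overshoot_cap}]"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "released", q)

    def window(self, t_min: float, t_max: float) -> "ReleaseProfile":
        """Restrict the profile to sampling times in [t_min, t_max]."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if mask.sum() < 3:
            raise ValueError("fewer than 3 points inside the fit window")
        return ReleaseProfile(
            self.times[mask], self.released[mask], self.label, self.overshoot_cap
        )

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ConcProfile:
    """Aqueous-humor concentration vs time for one treatment arm.

    ``concentrations`` are the per-time-point means across replicate eyes
    (the analysis level used for destructive sampling designs).  The raw
    replicate draws, when available, are kept in ``replicates`` as a list
    of arrays aligned with ``times``.
    """

    times: np.ndarray
    concentrations: np.ndarray
    n_per_point: int = 1
    arm: str = ""
    replicates: tuple = field(default=(), compare=False)
    lloq_censored: np.ndarray = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = _as_1d_float(self.times, "times")
        c = _as_1d_float(self.concentrations, "concentrations")
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if self.lloq_censored is None:
            object.__setattr__(
                self, "lloq_censored", np.zeros(t.size, dtype=bool)
            )

    def __len__(self) -> int:
        return self.times.size
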