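"""Shared container for relaxation-modulus curves on quasi-logarithmic grids."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class RelaxationModulus:
    """Relaxation modulus G(t) sampled on a (quasi-logarithmic) time grid.

    Parameters
    ----------
    times : ndarray
        Lag times in ps, strictly increasing.  May start at 0.
    values : ndarray
        G(t) in bar, or dimensionless G(t)/G(0) when ``normalized`` is True.
    counts : ndarray
        Number of samples (time origins x components) contributing per point.
    normalized : bool
        Whether ``values`` are divided by G(0).
    provenance : dict
        Free-form metadata: friction label, applied rescale factor, estimator
        settings.  Carried through superposition.
    """

    times: np.ndarray
    values: np.ndarray
    counts: np.ndarray = None
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.counts is None:
            self.counts = np.ones_like(self.values)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.normalized and self.times[0] == 0.0 and not np.isclose(
            self.values[0], 1.0
        ):
            raise ValueError("normalized curves must start at 1 at t=0")

    @property
    def g0(self) -> float:
        """Value at the shortest available lag (G(0) if t=0 is on the grid)."""
        return float(self.values[0])

    def normalize(self) -> "RelaxationModulus":
        """Return a copy scaled by 1/G(0) (no-op if already normalized)."""
        if self.normalized:
            return self
        g0 = self.g0
        if g0 == 0:
            raise ValueError("cannot normalize a curve with G(0) = 0")
        return replace(
            self,
            values=self.values / g0,
            normalized=True,
            provenance={**self.provenance, "g0_bar": g0},
        )

    def restricted(self, tmin: float, tmax: float) -> "RelaxationModulus":
        """Return the sub-curve with tmin <= t <= tmax."""
        sel = (self.times >= tmin) & (self.times <= tmax)
        if not np.any(sel):
            raise ValueError(f"no points in window [{tmin}, {tmax}]")
        return replace(
            self,
            times=self.times[sel],
            values=self.values[sel],
            counts=self.counts[sel],
        )


def quasi_log_grid(tmin: float, tmax: float, points_per_decade: int = 16) -> np.ndarray:
    """Logarithmically spaced time grid, tmin/tmax inclusive."""
    if tmin <= 0 or tmax <= tmin:
        raise ValueError("need 0 < tmin < tmax")
    n = max(2, int(np.ceil(np.log10(tmax / tmin) * points_per_decade)) + 1)
    return np.geomspace(tmin, tmax, n)
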