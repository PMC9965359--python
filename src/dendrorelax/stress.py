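"""Relaxation modulus from stress-tensor fluctuations, and curve fitting.

The Green-Kubo/fluctuation estimator used throughout is

    G(t) = V / (30 kB T) * sum_(ab in xy,yz,zx) [ 6 C_Pab(t) + C_Nab(t) ],

with N_ab = P_aa - P_bb the normal-stress differences and C_X(t) the
stationary autocorrelation of the fluctuating part of X (mean removed over
the full series).  Averaging the three shear components and the three normal
differences improves statistics by the factor the 1/30 prefactor accounts
for: in an isotropic system each shear ACF equals C and each difference ACF
equals 4C, so the combination has expectation 30 C and G(t) = V C(t) / kB T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_BAR_NM3
from .correlators import multitau_correlate
from .curves import RelaxationModulus, quasi_log_grid

COMPONENT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class StressSeries:
    """Uniformly sampled symmetric pressure tensor in bar.

    ``components`` is an (n_frames, 6) array ordered xx, yy, zz, xy, xz, yz.
    """

    dt: float  # ps
    components: np.ndarray
    volume: float  # nm^3
    temperature: float  # K
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 2 or self.components.shape[1] != 6:
            raise ValueError("components must be (n_frames, 6)")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.dt <= 0 or self.volume <= 0 or self.temperature <= 0:
            raise ValueError("dt, volume and temperature must be positive")

    @property
    def n_frames(self) -> int:
        return self.components.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.components[:, COMPONENT_ORDER.index(name)]


@dataclass
class TailFit:
    """Single-exponential terminal fit G ~ exp(-2 t / tau_max)."""

    tau_max: float  # in the time units of the fitted curve (ps here)
    amplitude: float
    window: tuple
    residual_rms: float

    @property
    def tau_max_ns(self) -> float:
        return self.tau_max / 1000.0


def relaxation_modulus(
    series: StressSeries,
    m: int = 16,
    average: int = 2,
    max_lag: int | None = None,
) -> RelaxationModulus:
    """Estimate G(t) in bar from a stress series on a quasi-log lag grid."""
    delta = series.components - series.components.mean(axis=0)
    xx, yy, zz = delta[:, 0], delta[:, 1], delta[:, 2]
    shear = [series_ for series_ in (delta[:, 3], delta[:, 5], delta[:, 4])]
    normal = [xx - yy, yy - zz, zz - xx]

    if max(np.ptp(c) for c in (*shear, *normal)) == 0.0:
        warnings.warn("constant stress input: degenerate (zero) modulus")
        flags = ["degenerate"]
    else:
        flags = []

    combined = None
    for s in shear:
        mt = multitau_correlate(s, m=m, average=average)
        combined = 6.0 * mt.acf if combined is None else combined + 6.0 * mt.acf
    for s in normal:
        mt = multitau_correlate(s, m=m, average=average)
        combined = combined + mt.acf

    lags, counts = mt.lags, mt.counts
    if max_lag is not None:
        if max_lag > series.n_frames // 2:
            warnings.warn(
                f"requested lag {max_lag} exceeds half the series "
                f"({series.n_frames // 2} frames); truncating"
            )
            max_lag = series.n_frames // 2
        keep = lags <= max_lag
        lags, counts, combined = lags[keep], counts[keep], combined[keep]

    prefac = series.volume / (30.0 * KB_BAR_NM3 * series.temperature)
    return RelaxationModulus(
        lags * series.dt,
        prefac * combined,
        counts=counts,
        provenance={
            "estimator": "stress-fluctuation",
            "m": m,
            "average": average,
            "dt_ps": series.dt,
            "volume_nm3": series.volume,
            "temperature_K": series.temperature,
            "flags": flags + series.flags,
        },
    )


def fit_loglog_slope(times, values, window: tuple):
    """OLS slope of log10(value) vs log10(time) on a window; returns (slope, stderr)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = (times >= window[0]) & (times <= window[1]) & (times > 0)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points in the fit window")
    if np.any(values[sel] <= 0):
        raise ValueError("log-log fit requires strictly positive values in the window")
    lx, ly = np.log10(times[sel]), np.log10(values[sel])
    n = lx.size
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    sxx = np.sum((lx - lx.mean()) ** 2)
    stderr = np.sqrt(resid @ resid / max(n - 2, 1) / sxx)
    return float(slope), float(stderr)


def fit_tail_time(curve: RelaxationModulus, window: tuple) -> TailFit:
    """Least squares of ln G vs t on a window; tau_max = -2/slope.

    The factor 2 follows the convention that each stress mode relaxes as
    exp(-2 t / tau): the fitted tail is  G(t) ~ A exp(-2 t / tau_max).
    """
    sel = (curve.times >= window[0]) & (curve.times <= window[1])
    if sel.sum() < 5:
        raise ValueError("tail window must contain at least 5 points")
    t, g = curve.times[sel], curve.values[sel]
    if np.any(g <= 0):
        raise ValueError("sign-changing or nonpositive G in the tail window")
    slope, intercept = np.polyfit(t, np.log(g), 1)
    if slope >= 0:
        raise ValueError("non-decaying G in the tail window")
    resid = np.log(g) - (slope * t + intercept)
    return TailFit(
        tau_max=-2.0 / slope,
        amplitude=float(np.exp(intercept)),
        window=(float(window[0]), float(window[1])),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def window_from_levels(curve: RelaxationModulus, lo: float, hi: float) -> tuple:
    """Time window where the normalized curve first passes from ``hi`` down to ``lo``.

    Scans forward from t=0: the window opens at the first point at or below
    ``hi`` and closes just before the first subsequent point below ``lo``
    (robust against noise re-entering the band at long times).
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    gn = curve.values / curve.g0 if not curve.normalized else curve.values
    idx_open = np.argmax(gn <= hi)
    if gn[idx_open] > hi:
        raise ValueError(f"curve never decays to {hi}")
    below = np.nonzero(gn[idx_open:] < lo)[0]
    idx_close = idx_open + below[0] - 1 if below.size else gn.size - 1
    if idx_close <= idx_open:
        raise ValueError("window is empty; curve decays faster than the grid resolves")
    return (float(curve.times[idx_open]), float(curve.times[idx_close]))


def superpose_master_curve(
    curves: list,
    tau_rots: list,
    ref: int = 0,
    points_per_decade: int = 16,
) -> RelaxationModulus:
    """Merge G(t) curves from different friction settings into one master curve.

    Each curve's time axis is multiplied by tau_rot(ref)/tau_rot(i); moduli
    are unchanged.  Rescaled curves are combined on a common quasi-log grid
    by sample-count-weighted averaging; grid points covered by no curve are
    dropped and the gap is flagged in the provenance.
    """
    if len(curves) != len(tau_rots):
        raise ValueError("one tau_rot per curve required")
    if any(t <= 0 for t in tau_rots):
        raise ValueError("tau_rot values must be positive")
    if len({c.normalized for c in curves}) != 1:
        raise ValueError("curves must all be normalized the same way")

    scaled = []
    for c, tr in zip(curves, tau_rots):
        f = tau_rots[ref] / tr
        scaled.append((c.times * f, c.values, c.counts, f, c.provenance))

    tmin = min(t[t > 0].min() for t, *_ in scaled)
    tmax = max(t.max() for t, *_ in scaled)
    grid = quasi_log_grid(tmin, tmax, points_per_decade)

    num = np.zeros_like(grid)
    den = np.zeros_like(grid)
    for t, v, n, _, _ in scaled:
        pos = t > 0
        t, v, n = t[pos], v[pos], n[pos]
        inside = (grid >= t[0]) & (grid <= t[-1])
        logt = np.log(t)
        vi = np.interp(np.log(grid[inside]), logt, v)
        ni = np.interp(np.log(grid[inside]), logt, n)
        num[inside] += vi * ni
        den[inside] += ni

    covered = den > 0
    gaps = _gap_intervals(grid, covered)
    grid, num, den = grid[covered], num[covered], den[covered]
    prov = {
        "superposition": [
            {"rescale_factor": f, "source": p.get("friction", i)}
            for i, (_, _, _, f, p) in enumerate(scaled)
        ],
        "reference": ref,
    }
    if gaps:
        prov["gaps"] = gaps
        warnings.warn(f"master curve has {len(gaps)} uncovered gap(s); not interpolated")
    return RelaxationModulus(
        grid, num / den, counts=den, normalized=curves[ref].normalized, provenance=prov
    )


def _gap_intervals(grid, covered):
    gaps = []
    in_gap = False
    for i in range(len(grid)):
        if not covered[i] and not in_gap:
            in_gap, start = True, grid[i]
        elif covered[i] and in_gap:
            in_gap = False
            gaps.append((float(start), float(grid[i - 1])))
    # leading/trailing uncovered points are grid-construction slack, not gaps,
    # only interior holes count
    interior = []
    first, last = np.nonzero(covered)[0][[0, -1]]
    for lo, hi in gaps:
        if lo > grid[first] and hi < grid[last]:
            interior.append((lo, hi))
    return interior
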