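"""Stationary Gaussian stress series with a prescribed relaxation modulus.

The target G(t) is a Prony series (sum of Maxwell modes).  Five independent
latent Gaussian processes e_1..e_5 with autocovariance

    c(t) = kB T G(t) / V

are built as exact sums of AR(1) (discretely sampled Ornstein-Uhlenbeck)
processes, one per Maxwell mode, and mapped onto the symmetric traceless
stress tensor so that the isotropic fluctuation structure

    <dP_ab(t) dP_gd(0)> = c(t) (d_ag d_bd + d_ad d_bg - (2/3) d_ab d_gd)

holds.  Applying the Eq.-(1)-style fluctuation estimator to the output then
has expectation exactly the target modulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from ..constants import KB_BAR_NM3
from ..stress import StressSeries


@dataclass(frozen=True)
class PronySeries:
    """Target relaxation modulus G(t) = sum_k g_k exp(-t / tau_k), in bar/ps."""

    modes: tuple  # ((g_bar, tau_ps), ...)

    def __post_init__(self):
        if not self.modes:
            raise ValueError("need at least one Maxwell mode")
        for g, tau in self.modes:
            if g < 0:
                raise ValueError(
                    "negative Prony weight: target is not realizable as a "
                    "positive-semidefinite autocovariance"
                )
            if tau <= 0:
                raise ValueError("mode times must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return sum(g * np.exp(-t / tau) for g, tau in self.modes)

    @property
    def g0(self) -> float:
        return sum(g for g, _ in self.modes)

    @property
    def tau_min(self) -> float:
        return min(tau for _, tau in self.modes)


def prony_from_powerlaw(
    exponent: float,
    window: tuple,
    amplitude: float = 100.0,
    modes_per_decade: int = 6,
    pad_decades: float = 1.0,
) -> PronySeries:
    """Prony approximation of a power law G(t) = amplitude (t/t1)^exponent.

    The power law (exponent < 0) is matched over ``window`` = (t1, t2) and a
    pad of ``pad_decades`` on both sides, so the realized target follows the
    power law cleanly across the whole stated window; outside, the mode sum
    plateaus at short times and cuts off exponentially at long times.
    """
    from scipy.optimize import nnls

    if exponent >= 0:
        raise ValueError("a relaxation modulus must be nonincreasing: exponent < 0")
    t1, t2 = window
    pad = 10.0**pad_decades
    t_fit = np.geomspace(t1 / pad, t2 * pad, 40 * int(np.ceil(np.log10(t2 / t1) + 2 * pad_decades)))
    target = amplitude * (t_fit / t1) ** exponent
    taus = np.geomspace(t1 / pad / 3.0, t2 * pad * 3.0, int(np.ceil(
        np.log10(t2 * pad * 9.0 / t1 * pad) * modes_per_decade)) + 1)
    design = np.exp(-t_fit[:, None] / taus[None, :]) / target[:, None]
    weights, _ = nnls(design, np.ones_like(t_fit))
    modes = tuple((float(w), float(tau)) for w, tau in zip(weights, taus) if w > 0)
    return PronySeries(modes)


# orthonormal basis of the traceless diagonal subspace
_T1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
_T2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)


def _latent(c_amps, taus, dt, n_frames, rng):
    """One latent process: sum of stationary AR(1) components."""
    x = np.zeros(n_frames)
    for a, tau in zip(c_amps, taus):
        if a == 0.0:
            continue
        phi = np.exp(-dt / tau)
        eps = rng.standard_normal(n_frames) * np.sqrt(a * (1.0 - phi**2))
        eps[0] = rng.standard_normal() * np.sqrt(a)  # stationary start
        x += lfilter([1.0], [1.0, -phi], eps)
    return x


def generate_stress_gp(
    target: PronySeries,
    dt: float,
    n_frames: int,
    volume: float,
    temperature: float,
    seed: int = 0,
) -> StressSeries:
    """Synthesize a stress series whose expected relaxation modulus is ``target``."""
    if dt <= 0 or n_frames < 2:
        raise ValueError("need dt > 0 and n_frames >= 2")
    rng = np.random.default_rng(seed)
    scale = KB_BAR_NM3 * temperature / volume
    amps = [scale * g for g, _ in target.modes]
    taus = [tau for _, tau in target.modes]

    e = [_latent(amps, taus, dt, n_frames, rng) for _ in range(5)]
    comp = np.empty((n_frames, 6))
    diag = np.sqrt(2.0) * (np.outer(e[3], _T1) + np.outer(e[4], _T2))
    comp[:, 0:3] = diag
    comp[:, 3] = e[0]  # xy
    comp[:, 4] = e[2]  # xz (= zx)
    comp[:, 5] = e[1]  # yz

    series = StressSeries(
        dt=dt, components=comp, volume=volume, temperature=temperature
    )
    if target.tau_min < 2.0 * dt:
        series.flags.append("undersampled-mode")
    return series
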