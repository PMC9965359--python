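"""Storage and loss moduli from a relaxation modulus.

Two routes are provided: a Prony-series route (nonnegative least squares on
log-spaced mode times, then the closed-form one-sided Fourier transform of
the mode sum) and a direct numeric route (analytic sine/cosine transforms of
the piecewise-linear interpolant of the same closed curve).  They serve as
mutual cross-checks; Prony is the default because it is noise-robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import nnls

from .curves import RelaxationModulus
from .stress import TailFit


@dataclass
class ModulusSpectrum:
    omegas: np.ndarray  # rad/ps, increasing
    gprime: np.ndarray  # storage, bar (or normalized like the source curve)
    gloss: np.ndarray  # loss
    prony: list = field(default_factory=list)  # [(g_k, tau_k)] when fitted

    def __post_init__(self):
        if np.any(np.diff(self.omegas) <= 0):
            raise ValueError("omega grid must be increasing")
        if np.any(self.gprime < -1e-12) or np.any(self.gloss < -1e-12):
            raise ValueError("negative modulus")


def default_omega_grid(curve: RelaxationModulus, points_per_decade: int = 8):
    t = curve.times[curve.times > 0]
    lo, hi = 0.1 / t.max(), 10.0 / t.min()
    n = int(np.ceil(np.log10(hi / lo) * points_per_decade)) + 1
    return np.geomspace(lo, hi, n)


def prony_fit(
    times: np.ndarray,
    values: np.ndarray,
    modes_per_decade: int = 12,
    tau_pad: float = 3.0,
    floor: float = 1e-3,
    refine: bool = True,
) -> list:
    """Fit G(t) ~ sum_k g_k exp(-t/tau_k), g_k >= 0, on log-spaced tau_k.

    The fit minimizes relative residuals so that decades of decay are weighted
    evenly; points below ``floor`` times the largest value are excluded (their
    relative weights would otherwise dominate the fit with data that no longer
    matters for the moduli).  The nonnegativity constraint makes the NNLS
    solution sparse; with ``refine`` the surviving (g_k, tau_k) are polished by
    log-parametrized least squares, which removes the mode-placement ripple of
    the fixed tau grid.  Returns the list of (g_k, tau_k) with g_k > 0.
    """
    pos = (times > 0) & (values > 0)
    pos &= values >= floor * values[pos].max()
    t, g = times[pos], values[pos]
    if t.size < 5:
        raise ValueError("too few positive points for a Prony fit")
    tau_lo, tau_hi = t.min() / tau_pad, t.max() * tau_pad
    n_modes = int(np.ceil(np.log10(tau_hi / tau_lo) * modes_per_decade)) + 1
    taus = np.geomspace(tau_lo, tau_hi, n_modes)
    design = np.exp(-t[:, None] / taus[None, :]) / g[:, None]
    weights, _ = nnls(design, np.ones_like(g))
    modes = [(float(w), float(tau)) for w, tau in zip(weights, taus) if w > 0]
    if refine and modes:
        from scipy.optimize import least_squares

        k = len(modes)
        p0 = np.log(np.array([m[0] for m in modes] + [m[1] for m in modes]))

        def resid(p):
            amps, mtaus = np.exp(p[:k]), np.exp(p[k:])
            model = (amps[None, :] * np.exp(-t[:, None] / mtaus[None, :])).sum(axis=1)
            return model / g - 1.0

        sol = least_squares(resid, p0, method="lm", max_nfev=60 * (2 * k + 1))
        if np.all(np.isfinite(sol.x)):
            amps, mtaus = np.exp(sol.x[:k]), np.exp(sol.x[k:])
            modes = sorted(zip(amps.tolist(), mtaus.tolist()), key=lambda m: m[1])
    return modes


def prony_moduli(prony: list, omegas: np.ndarray):
    g = np.array([p[0] for p in prony])
    tau = np.array([p[1] for p in prony])
    wt = omegas[:, None] * tau[None, :]
    gp = (g[None, :] * wt**2 / (1 + wt**2)).sum(axis=1)
    gpp = (g[None, :] * wt / (1 + wt**2)).sum(axis=1)
    return gp, gpp


def moduli_spectrum(
    curve: RelaxationModulus,
    method: str = "prony",
    omegas: np.ndarray | None = None,
    tail: TailFit | None = None,
    modes_per_decade: int = 6,
) -> ModulusSpectrum:
    """G'(omega), G''(omega) from a relaxation curve.

    The curve must be "closed": either it decays to <= 1% of G(0) within the
    data, or a terminal ``tail`` fit (from :func:`fit_tail_time`) is supplied
    to continue it analytically.
    """
    if omegas is None:
        omegas = default_omega_grid(curve)
    omegas = np.asarray(omegas, dtype=float)

    decayed = curve.values.min() <= 0.01 * curve.g0
    if not decayed and tail is None:
        raise ValueError(
            "curve does not decay to 1% of G(0); close the tail with "
            "fit_tail_time and pass the result as tail="
        )

    if method == "prony":
        t, v = curve.times, curve.values
        if tail is not None:
            # extend with analytic tail samples so the fit sees the closure
            rate = 2.0 / tail.tau_max
            t_ext = np.geomspace(t.max() * 1.2, t.max() + 6.0 / rate, 24)
            v_ext = tail.amplitude * np.exp(-rate * t_ext)
            t, v = np.concatenate([t, t_ext]), np.concatenate([v, v_ext])
        prony = prony_fit(t, v, modes_per_decade=modes_per_decade)
        gp, gpp = prony_moduli(prony, omegas)
        return ModulusSpectrum(omegas, gp, gpp, prony=prony)
    if method == "direct":
        gp, gpp = _direct_transform(curve, omegas, tail)
        return ModulusSpectrum(omegas, np.maximum(gp, 0), np.maximum(gpp, 0))
    raise ValueError(f"unknown method: {method!r}")


def _direct_transform(curve, omegas, tail):
    """Analytic sine/cosine transform of the piecewise-linear closed curve.

    G'(w) = w Int_0^inf G(t) sin(wt) dt,  G''(w) = w Int_0^inf G(t) cos(wt) dt.
    The curve is resampled densely in log-time (monotone PCHIP) so the
    piecewise-linear interpolation error is negligible; each linear segment
    and the exponential tail are integrated in closed form, which keeps the
    transform exact for arbitrarily fast oscillation.
    """
    pos = curve.times > 0
    t_raw, v_raw = curve.times[pos], curve.values[pos]
    interp = PchipInterpolator(np.log(t_raw), v_raw)
    t = np.geomspace(t_raw[0], t_raw[-1], max(64 * int(np.log10(t_raw[-1] / t_raw[0])), 64))
    v = interp(np.log(t))
    # refine uniformly where G is non-negligible so that omega*dt stays small
    # (pure log spacing leaves coherent chord error once omega*dt > 1)
    w_max = omegas.max()
    step = 0.1 / w_max
    g0 = v_raw[0]
    alive = t[v > 1e-6 * g0]
    t_trunc = alive[-1] if alive.size else t[0]
    n_uniform = int(min((t_trunc - t_raw[0]) / step, 2_000_000))
    if n_uniform > 2:
        t_uni = t_raw[0] + step * np.arange(n_uniform + 1)
        t = np.unique(np.concatenate([t, t_uni]))
        v = interp(np.log(t))
    # linear extrapolation to t=0 (a flat continuation biases G'' once
    # omega * t_min is order 1)
    v0 = v[0] - (v[1] - v[0]) / (t[1] - t[0]) * t[0]
    t = np.concatenate([[0.0], t])
    v = np.concatenate([[max(v0, v[0])], v])

    t1, t2 = t[:-1][None, :], t[1:][None, :]
    f1, f2 = v[:-1][None, :], v[1:][None, :]
    b = (f2 - f1) / (t2 - t1)
    w = omegas[:, None]
    s1, s2 = np.sin(w * t1), np.sin(w * t2)
    c1, c2 = np.cos(w * t1), np.cos(w * t2)
    i_sin = (f1 * c1 - f2 * c2) / w + b * (s2 - s1) / w**2
    i_cos = (f2 * s2 - f1 * s1) / w + b * (c2 - c1) / w**2
    gp = omegas * i_sin.sum(axis=1)
    gpp = omegas * i_cos.sum(axis=1)

    if tail is not None:
        r = 2.0 / tail.tau_max
        big_t = t[-1]
        amp = tail.amplitude * np.exp(0.0)
        e = amp * np.exp(-r * big_t)
        ws, wc = np.sin(omegas * big_t), np.cos(omegas * big_t)
        gp += omegas * e * (r * ws + omegas * wc) / (r**2 + omegas**2)
        gpp += omegas * e * (r * wc - omegas * ws) / (r**2 + omegas**2)
    return gp, gpp


def crossover_regions(spec: ModulusSpectrum) -> list:
    """Maximal omega-intervals where G' > G'' (elastic-dominated response).

    Endpoints interior to the grid are located by log-linear interpolation of
    the sign change of G' - G''; intervals touching the grid edge use the
    edge frequency.  Returns a list of (omega_lo, omega_hi).
    """
    d = spec.gprime - spec.gloss
    above = d > 0
    if not above.any():
        return []
    logw = np.log(spec.omegas)
    intervals = []
    i = 0
    n = len(d)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        lo = (
            spec.omegas[0]
            if i == 0
            else float(np.exp(logw[i - 1] + (logw[i] - logw[i - 1]) * (0 - d[i - 1]) / (d[i] - d[i - 1])))
        )
        hi = (
            spec.omegas[-1]
            if j == n - 1
            else float(np.exp(logw[j] + (logw[j + 1] - logw[j]) * (0 - d[j]) / (d[j + 1] - d[j])))
        )
        intervals.append((lo, hi))
        i = j + 1
    return intervals
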