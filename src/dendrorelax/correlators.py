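"""Multiple-tau (hierarchical block-averaging) autocorrelation.

The estimator follows the standard on-the-fly correlator design: the first
level correlates the raw series at lags 0..m-1; every further level first
averages the series in blocks of ``average`` frames and correlates the
coarsened series at lags m//average..m-1 (in coarse units).  This spans many
decades of lag at O(n log n) cost; the lag-0 value is the exact series
variance (no averaging is applied at level 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MultiTauACF:
    lags: np.ndarray  # in frames, strictly increasing, starting at 0
    acf: np.ndarray
    counts: np.ndarray  # number of time origins per lag


def _acf_at_lags(x: np.ndarray, lags: np.ndarray):
    n = x.size
    vals = np.empty(lags.size)
    cnts = np.empty(lags.size)
    for i, k in enumerate(lags):
        vals[i] = np.dot(x[: n - k], x[k:]) / (n - k)
        cnts[i] = n - k
    return vals, cnts


def multitau_correlate(
    x: np.ndarray,
    m: int = 16,
    average: int = 2,
    subtract_mean: bool = False,
) -> MultiTauACF:
    """Quasi-logarithmic autocorrelation of a scalar series.

    Parameters
    ----------
    x : 1-d array
    m : points per correlator level (>= 4)
    average : block-averaging factor between levels (>= 2)
    subtract_mean : remove the global mean before correlating
    """
    if m < 4:
        raise ValueError("need m >= 4 points per level")
    if average < 2:
        raise ValueError("averaging factor must be >= 2")
    x = np.asarray(x, dtype=float)
    if x.size < m:
        raise ValueError(f"series of length {x.size} is shorter than one level (m={m})")
    if subtract_mean:
        x = x - x.mean()

    lags_all, acf_all, cnt_all = [], [], []
    level_lags = np.arange(m)
    vals, cnts = _acf_at_lags(x, level_lags)
    lags_all.append(level_lags)
    acf_all.append(vals)
    cnt_all.append(cnts)

    scale = 1
    data = x
    coarse_lags = np.arange(m // average, m)
    while True:
        n_blocks = data.size // average
        if n_blocks < m:
            break
        data = data[: n_blocks * average].reshape(n_blocks, average).mean(axis=1)
        scale *= average
        vals, cnts = _acf_at_lags(data, coarse_lags)
        lags_all.append(coarse_lags * scale)
        acf_all.append(vals)
        cnt_all.append(cnts)

    return MultiTauACF(
        np.concatenate(lags_all),
        np.concatenate(acf_all),
        np.concatenate(cnt_all),
    )


def acf_fft(x: np.ndarray) -> np.ndarray:
    """Plain autocorrelation <x(t0) x(t0+t)> at all lags, FFT-based, unbiased."""
    x = np.asarray(x, dtype=float)
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(f * np.conj(f), nfft)[:n]
    return raw / (n - np.arange(n))


def quasi_log_lags(n: int, m: int = 16, average: int = 2) -> np.ndarray:
    """The lag set (in frames) a multitau correlator of these settings visits."""
    lags = list(range(min(m, n)))
    scale = 1
    length = n
    while length // average >= m:
        length //= average
        scale *= average
        lags.extend(k * scale for k in range(m // average, m))
    return np.array(sorted(set(lags)))
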