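"""Isotropic rotational diffusion of molecular axis vectors on the unit sphere.

Small tangent-space Gaussian kicks of variance 2 D dt per component followed
by renormalization; the rank-1 orientational correlation then decays as
P1(t) = exp(-2 D t), so the fitted rotational time is tau_rot = 1/(2 D).
"""

from __future__ import annotations

import numpy as np

from ..frames import VectorSeries


def generate_rotational_series(
    d_rot: float,
    dt: float,
    n_frames: int,
    n_molecules: int,
    seed: int = 0,
) -> VectorSeries:
    if d_rot < 0:
        raise ValueError("rotational diffusion coefficient must be >= 0")
    if dt <= 0 or n_frames < 2 or n_molecules < 1:
        raise ValueError("need dt > 0, n_frames >= 2, n_molecules >= 1")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_molecules, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    out = np.empty((n_frames, n_molecules, 3))
    out[0] = u
    if d_rot == 0.0:
        out[1:] = u
        return VectorSeries(out, dt=dt)
    amp = np.sqrt(2.0 * d_rot * dt)
    for k in range(1, n_frames):
        xi = amp * rng.standard_normal((n_molecules, 3))
        xi -= (xi * u).sum(axis=1, keepdims=True) * u  # tangent projection
        u = u + xi
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        out[k] = u
    return VectorSeries(out, dt=dt)
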