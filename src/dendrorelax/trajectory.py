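"""Rotational ACFs, gyration statistics, and radial density profiles.

P1(t) is the rank-1 orientational autocorrelation <u(t0+t).u(t0)> of a
molecule-fixed axis, averaged over time origins and molecules; its
exponential tail defines the rotational time tau_rot.  Gyration tensors are
mass-weighted; the fluctuation function <dRg_x^2(t)> follows the squared
increments of the xx-component on quasi-logarithmic lags.  Density profiles
are rho(r) = <m(r)>/V(r) in spherical shells around each molecule's centre
of mass, split into the reference molecule's own mass (rho_D) and everything
else (rho_overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import G_CM3_PER_AMU_NM3
from .correlators import acf_fft, quasi_log_lags
from .frames import TrajectoryFrames, VectorSeries, minimum_image


@dataclass
class RotationalACF:
    lags: np.ndarray  # ps
    p1: np.ndarray
    tau_rot: float  # ps; inf when the axis is frozen
    fit_window: tuple | None
    n_molecules: int


@dataclass
class GyrationSeries:
    rg_per_frame: np.ndarray  # (n_frames, n_molecules), nm
    rgx_per_frame: np.ndarray  # sqrt of xx tensor component
    tensors_mean: np.ndarray  # (n_molecules, 3, 3), nm^2
    fluct_lags: np.ndarray  # ps
    fluct: np.ndarray  # <dRg_x^2(t)>, nm^2

    @property
    def rg_ensemble(self) -> float:
        """Ensemble radius of gyration sqrt(<Rg^2>), nm."""
        return float(np.sqrt(np.mean(self.rg_per_frame**2)))


@dataclass
class DensityProfile:
    r_edges: np.ndarray  # nm
    rho_d: np.ndarray  # amu/nm^3
    rho_overlap: np.ndarray

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def in_g_cm3(self):
        return self.rho_d * G_CM3_PER_AMU_NM3, self.rho_overlap * G_CM3_PER_AMU_NM3


def rotational_acf(
    vectors: VectorSeries,
    fit_window: tuple | None = None,
    window_levels: tuple = (0.05, 0.5),
    max_lag_fraction: float = 0.5,
) -> RotationalACF:
    """P1(t) averaged over origins and molecules, with an exponential tail fit.

    The fit window defaults to the lag range where P1 is inside
    ``window_levels`` (chosen on the computed curve); pass ``fit_window`` in
    ps to override.  Frozen axes give P1 = 1 and tau_rot = inf.
    """
    if vectors.n_frames < 2:
        raise ValueError("need at least 2 frames")
    n = vectors.n_frames
    max_lag = max(2, int(n * max_lag_fraction))
    p1 = np.zeros(max_lag)
    for m in range(vectors.n_molecules):
        for c in range(3):
            p1 += acf_fft(vectors.u[:, m, c])[:max_lag]
    p1 /= vectors.n_molecules
    lags = np.arange(max_lag) * vectors.dt

    if np.allclose(p1, 1.0, atol=1e-9):
        return RotationalACF(lags, p1, np.inf, None, vectors.n_molecules)

    if fit_window is None:
        lo, hi = window_levels
        idx_open = np.argmax(p1 <= hi)
        if p1[idx_open] > hi:
            return RotationalACF(lags, p1, np.inf, None, vectors.n_molecules)
        below = np.nonzero(p1[idx_open:] < lo)[0]
        idx_close = idx_open + below[0] - 1 if below.size else max_lag - 1
        if idx_close <= idx_open:
            # decay faster than the lag grid resolves; no exponential window
            return RotationalACF(lags, p1, np.nan, None, vectors.n_molecules)
        fit_window = (lags[idx_open], lags[idx_close])
    sel = (lags >= fit_window[0]) & (lags <= fit_window[1])
    if np.any(p1[sel] <= 0):
        raise ValueError("P1 <= 0 inside the fit window; choose an earlier window")
    slope = np.polyfit(lags[sel], np.log(p1[sel]), 1)[0]
    tau = np.inf if slope >= 0 else -1.0 / slope
    return RotationalACF(lags, p1, float(tau), tuple(map(float, fit_window)), vectors.n_molecules)


def molecular_axis_vectors(
    frames: TrajectoryFrames,
    core_selector,
    periphery_selector,
    average_all_periphery: bool = False,
) -> VectorSeries:
    """Normalized core->periphery axis per molecule per frame.

    Selectors are callables ``f(global_index, element) -> bool``.  Each
    molecule must select exactly one core atom; of the periphery atoms the
    lowest bead index is used (or all, averaged before normalization, with
    ``average_all_periphery``).  Displacements use the minimum image.
    """
    mols = frames.molecules()
    axes = np.empty((frames.n_frames, len(mols), 3))
    for m, idx in enumerate(mols):
        cores = [i for i in idx if core_selector(i, frames.elements[i])]
        periph = [i for i in idx if periphery_selector(i, frames.elements[i])]
        if len(cores) != 1:
            raise ValueError(
                f"molecule {m}: core selector matched {len(cores)} atoms (need exactly 1)"
            )
        if not periph:
            raise ValueError(f"molecule {m}: periphery selector matched 0 atoms")
        chosen = periph if average_all_periphery else [min(periph)]
        d = np.zeros((frames.n_frames, 3))
        for p in chosen:
            d += minimum_image(
                frames.coords[:, p, :] - frames.coords[:, cores[0], :], frames.box
            )
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(norm == 0):
            raise ValueError(f"molecule {m}: degenerate (zero-length) axis")
        axes[:, m, :] = d / norm
    return VectorSeries(axes, dt=frames.dt)


def gyration_series(frames: TrajectoryFrames, m_lags: int = 16) -> GyrationSeries:
    """Mass-weighted gyration tensors and the <dRg_x^2(t)> fluctuation function.

    Expects whole (unwrapped) molecules; use ``frames.make_whole()`` first
    for wrapped input.
    """
    mols = frames.molecules()
    nf, nm = frames.n_frames, len(mols)
    rg = np.empty((nf, nm))
    rgx = np.empty((nf, nm))
    tensors_sum = np.zeros((nm, 3, 3))
    for m, idx in enumerate(mols):
        w = frames.masses[idx]
        if len(idx) == 1:
            warnings.warn(f"molecule {m} has a single bead; gyration tensor is zero")
        wt = w / w.sum()
        xyz = frames.coords[:, idx, :]
        com = (xyz * wt[None, :, None]).sum(axis=1, keepdims=True)
        rel = xyz - com
        t = np.einsum("fip,fiq,i->fpq", rel, rel, wt)
        tensors_sum[m] = t.mean(axis=0)
        rg[:, m] = np.sqrt(np.trace(t, axis1=1, axis2=2))
        rgx[:, m] = np.sqrt(t[:, 0, 0])

    lags = quasi_log_lags(nf, m=m_lags)
    lags = lags[lags < nf]
    fluct = np.zeros(lags.size)
    for li, k in enumerate(lags):
        if k == 0:
            continue
        diffs = rgx[k:, :] - rgx[:-k or None, :]
        fluct[li] = np.mean(diffs**2)
    return GyrationSeries(
        rg_per_frame=rg,
        rgx_per_frame=rgx,
        tensors_mean=tensors_sum,
        fluct_lags=lags * frames.dt,
        fluct=fluct,
    )


def radial_density_profiles(
    frames: TrajectoryFrames,
    bin_width: float = 0.02,
    r_max: float | None = None,
    reference_molecules: list | None = None,
) -> DensityProfile:
    """rho_D(r) and rho_overlap(r) around each molecule's centre of mass.

    Shell masses are averaged over reference molecules and frames and
    divided by the shell volume V(r) = (4 pi / 3)(r_out^3 - r_in^3).
    Distances to other molecules' beads use the minimum image; bins beyond
    half the box are truncated with a warning.
    """
    half_box = float(frames.box.min()) / 2.0
    if r_max is None:
        r_max = half_box
    elif r_max > half_box:
        warnings.warn("bins beyond half the box truncated")
        r_max = half_box
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    mols = frames.molecules()
    if reference_molecules is not None:
        uniq = list(np.unique(frames.molecule_id))
        mols = [mols[uniq.index(m)] for m in reference_molecules]
    mass_d = np.zeros(edges.size - 1)
    mass_ov = np.zeros(edges.size - 1)
    n_ref = 0
    for idx in mols:
        w = frames.masses[idx]
        com = (frames.coords[:, idx, :] * (w / w.sum())[None, :, None]).sum(axis=1)
        d_all = minimum_image(
            frames.coords - com[:, None, :], frames.box[:, None, :]
        )
        r_all = np.linalg.norm(d_all, axis=2)
        own = np.zeros(frames.n_beads, dtype=bool)
        own[idx] = True
        mass_d += np.histogram(
            r_all[:, own].ravel(), bins=edges,
            weights=np.tile(frames.masses[own], frames.n_frames),
        )[0]
        mass_ov += np.histogram(
            r_all[:, ~own].ravel(), bins=edges,
            weights=np.tile(frames.masses[~own], frames.n_frames),
        )[0]
        n_ref += frames.n_frames
    vol = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    return DensityProfile(edges, mass_d / n_ref / vol, mass_ov / n_ref / vol)
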