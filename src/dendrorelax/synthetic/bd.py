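"""Brownian-dynamics bead-spring dendrimer melts with virial stress.

Overdamped (Euler-Maruyama) Langevin dynamics of Gaussian phantom chains:

    r <- r - (K/zeta) (L r) dt + sqrt(2 kB T dt / zeta) xi,

with L the connectivity (Laplacian) matrix, K the spring constant and zeta
the bead friction.  Molecules do not interact (no excluded volume or
electrostatics): the melt is an ideal superposition, which is exactly the
regime whose stress relaxation the viscoelastic mode spectrum describes.
Initial coordinates are drawn from the exact Gaussian equilibrium via normal
modes, so no equilibration burn-in is needed.

Stress is the spring virial P_ab = -(K/V) sum_springs b_a b_b (fluctuating
part only; the ideal-gas/kinetic contribution is a constant offset that the
fluctuation estimator removes anyway), converted to bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ..constants import BAR_PER_KJ_MOL_NM3, KB_KJ_MOL
from ..frames import TrajectoryFrames
from ..stress import StressSeries
from ..topology import DendrimerTopology


@dataclass
class BDParams:
    spring_constant: float = 1.0  # kJ mol^-1 nm^-2
    friction: float = 1.0  # amu ps^-1
    temperature: float = 300.0  # K
    timestep: float = 0.01  # ps
    n_steps: int = 10000
    stress_stride: int = 1
    coord_stride: int = 0  # 0: do not store coordinates
    stress_groups: int = 1  # >1: independent per-group stress series
    seed: int = 0

    def __post_init__(self):
        if min(self.spring_constant, self.friction, self.timestep) <= 0:
            raise ValueError("spring constant, friction and timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")
        if self.n_steps < 1:
            raise ValueError("need at least one step")
        if self.timestep * self.spring_constant / self.friction >= 0.1:
            raise ValueError(
                "unstable timestep: require dt * K / zeta < 0.1 "
                f"(got {self.timestep * self.spring_constant / self.friction:.3g})"
            )


def _equilibrium_positions(topologies, params, box, rng):
    """Exact Gaussian equilibrium draw; molecule COMs on a cubic lattice."""
    n_total = sum(t.n_beads for t in topologies)
    coords = np.empty((n_total, 3))
    n_mol = len(topologies)
    cells = int(np.ceil(n_mol ** (1.0 / 3.0)))
    pitch = box / cells
    offset = 0
    for m, topo in enumerate(topologies):
        n = topo.n_beads
        com = (np.array(np.unravel_index(m, (cells,) * 3)) + 0.5) * pitch
        if params.temperature == 0.0:
            rel = np.zeros((n, 3))
        else:
            lam, vec = np.linalg.eigh(topo.laplacian())
            amp = np.zeros((n, 3))
            nonzero = lam > 1e-10
            sigma = np.sqrt(
                KB_KJ_MOL * params.temperature
                / (params.spring_constant * lam[nonzero])
            )
            amp[nonzero] = sigma[:, None] * rng.standard_normal((nonzero.sum(), 3))
            rel = vec @ amp
            rel -= rel.mean(axis=0)
        coords[offset : offset + n] = com + rel
        offset += n
    return coords


def simulate_bead_spring_bd(
    topologies: list,
    params: BDParams,
    box: float,
) -> tuple:
    """Run BD for a list of dendrimer topologies in a cubic box of edge ``box`` nm.

    Returns (TrajectoryFrames, StressSeries) — or (TrajectoryFrames,
    [StressSeries, ...]) when ``params.stress_groups > 1``, in which case the
    molecules are partitioned into that many independent sub-melts and each
    group's virial stress (with its share of the volume) is reported
    separately.  Since molecules do not interact, group series are
    statistically independent, and averaging their estimated moduli improves
    the relaxation-modulus statistics the way independent replicas do.
    Coordinates are stored unwrapped (molecules whole).  Deterministic for a
    given ``params.seed``.
    """
    if not topologies:
        raise ValueError("empty topology list")
    if not all(isinstance(t, DendrimerTopology) for t in topologies):
        raise TypeError("topologies must be DendrimerTopology instances")
    rng = np.random.default_rng(params.seed)
    volume = float(box) ** 3

    # global edge list and Laplacian over the concatenated bead set
    offsets = np.cumsum([0] + [t.n_beads for t in topologies])
    n_total = int(offsets[-1])
    edges = []
    mol_id = np.empty(n_total, dtype=int)
    elements, masses = [], []
    for m, topo in enumerate(topologies):
        local = {bid: k for k, bid in enumerate(topo.bead_ids)}
        for a, b in topo.edges:
            edges.append((offsets[m] + local[a], offsets[m] + local[b]))
        mol_id[offsets[m] : offsets[m + 1]] = m
        elements.extend(topo.elements)
        masses.extend(topo.masses)
    edges = np.array(edges)
    rows = np.concatenate([edges[:, 0], edges[:, 1], edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0], edges[:, 0], edges[:, 1]])
    vals = np.concatenate(
        [-np.ones(2 * len(edges)), np.ones(2 * len(edges))]
    )
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n_total, n_total))

    n_groups = params.stress_groups
    if len(topologies) % n_groups != 0:
        raise ValueError("number of molecules must divide evenly into stress_groups")
    edge_group = mol_id[edges[:, 0]] * n_groups // len(topologies)
    gmat = sp.csr_matrix(
        (np.ones(len(edges)), (edge_group, np.arange(len(edges)))),
        shape=(n_groups, len(edges)),
    )

    r = _equilibrium_positions(topologies, params, box, rng)
    k_over_z = params.spring_constant / params.friction
    dt = params.timestep
    noise_amp = np.sqrt(2.0 * KB_KJ_MOL * params.temperature * dt / params.friction)
    group_volume = volume / n_groups
    kv = params.spring_constant / group_volume * BAR_PER_KJ_MOL_NM3

    n_stress = params.n_steps // params.stress_stride
    stress = np.empty((n_stress, n_groups, 6))
    store_coords = params.coord_stride > 0
    if store_coords:
        n_coord = params.n_steps // params.coord_stride
        traj = np.empty((n_coord, n_total, 3))
    i_stress = i_coord = 0

    ei, ej = edges[:, 0], edges[:, 1]
    prod = np.empty((len(edges), 6))
    for step in range(1, params.n_steps + 1):
        r = r - k_over_z * dt * (lap @ r)
        if params.temperature > 0.0:
            r = r + noise_amp * rng.standard_normal((n_total, 3))
        if step % params.stress_stride == 0:
            b = r[ei] - r[ej]
            prod[:, 0] = b[:, 0] * b[:, 0]
            prod[:, 1] = b[:, 1] * b[:, 1]
            prod[:, 2] = b[:, 2] * b[:, 2]
            prod[:, 3] = b[:, 0] * b[:, 1]
            prod[:, 4] = b[:, 0] * b[:, 2]
            prod[:, 5] = b[:, 1] * b[:, 2]
            stress[i_stress] = -kv * (gmat @ prod)
            i_stress += 1
        if store_coords and step % params.coord_stride == 0:
            traj[i_coord] = r
            i_coord += 1

    temp = params.temperature if params.temperature > 0 else 1.0
    series_list = []
    for g in range(n_groups):
        s = StressSeries(
            dt=dt * params.stress_stride,
            components=stress[:, g, :],
            volume=group_volume,
            temperature=temp,
        )
        if params.temperature == 0.0:
            s.flags.append("zero-temperature")
        series_list.append(s)
    stress_series = series_list[0] if n_groups == 1 else series_list
    frames = TrajectoryFrames(
        coords=traj if store_coords else r[None, :, :],
        molecule_id=mol_id,
        elements=elements,
        masses=np.array(masses),
        box=np.full(3, float(box)),
        dt=dt * params.coord_stride if store_coords else dt * params.n_steps,
        bonds=[tuple(e) for e in edges],
    )
    return frames, stress_series
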