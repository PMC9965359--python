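"""Coordinate frames with hydrogen-bond triplets planted at exact geometries.

Each molecule carries an N-H donor group plus a carbon filler; every
requested bond adds a dedicated O acceptor bead to the acceptor molecule,
placed at exactly the requested donor-acceptor distance and donor-vertex
angle (between the donor->hydrogen and donor->acceptor directions).  All
other beads sit on a lattice far from any triplet, so a geometric
donor/acceptor search must find exactly the planted bonds.
"""

from __future__ import annotations

import numpy as np

from ..frames import TrajectoryFrames

_NH_BOND = 0.10  # nm


def plant_hbond_configuration(
    n_molecules: int,
    bonds: list,
    box: float,
    seed: int = 0,
    n_frames: int = 1,
) -> TrajectoryFrames:
    """Build frames containing exactly the requested donor-H...acceptor triplets.

    ``bonds`` is a list of (donor_mol, acceptor_mol, distance_nm, angle_deg).
    """
    box = float(box)
    for d, a, dist, ang in bonds:
        if not (0 <= d < n_molecules and 0 <= a < n_molecules):
            raise ValueError("molecule index out of range")
        if dist < 0 or ang < 0:
            raise ValueError("distances and angles must be nonnegative")
        if dist > box / 2:
            raise ValueError(
                f"requested donor-acceptor distance {dist} nm exceeds half the box"
            )
    rng = np.random.default_rng(seed)

    # lattice of molecule anchors, pitch >= 1.5 nm so fillers never pair up
    cells = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    pitch = box / cells
    if pitch < 1.2:
        raise ValueError("box too small for the requested number of molecules")

    coords, elements, mol_id, mol_bonds = [], [], [], []
    donor_idx, hydrogen_idx = {}, {}
    for m in range(n_molecules):
        anchor = (np.array(np.unravel_index(m, (cells,) * 3)) + 0.35) * pitch
        d_hat = _random_unit(rng)
        donor = anchor
        hydrogen = donor + _NH_BOND * d_hat
        filler = donor + np.array([0.0, 0.0, 0.45])
        base = len(coords)
        coords.extend([donor, hydrogen, filler])
        elements.extend(["N", "H", "C"])
        mol_id.extend([m, m, m])
        mol_bonds.append((base, base + 1))  # N-H
        mol_bonds.append((base, base + 2))
        donor_idx[m] = base
        hydrogen_idx[m] = base + 1

    for d_mol, a_mol, dist, ang in bonds:
        donor = np.asarray(coords[donor_idx[d_mol]])
        d_hat = coords[hydrogen_idx[d_mol]] - donor
        d_hat = d_hat / np.linalg.norm(d_hat)
        perp = _perpendicular(d_hat, rng)
        theta = np.deg2rad(ang)
        acceptor = donor + dist * (np.cos(theta) * d_hat + np.sin(theta) * perp)
        coords.append(acceptor)
        elements.append("O")
        mol_id.append(a_mol)

    coords = np.asarray(coords)
    masses = np.array(
        [{"N": 14.007, "H": 1.008, "C": 12.011, "O": 15.999}[e] for e in elements]
    )
    return TrajectoryFrames(
        coords=np.repeat(coords[None, :, :], n_frames, axis=0),
        molecule_id=np.array(mol_id),
        elements=elements,
        masses=masses,
        box=np.full(3, box),
        dt=1.0,
        bonds=mol_bonds,
    )


def _random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _perpendicular(u, rng):
    v = rng.standard_normal(3)
    v -= (v @ u) * u
    return v / np.linalg.norm(v)
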