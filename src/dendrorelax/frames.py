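"""In-memory containers for coordinate trajectories and orientation series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class TrajectoryFrames:
    """Bead coordinates for a multi-molecule system in an orthorhombic box.

    coords : (n_frames, n_beads, 3), nm
    molecule_id : (n_beads,) int — partitions beads into molecules
    elements : list of element symbols per bead
    masses : (n_beads,), amu
    box : (n_frames, 3) box edge lengths, nm
    dt : sampling interval, ps
    bonds : optional list of (i, j) bead-index pairs (global indices)
    """

    coords: np.ndarray
    molecule_id: np.ndarray
    elements: list
    masses: np.ndarray
    box: np.ndarray
    dt: float
    bonds: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_beads, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if self.molecule_id.shape[0] != self.n_beads:
            raise ValueError("molecule_id length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id))

    def molecules(self) -> list:
        return [
            np.nonzero(self.molecule_id == mid)[0]
            for mid in np.unique(self.molecule_id)
        ]

    def wrapped(self) -> "TrajectoryFrames":
        """Copy with all coordinates wrapped into [0, box)."""
        coords = np.mod(self.coords, self.box[:, None, :])
        return replace(self, coords=coords)

    def make_whole(self) -> "TrajectoryFrames":
        """Unwrap molecules across periodic boundaries using the bond list.

        Walks each molecule's bond tree from its lowest-index bead and places
        every neighbour at the minimum-image position relative to its parent.
        Requires bonds and bond lengths < half the box.
        """
        if not self.bonds:
            raise ValueError("make_whole requires a bond list")
        adj: dict = {}
        for i, j in self.bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        coords = self.coords.copy()
        box = self.box[:, None, :]
        for mol in self.molecules():
            root = mol[0]
            seen = {root}
            stack = [root]
            while stack:
                parent = stack.pop()
                for child in adj.get(parent, []):
                    if child in seen:
                        continue
                    seen.add(child)
                    d = coords[:, child, :] - coords[:, parent, :]
                    d -= np.round(d / self.box) * self.box
                    coords[:, child, :] = coords[:, parent, :] + d
                    stack.append(child)
        _ = box
        return replace(self, coords=coords)


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    return d - np.round(d / box) * box


@dataclass
class VectorSeries:
    """Per-frame, per-molecule unit vectors (molecular axes)."""

    u: np.ndarray  # (n_frames, n_molecules, 3)
    dt: float

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[2] != 3:
            raise ValueError("u must be (n_frames, n_molecules, 3)")
        norms = np.linalg.norm(self.u, axis=2)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("vectors must be unit length to 1e-9")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.u.shape[1]
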