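"""Geometric hydrogen-bond detection and statistics.

A donor-H...acceptor triplet is a hydrogen bond when the donor-acceptor
distance is at most 0.35 nm and the angle at the donor between the
donor->hydrogen and donor->acceptor directions is at most 30 degrees (the
standard near-linear-bond geometric criterion; the vertex atom is
configurable).  Counting follows the double-counting convention: each bond
contributes 2 to the per-system total (once for the donor side, once for
the acceptor side) before dividing by the number of molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import TrajectoryFrames, minimum_image


@dataclass
class HBondCriteria:
    max_distance: float = 0.35  # donor-acceptor, nm
    max_angle: float = 30.0  # degrees, at the vertex atom
    donor_elements: tuple = ("N", "O")
    acceptor_elements: tuple = ("N", "O")
    hydrogen_element: str = "H"
    angle_vertex: str = "donor"  # or "hydrogen"

    def __post_init__(self):
        if self.max_distance <= 0 or self.max_angle <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_vertex not in ("donor", "hydrogen"):
            raise ValueError("angle_vertex must be 'donor' or 'hydrogen'")


@dataclass
class HBondRecord:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    donor_mol: int
    acceptor_mol: int
    distance: float
    angle: float

    @property
    def intra(self) -> bool:
        return self.donor_mol == self.acceptor_mol


@dataclass
class HBondSummary:
    nhb_intra: float  # per dendrimer, double-counting convention
    nhb_inter: float
    distance_hist: tuple  # (bin_centers, counts)
    angle_hist: tuple
    mean_lifetime: float  # ps
    n_records: int = 0


def detect_hbonds(frames: TrajectoryFrames, criteria: HBondCriteria) -> list:
    """All donor-H...acceptor triplets passing both cutoffs, per frame.

    Donor hydrogens are identified from the frame bond list (an H bonded to
    a donor-element heavy atom).  Distances use the minimum image.
    """
    if not frames.bonds:
        raise ValueError("hydrogen-bond detection requires a bond list on the frames")
    elements = frames.elements
    dh_pairs = []
    for i, j in frames.bonds:
        if elements[i] == criteria.hydrogen_element and elements[j] in criteria.donor_elements:
            dh_pairs.append((j, i))
        elif elements[j] == criteria.hydrogen_element and elements[i] in criteria.donor_elements:
            dh_pairs.append((i, j))
    acceptors = np.array(
        [i for i, e in enumerate(elements) if e in criteria.acceptor_elements]
    )
    if not dh_pairs or acceptors.size == 0:
        warnings.warn("no donors or no acceptors selected; returning no bonds")
        return []

    records = []
    cos_cut = np.cos(np.deg2rad(criteria.max_angle))
    for f in range(frames.n_frames):
        box = frames.box[f]
        pos = np.mod(frames.coords[f], box)
        tree = cKDTree(pos[acceptors], boxsize=box)
        for donor, hydrogen in dh_pairs:
            for ai in tree.query_ball_point(pos[donor], criteria.max_distance):
                acc = int(acceptors[ai])
                if acc == donor:
                    continue
                d_da = minimum_image(pos[acc] - pos[donor], box)
                dist = float(np.linalg.norm(d_da))
                if dist > criteria.max_distance:
                    continue
                if criteria.angle_vertex == "donor":
                    v1 = minimum_image(pos[hydrogen] - pos[donor], box)
                    v2 = d_da
                else:
                    v1 = minimum_image(pos[donor] - pos[hydrogen], box)
                    v2 = minimum_image(pos[acc] - pos[hydrogen], box)
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if cosang < cos_cut:
                    continue
                records.append(
                    HBondRecord(
                        frame=f,
                        donor=donor,
                        hydrogen=hydrogen,
                        acceptor=acc,
                        donor_mol=int(frames.molecule_id[donor]),
                        acceptor_mol=int(frames.molecule_id[acc]),
                        distance=dist,
                        angle=float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))),
                    )
                )
    return records


def hbond_statistics(
    records: list,
    n_molecules: int,
    n_frames: int,
    dt: float,
    distance_bin: float = 0.005,
    angle_bin: float = 1.0,
    max_distance: float = 0.35,
    max_angle: float = 30.0,
) -> HBondSummary:
    """Per-dendrimer bond counts, geometry histograms, and mean lifetime.

    <N_HB> uses the double-counting convention (a bond counts once for its
    donor molecule and once for its acceptor molecule).  The mean lifetime
    is the integrated correlation time of the intermittent bond-presence
    indicator h(t): tau = dt * sum_{t=-inf}^{inf} C(t) with
    C(t) = <h(0)h(t)> / <h^2>, which for a bond present over one
    uninterrupted stretch of k frames equals k dt exactly.
    """
    n_intra = sum(1 for r in records if r.intra)
    n_inter = len(records) - n_intra
    nhb_intra = 2.0 * n_intra / n_frames / n_molecules
    nhb_inter = 2.0 * n_inter / n_frames / n_molecules

    d_edges = np.arange(0.0, max_distance + distance_bin, distance_bin)
    a_edges = np.arange(0.0, max_angle + angle_bin, angle_bin)
    d_hist = np.histogram([r.distance for r in records], bins=d_edges)[0]
    a_hist = np.histogram([r.angle for r in records], bins=a_edges)[0]

    lifetime = 0.0
    if records:
        triples: dict = {}
        for r in records:
            triples.setdefault((r.donor, r.hydrogen, r.acceptor), set()).add(r.frame)
        from .correlators import acf_fft

        num = 0.0
        den = 0.0
        for frames_on in triples.values():
            h = np.zeros(n_frames)
            h[sorted(frames_on)] = 1.0
            c = acf_fft(h)
            num += c[0] + 2.0 * c[1:].sum()
            den += c[0]
        lifetime = dt * num / den

    return HBondSummary(
        nhb_intra=nhb_intra,
        nhb_inter=nhb_inter,
        distance_hist=(0.5 * (d_edges[:-1] + d_edges[1:]), d_hist),
        angle_hist=(0.5 * (a_edges[:-1] + a_edges[1:]), a_hist),
        mean_lifetime=lifetime,
        n_records=len(records),
    )
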