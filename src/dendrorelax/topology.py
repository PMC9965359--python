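"""Dendrimer tree topologies, chemical compositions, and Rouse-type mode spectra.

A dendrimer is modelled at the viscoelastic granularity: one bead per branch
point and per terminal group, one entropic spring per segment.  The
second-generation presets (PAMAM, PPI, PCS) are defined by explicit layer
lists, each yielding 16 terminal groups:

* PAMAM/PPI: a two-bead core (formal core functionality F_c = 2, carrying
  four outgoing first-layer segments), then trifunctional branch layers of
  4 and 8 beads, then 16 terminal beads.
* PCS: a single tetrafunctional core (F_c = 4), branch layers of 4 and 8
  silicon beads, then 16 terminal beads.

The mode spectrum is the graph-Laplacian spectrum with the tethered-segment
normalization: a single bead bound by one spring to a fixed point has
eigenvalue 1, so its relaxation time is the terminal-segment time tau0 and
mode p relaxes with tau_p = tau0 / lambda_p.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .constants import ATOMIC_MASSES, KB_BAR_NM3, KB_KJ_MOL
from .curves import RelaxationModulus


class Family(str, enum.Enum):
    PAMAM = "PAMAM"
    PPI = "PPI"
    PCS = "PCS"
    GENERIC = "generic"


@dataclass(frozen=True)
class DendrimerSpec:
    """Architectural parameters of a dendrimer family.

    ``generation`` counts growth layers beyond the first shell of segments
    attached to the core (generation numbering conventions differ between
    dendrimer literatures; the chemical presets are pinned to explicit layer
    lists instead of a closed-form terminal count).
    """

    family: Family = Family.GENERIC
    core_functionality: int = 3
    branch_functionality: int = 3
    generation: int = 2
    spacer_beads: int = 1

    def __post_init__(self):
        if self.core_functionality < 1:
            raise ValueError("core functionality must be >= 1")
        if self.branch_functionality < 2:
            raise ValueError("branch functionality must be >= 2")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if self.spacer_beads < 1:
            raise ValueError("spacer_beads must be >= 1")


@dataclass
class DendrimerTopology:
    """Tree of beads: ids, generation layer, element symbol and mass per bead."""

    beads: list  # (id, layer g, element, mass amu)
    edges: list  # (id1, id2)
    terminal_ids: list
    family: Family = Family.GENERIC

    def __post_init__(self):
        g = self.graph()
        if g.number_of_nodes() != len(self.beads):
            raise ValueError("edge list references unknown beads")
        if not nx.is_tree(g):
            raise ValueError("dendrimer topology must be a connected tree")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(b[0] for b in self.beads)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def bead_ids(self) -> list:
        return [b[0] for b in self.beads]

    @property
    def masses(self) -> np.ndarray:
        return np.array([b[3] for b in self.beads], dtype=float)

    @property
    def elements(self) -> list:
        return [b[2] for b in self.beads]

    @property
    def layers(self) -> np.ndarray:
        return np.array([b[1] for b in self.beads], dtype=int)

    def core_ids(self) -> list:
        return [b[0] for b in self.beads if b[1] == 0]

    def laplacian(self) -> np.ndarray:
        g = self.graph()
        return nx.laplacian_matrix(g, nodelist=self.bead_ids).toarray().astype(float)

    def export(self, path) -> None:
        """Write an edge list plus a bead table as plain text."""
        with open(path, "w") as fh:
            fh.write(f"# dendrorelax topology family={self.family.value}\n")
            fh.write("# beads: id layer element mass_amu\n")
            for bid, layer, elem, mass in self.beads:
                fh.write(f"bead {bid} {layer} {elem} {mass:.4f}\n")
            fh.write("# edges: id1 id2\n")
            for a, b in self.edges:
                fh.write(f"{a} {b}\n")


@dataclass
class ChemicalComposition:
    element_counts: dict
    molar_mass: float

    def __post_init__(self):
        m = sum(ATOMIC_MASSES[el] * n for el, n in self.element_counts.items())
        if abs(m - self.molar_mass) > 1e-6:
            raise ValueError("molar mass inconsistent with element counts")
        if any(n <= 0 or n != int(n) for n in self.element_counts.values()):
            raise ValueError("element counts must be positive integers")


@dataclass
class ModeSpectrum:
    """Connectivity-matrix eigenvalues with multiplicities and relaxation times."""

    eigenvalues: np.ndarray  # ascending, one entry per mode (with repeats)
    tau0: float  # terminal-segment relaxation time, ps
    n_zero_modes: int = field(init=False)

    def __post_init__(self):
        self.eigenvalues = np.sort(np.asarray(self.eigenvalues, dtype=float))
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        zero = np.isclose(self.eigenvalues, 0.0, atol=1e-9)
        self.eigenvalues[zero] = 0.0
        self.n_zero_modes = int(zero.sum())
        if np.any(self.eigenvalues < 0):
            raise ValueError("negative Laplacian eigenvalue — invalid topology")

    @property
    def nonzero(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > 0]

    @property
    def times(self) -> np.ndarray:
        """Relaxation times tau_p = tau0 / lambda_p for the nonzero modes, ps."""
        return self.tau0 / self.nonzero

    def degeneracy_table(self, decimals: int = 8) -> list:
        """Unique (eigenvalue, multiplicity, tau_p) triples; tau is inf at 0."""
        vals, counts = np.unique(np.round(self.eigenvalues, decimals), return_counts=True)
        return [
            (float(v), int(c), float(self.tau0 / v) if v > 0 else np.inf)
            for v, c in zip(vals, counts)
        ]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Chemical fragment masses are assembled from ATOMIC_MASSES at build time so a
# single atomic-mass table controls everything.
def _m(formula: dict) -> float:
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())


# Per-bead fragments of the coarse model, by family:
#   core: the central unit (split over two beads for PAMAM/PPI)
#   branch: repeat unit owned by each non-core branch-point bead
#   terminal: terminal-group unit
_PRESETS = {
    Family.PAMAM: {
        "core": {"C": 2, "H": 4, "N": 2},       # ethylenediamine core, N-H replaced
        "branch": {"C": 5, "H": 9, "N": 2, "O": 1},   # -CH2CH2-CO-NH-CH2CH2-N<
        "terminal": {"C": 5, "H": 11, "N": 2, "O": 1},  # ...-NH2
        "core_beads": 2,
        "branch_element": "N",
        "terminal_element": "N",
    },
    Family.PPI: {
        "core": {"C": 4, "H": 8, "N": 2},       # diaminobutane core
        "branch": {"C": 3, "H": 6, "N": 1},     # -(CH2)3-N<
        "terminal": {"C": 3, "H": 8, "N": 1},   # -(CH2)3-NH2
        "core_beads": 2,
        "branch_element": "N",
        "terminal_element": "N",
    },
    Family.PCS: {
        # Fig-1c reading: Si core (F_c=4), trimethylene segments, one methyl on
        # every non-core Si, n-butyl terminal groups.  Terminal chemistry is
        # pinned by matching the printed molar mass (1964.3 g/mol) and is the
        # main residual ambiguity of this preset.
        "core": {"Si": 1},
        "branch": {"C": 4, "H": 9, "Si": 1},    # -(CH2)3-Si(CH3)<
        "terminal": {"C": 4, "H": 9},           # n-butyl
        "core_beads": 1,
        "branch_element": "Si",
        "terminal_element": "C",
    },
}

# Layer occupancies for the G2 presets (16 terminal groups each).
_G2_BRANCH_LAYERS = (4, 8)
_G2_TERMINALS = 16


def build_topology(spec: DendrimerSpec) -> DendrimerTopology:
    """Construct the coarse bead-spring tree for a dendrimer spec.

    Chemical presets (PAMAM/PPI/PCS) currently ship at generation 2 (the
    16-terminal-group architecture).  The generic family builds
    F_c first-shell segments followed by ``generation`` trifunctional-style
    growth layers of F-1 children each, with ``spacer_beads`` beads per
    segment.
    """
    if spec.family is Family.GENERIC:
        return _build_generic(spec)
    if spec.family not in _PRESETS:
        raise ValueError(f"unknown dendrimer family: {spec.family}")
    if spec.generation != 2:
        raise ValueError(
            f"{spec.family.value} preset is defined at generation 2 "
            "(16 terminal groups); use the generic family for other sizes"
        )
    p = _PRESETS[spec.family]
    beads, edges = [], []
    nxt = 0
    core = []
    core_mass = _m(p["core"]) / p["core_beads"]
    for _ in range(p["core_beads"]):
        beads.append((nxt, 0, p["branch_element"], core_mass))
        core.append(nxt)
        nxt += 1
    if len(core) == 2:
        edges.append((core[0], core[1]))
    # first branch layer: 4 beads distributed over the core bead(s)
    frontier = []
    n_first = _G2_BRANCH_LAYERS[0]
    m_branch = _m(p["branch"])
    for i in range(n_first):
        parent = core[i % len(core)]
        beads.append((nxt, 1, p["branch_element"], m_branch))
        edges.append((parent, nxt))
        frontier.append(nxt)
        nxt += 1
    # second branch layer: each first-layer bead spawns F-1 = 2 children
    new_frontier = []
    for parent in frontier:
        for _ in range(2):
            beads.append((nxt, 2, p["branch_element"], m_branch))
            edges.append((parent, nxt))
            new_frontier.append(nxt)
            nxt += 1
    # terminal layer
    m_term = _m(p["terminal"])
    terminals = []
    for parent in new_frontier:
        for _ in range(2):
            beads.append((nxt, 3, p["terminal_element"], m_term))
            edges.append((parent, nxt))
            terminals.append(nxt)
            nxt += 1
    assert len(terminals) == _G2_TERMINALS
    return DendrimerTopology(beads, edges, terminals, family=spec.family)


def _build_generic(spec: DendrimerSpec) -> DendrimerTopology:
    beads = [(0, 0, "X", 1.0)]
    edges, nxt = [], 1

    def add_segment(parent, layer):
        nonlocal nxt
        for _ in range(spec.spacer_beads):
            beads.append((nxt, layer, "X", 1.0))
            edges.append((parent, nxt))
            parent = nxt
            nxt += 1
        return parent

    frontier = [add_segment(0, 1) for _ in range(spec.core_functionality)]
    for layer in range(2, spec.generation + 2):
        frontier = [
            add_segment(parent, layer)
            for parent in frontier
            for _ in range(spec.branch_functionality - 1)
        ]
    return DendrimerTopology(beads, edges, frontier, family=Family.GENERIC)


def composition_and_mass(spec: DendrimerSpec) -> ChemicalComposition:
    """Element counts and molar mass of a chemical preset (G2)."""
    if spec.family is Family.GENERIC:
        raise ValueError("generic family has no chemistry; use a PAMAM/PPI/PCS preset")
    if spec.generation != 2:
        raise ValueError("chemical presets are defined at generation 2")
    p = _PRESETS[spec.family]
    n_branch = sum(_G2_BRANCH_LAYERS)
    counts: dict = {}
    for frag, mult in ((p["core"], 1), (p["branch"], n_branch), (p["terminal"], _G2_TERMINALS)):
        for el, n in frag.items():
            counts[el] = counts.get(el, 0) + n * mult
    return ChemicalComposition(counts, _m(counts))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def connectivity_spectrum(topology: DendrimerTopology, tau0: float) -> ModeSpectrum:
    """Rouse-matrix (graph Laplacian) eigenvalues of a dendrimer tree.

    Under the tethered-segment normalization (one bead on one spring to a
    fixed point has eigenvalue 1), mode p has relaxation time tau0/lambda_p.
    """
    g = topology.graph()
    if not nx.is_connected(g):
        raise ValueError("topology graph is disconnected")
    lam = np.linalg.eigvalsh(topology.laplacian())
    return ModeSpectrum(lam, tau0=tau0)


def internal_band(branch_functionality: int) -> tuple:
    """Eigenvalue band [F - 2 sqrt(F-1), F + 2 sqrt(F-1)] of the internal spectrum.

    The reciprocals give the internal relaxation-time window in units of tau0;
    for F = 3 this is 0.17 tau0 to 5.8 tau0.
    """
    f = branch_functionality
    if f < 2:
        raise ValueError("branch functionality must be >= 2")
    half = 2.0 * np.sqrt(f - 1.0)
    return (f - half, f + half)


def classify_modes(topology: DendrimerTopology, atol: float = 1e-8) -> list:
    """Label every Laplacian mode of a dendrimer tree.

    Returns a list of (eigenvalue, label) with labels:

    * ``translation`` — the zero mode;
    * ``core-coupled`` — the eigenvector moves the core bead(s);
    * ``pulsation`` — zero core amplitude and nodeless (single-signed) on each
      connected component of its support: whole-(sub)branch breathing motions,
      whose times fall outside the internal band for deep branches;
    * ``internal`` — zero core amplitude with sign changes: small-scale modes
      confined to the interior band [F - 2 sqrt(F-1), F + 2 sqrt(F-1)].
    """
    lap = topology.laplacian()
    w, v = np.linalg.eigh(lap)
    ids = topology.bead_ids
    index = {bid: i for i, bid in enumerate(ids)}
    core_idx = [index[c] for c in topology.core_ids()]
    g = topology.graph()
    out = []
    for k in range(len(w)):
        vec = v[:, k]
        if np.isclose(w[k], 0.0, atol=1e-9):
            out.append((0.0, "translation"))
            continue
        scale = np.abs(vec).max()
        if any(abs(vec[c]) > atol * scale for c in core_idx):
            out.append((float(w[k]), "core-coupled"))
            continue
        support = [ids[i] for i in range(len(ids)) if abs(vec[i]) > atol * scale]
        sub = g.subgraph(support)
        sign_change = False
        for comp in nx.connected_components(sub):
            signs = np.sign([vec[index[n]] for n in comp])
            if signs.max() != signs.min():
                sign_change = True
                break
        out.append((float(w[k]), "internal" if sign_change else "pulsation"))
    return out


def theoretical_relaxation_modulus(
    spectrum: ModeSpectrum,
    number_density: float,
    temperature: float,
    tgrid: np.ndarray,
) -> RelaxationModulus:
    """Viscoelastic-model modulus G(t) = nu kB T sum_p exp(-2 t / tau_p), in bar.

    Each Rouse mode relaxes stress with the factor-2 exponent (stress is
    quadratic in mode amplitudes).  ``number_density`` is molecules per nm^3;
    modes are summed with their multiplicities over one molecule's spectrum.
    """
    tgrid = np.asarray(tgrid, dtype=float)
    if np.any(np.diff(tgrid) <= 0) or np.any(tgrid < 0):
        raise ValueError("tgrid must be ascending and nonnegative")
    taus = spectrum.times
    if taus.size == 0:
        raise ValueError("spectrum has no relaxing modes")
    g = number_density * KB_BAR_NM3 * temperature * np.exp(
        -2.0 * tgrid[:, None] / taus[None, :]
    ).sum(axis=1)
    return RelaxationModulus(
        tgrid,
        g,
        provenance={
            "source": "viscoelastic-model",
            "tau0_ps": spectrum.tau0,
            "number_density_nm3": number_density,
            "temperature_K": temperature,
        },
    )


def gaussian_rg2(topology: DendrimerTopology, temperature: float, spring_constant: float) -> float:
    """Analytic mean-square gyration radius of the Gaussian (phantom) tree, nm^2.

    <Rg^2> = (1/N^2) sum_{i<j} d_ij b^2 with b^2 = 3 kB T / K the mean-square
    spring length and d_ij the topological (edge-count) distance.
    """
    g = topology.graph()
    n = topology.n_beads
    b2 = 3.0 * KB_KJ_MOL * temperature / spring_constant
    total = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        total += sum(dists.values())
    return total / 2 / n**2 * b2
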