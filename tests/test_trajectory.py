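"""Rotational ACF, molecular axes, gyration statistics, density profiles."""

import numpy as np
import pytest

from dendrorelax.frames import TrajectoryFrames, VectorSeries
from dendrorelax.trajectory import (
    gyration_series,
    molecular_axis_vectors,
    radial_density_profiles,
    rotational_acf,
)


def frames_from(coords, mol_id, elements, masses, box=20.0, dt=1.0, bonds=()):
    return TrajectoryFrames(
        coords=np.asarray(coords, dtype=float),
        molecule_id=np.asarray(mol_id),
        elements=list(elements),
        masses=np.asarray(masses, dtype=float),
        box=np.full(3, box),
        dt=dt,
        bonds=list(bonds),
    )


class TestRotationalACF:
    def test_frozen_vectors_flagged_infinite(self):
        u = np.tile(np.array([0.0, 0.0, 1.0]), (100, 2, 1))
        acf = rotational_acf(VectorSeries(u, dt=1.0))
        assert np.allclose(acf.p1, 1.0)
        assert np.isinf(acf.tau_rot)

    def test_duplicated_molecule_changes_nothing(self, rng):
        from dendrorelax.synthetic.rotational import generate_rotational_series

        vs = generate_rotational_series(0.01, dt=0.5, n_frames=2000, n_molecules=1, seed=8)
        dup = VectorSeries(np.concatenate([vs.u, vs.u], axis=1), dt=0.5)
        a = rotational_acf(vs)
        b = rotational_acf(dup)
        assert np.allclose(a.p1, b.p1)
        assert a.tau_rot == pytest.approx(b.tau_rot, rel=1e-12)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        from dendrorelax.synthetic.rotational import generate_rotational_series

        vs = generate_rotational_series(0.05, dt=0.5, n_frames=300, n_molecules=4, seed=9)
        rot = Rotation.from_euler("zyx", [0.3, 1.1, -0.4]).as_matrix()
        rotated = VectorSeries(vs.u @ rot.T, dt=0.5)
        a = rotational_acf(vs, fit_window=(2, 20))
        b = rotational_acf(rotated, fit_window=(2, 20))
        assert np.allclose(a.p1, b.p1, atol=1e-12)

    def test_nonpositive_window_rejected(self):
        u = np.zeros((50, 1, 3))
        u[:, :, 0] = np.where(np.arange(50)[:, None] % 2 == 0, 1.0, -1.0)
        with pytest.raises(ValueError, match="P1"):
            rotational_acf(VectorSeries(u, dt=1.0), fit_window=(1, 10))


class TestMolecularAxis:
    def _two_atom(self, second=(1.0, 0.0, 0.0)):
        coords = np.array([[[0.0, 0.0, 0.0], list(second)]])
        return frames_from(coords, [0, 0], ["N", "N"], [14.0, 14.0])

    def test_axis_along_x(self):
        fr = self._two_atom()
        vs = molecular_axis_vectors(fr, lambda i, e: i == 0, lambda i, e: i == 1)
        assert np.allclose(vs.u[0, 0], [1.0, 0.0, 0.0])

    def test_right_angle_rotation_decorrelates(self):
        coords = np.array([
            [[0, 0, 0], [1.0, 0, 0]],
            [[0, 0, 0], [0, 1.0, 0]],
        ])
        fr = frames_from(coords, [0, 0], ["N", "N"], [14.0, 14.0])
        vs = molecular_axis_vectors(fr, lambda i, e: i == 0, lambda i, e: i == 1)
        assert vs.u[0, 0] @ vs.u[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_minimum_image_across_boundary(self):
        coords = np.array([[[0.2, 0.0, 0.0], [19.8, 0.0, 0.0]]])
        fr = frames_from(coords, [0, 0], ["N", "N"], [14.0, 14.0], box=20.0)
        vs = molecular_axis_vectors(fr, lambda i, e: i == 0, lambda i, e: i == 1)
        assert np.allclose(vs.u[0, 0], [-1.0, 0.0, 0.0])

    def test_empty_selector_names_molecule(self):
        fr = self._two_atom()
        with pytest.raises(ValueError, match="molecule 0"):
            molecular_axis_vectors(fr, lambda i, e: False, lambda i, e: True)


class TestGyration:
    def test_rigid_translation_has_zero_fluctuation(self):
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, 1.0, 0]])
        coords = np.array([base + [0.1 * k, 0.05 * k, 0.0] for k in range(32)])
        fr = frames_from(coords, [0, 0, 0], ["C"] * 3, [12.0] * 3, box=100.0)
        g = gyration_series(fr)
        assert np.allclose(g.fluct, 0.0, atol=1e-24)

    def test_two_equal_masses(self):
        d = 0.8
        coords = np.array([[[0.0, 0, 0], [d, 0, 0]]])
        fr = frames_from(coords, [0, 0], ["C", "C"], [12.0, 12.0])
        g = gyration_series(fr)
        assert g.rgx_per_frame[0, 0] == pytest.approx(d / 2, rel=1e-12)
        assert g.rg_per_frame[0, 0] == pytest.approx(d / 2, rel=1e-12)

    def test_translation_invariance_and_pairwise_form(self, rng):
        n = 12
        coords = rng.standard_normal((1, n, 3))
        masses = rng.uniform(1, 5, n)
        fr = frames_from(coords, [0] * n, ["C"] * n, masses, box=200.0)
        fr2 = frames_from(coords + 17.0, [0] * n, ["C"] * n, masses, box=200.0)
        g1, g2 = gyration_series(fr), gyration_series(fr2)
        assert np.allclose(g1.rg_per_frame, g2.rg_per_frame, rtol=1e-10)
        # pairwise (Lagrange) form of Rg^2
        m = masses.sum()
        r = coords[0]
        pair = sum(
            masses[i] * masses[j] * np.sum((r[i] - r[j]) ** 2)
            for i in range(n) for j in range(i + 1, n)
        ) / m**2
        assert g1.rg_per_frame[0, 0] ** 2 == pytest.approx(pair, rel=1e-10)

    def test_single_bead_flagged(self):
        fr = frames_from(np.zeros((2, 1, 3)), [0], ["C"], [12.0])
        with pytest.warns(UserWarning, match="single bead"):
            g = gyration_series(fr)
        assert np.allclose(g.rg_per_frame, 0.0)


class TestDensityProfiles:
    def test_single_bead_mass_conserved(self):
        fr = frames_from(np.zeros((1, 1, 3)), [0], ["C"], [12.0], box=10.0)
        prof = radial_density_profiles(fr, bin_width=0.1)
        vol = 4 * np.pi / 3 * (prof.r_edges[1:] ** 3 - prof.r_edges[:-1] ** 3)
        assert (prof.rho_d * vol).sum() == pytest.approx(12.0, rel=1e-12)
        assert np.all(prof.rho_overlap == 0)

    def test_mass_conservation_multi_bead(self, rng):
        n = 20
        coords = 5.0 + 0.3 * rng.standard_normal((3, n, 3))
        fr = frames_from(coords, [0] * n, ["C"] * n, np.full(n, 2.5), box=10.0)
        prof = radial_density_profiles(fr, bin_width=0.05)
        vol = 4 * np.pi / 3 * (prof.r_edges[1:] ** 3 - prof.r_edges[:-1] ** 3)
        assert (prof.rho_d * vol).sum() == pytest.approx(n * 2.5, rel=1e-12)

    def test_uniform_background_recovered(self, rng):
        # one reference bead + an ideal-gas background of uniform density
        box = 10.0
        n_bg = 8000
        coords = np.concatenate(
            [np.full((1, 1, 3), box / 2), rng.uniform(0, box, (1, n_bg, 3))], axis=1
        )
        fr = frames_from(coords, [0] + [1] * n_bg, ["C"] * (n_bg + 1),
                         np.ones(n_bg + 1), box=box)
        prof = radial_density_profiles(fr, bin_width=0.5, reference_molecules=[0])
        rho0 = n_bg / box**3
        # reference molecule's own profile only probes its own bead; the
        # overlap profile must be flat at rho0 (skip the tiny first shells)
        mols = prof.rho_overlap[2:]
        # crude sampling errors per shell
        vol = 4 * np.pi / 3 * (prof.r_edges[1:] ** 3 - prof.r_edges[:-1] ** 3)
        sigma = np.sqrt(rho0 / vol[2:])
        assert np.all(np.abs(mols - rho0) < 4 * sigma + 1e-9)

    def test_distant_molecules_do_not_overlap(self):
        coords = np.array([[[1.0, 1, 1], [9.0, 9, 9]]])
        fr = frames_from(coords, [0, 1], ["C", "C"], [12.0, 12.0], box=20.0)
        prof = radial_density_profiles(fr, bin_width=0.5, r_max=5.0)
        assert np.all(prof.rho_overlap == 0)

    def test_wrapping_independence(self, rng):
        n = 6
        coords = 2.0 + 0.4 * rng.standard_normal((2, n, 3))
        fr = frames_from(coords, [0] * 3 + [1] * 3, ["C"] * n, np.ones(n), box=8.0)
        shifted = frames_from(np.mod(coords + 4.0, 8.0) - 0.0, [0] * 3 + [1] * 3,
                              ["C"] * n, np.ones(n), box=8.0)
        # same geometry modulo box translation+wrap => same profiles
        a = radial_density_profiles(fr, bin_width=0.25)
        b = radial_density_profiles(shifted, bin_width=0.25)
        assert np.allclose(a.rho_overlap, b.rho_overlap)

    def test_bins_beyond_half_box_truncated(self):
        fr = frames_from(np.zeros((1, 1, 3)), [0], ["C"], [1.0], box=4.0)
        with pytest.warns(UserWarning, match="half the box"):
            prof = radial_density_profiles(fr, bin_width=0.5, r_max=10.0)
        assert prof.r_edges.max() <= 2.0 + 1e-12
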