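"""Synthetic generators: BD melts, prescribed-spectrum stress, rotation, planting."""

import numpy as np
import pytest

from dendrorelax.constants import KB_KJ_MOL
from dendrorelax.stress import relaxation_modulus
from dendrorelax.synthetic.bd import BDParams, simulate_bead_spring_bd
from dendrorelax.synthetic.gpstress import PronySeries, generate_stress_gp, prony_from_powerlaw
from dendrorelax.synthetic.planted import plant_hbond_configuration
from dendrorelax.synthetic.rotational import generate_rotational_series
from dendrorelax.topology import connectivity_spectrum, gaussian_rg2, theoretical_relaxation_modulus
from dendrorelax.trajectory import gyration_series


class TestBeadSpringBD:
    def test_dumbbell_equipartition(self, dumbbell):
        k, temp = 2.0, 300.0
        p = BDParams(spring_constant=k, friction=1.0, temperature=temp,
                     timestep=0.002, n_steps=50000, coord_stride=10, seed=3)
        frames, _ = simulate_bead_spring_bd([dumbbell] * 32, p, box=30.0)
        b = frames.coords[:, 0::2, :] - frames.coords[:, 1::2, :]
        b2 = (b**2).sum(axis=2)
        mean = b2.mean()
        se = b2.mean(axis=0).std(ddof=1) / np.sqrt(b2.shape[1])
        assert abs(mean - 3 * KB_KJ_MOL * temp / k) < 3 * se

    def test_zero_temperature_freezes_everything(self, dumbbell):
        p = BDParams(temperature=0.0, n_steps=500, coord_stride=50, seed=1)
        frames, stress = simulate_bead_spring_bd([dumbbell] * 4, p, box=10.0)
        assert np.ptp(stress.components, axis=0).max() == 0.0
        assert np.allclose(frames.coords[0], frames.coords[-1])
        assert "zero-temperature" in stress.flags

    def test_seeded_determinism(self, dumbbell):
        p = BDParams(n_steps=200, seed=9)
        _, a = simulate_bead_spring_bd([dumbbell] * 3, p, box=10.0)
        _, b = simulate_bead_spring_bd([dumbbell] * 3, p, box=10.0)
        assert np.array_equal(a.components, b.components)
        _, c = simulate_bead_spring_bd([dumbbell] * 3, BDParams(n_steps=200, seed=10), box=10.0)
        assert not np.array_equal(a.components, c.components)

    def test_unstable_timestep_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            BDParams(spring_constant=100.0, friction=1.0, timestep=0.01)

    def test_empty_topology_list_rejected(self, dumbbell):
        with pytest.raises(ValueError, match="empty"):
            simulate_bead_spring_bd([], BDParams(), box=10.0)

    def test_g2_dendrimer_gyration_matches_gaussian_closed_form(self, g2_trifunctional):
        temp, k = 300.0, 1.0
        p = BDParams(spring_constant=k, friction=1.0, temperature=temp,
                     timestep=0.02, n_steps=60000, stress_stride=100,
                     coord_stride=20, seed=11)
        frames, _ = simulate_bead_spring_bd([g2_trifunctional] * 8, p, box=40.0)
        g = gyration_series(frames)
        rg2 = np.mean(g.rg_per_frame**2)
        per_mol = (g.rg_per_frame**2).mean(axis=0)
        se = per_mol.std(ddof=1) / np.sqrt(per_mol.size)
        assert abs(rg2 - gaussian_rg2(g2_trifunctional, temp, k)) < 3 * se

    def test_dumbbell_stress_acf_matches_normal_mode_oracle(self, dumbbell):
        # stress ACF of one harmonic spring: exp(-2t/tau), tau = zeta/(2K)
        k, zeta = 0.5, 1.0
        tau = zeta / (2 * k)
        p = BDParams(spring_constant=k, friction=zeta, temperature=300.0,
                     timestep=0.01, n_steps=1 << 17, stress_groups=128, seed=7)
        _, groups = simulate_bead_spring_bd([dumbbell] * 128, p, box=50.0)
        curves = [relaxation_modulus(s) for s in groups]
        t = curves[0].times
        mean = np.mean([c.values for c in curves], axis=0)
        mean /= mean[0]
        sel = (t >= 0.012) & (t <= 1.2)  # two decades of lag
        ref = np.exp(-2 * t[sel] / tau)
        assert np.max(np.abs(mean[sel] - ref) / ref) < 0.05

    def test_melt_modulus_matches_viscoelastic_theory(self, g2_trifunctional):
        # end-to-end: BD melt modulus vs the mode-sum prediction, within
        # Monte-Carlo error bars estimated from independent molecule groups
        temp, k, zeta, box = 300.0, 0.25, 1.0, 30.0
        n_mol = 24
        p = BDParams(spring_constant=k, friction=zeta, temperature=temp,
                     timestep=0.02, n_steps=1 << 17, stress_groups=n_mol, seed=5)
        _, groups = simulate_bead_spring_bd([g2_trifunctional] * n_mol, p, box=box)
        curves = [relaxation_modulus(s) for s in groups]
        t = curves[0].times
        vals = np.array([c.values for c in curves])
        mean, se = vals.mean(axis=0), vals.std(axis=0, ddof=1) / np.sqrt(n_mol)
        spectrum = connectivity_spectrum(g2_trifunctional, tau0=zeta / k)
        density = n_mol / box**3  # each group holds one molecule in V/n_mol
        sel = (t > 0) & (t <= 40.0)  # up to the slowest mode time
        theory = theoretical_relaxation_modulus(
            spectrum, density, temp, t[sel]).values
        z = (mean[sel] - theory) / se[sel]
        assert np.mean(np.abs(z)) < 2.0
        assert np.max(np.abs(z)) < 6.0


class TestGPStress:
    def test_maxwell_target_recovered(self):
        target = PronySeries(((50.0, 100.0),))
        s = generate_stress_gp(target, dt=1.0, n_frames=1 << 19, volume=100.0,
                               temperature=600.0, seed=3)
        curve = relaxation_modulus(s)
        gn = curve.values / curve.g0
        sel = (curve.times > 0) & (curve.times <= 300)
        ref = np.exp(-curve.times[sel] / 100.0)
        assert np.max(np.abs(gn[sel] - ref)) < 0.03  # Monte-Carlo error bound

    def test_g0_scale_matches_target(self):
        target = PronySeries(((50.0, 100.0),))
        s = generate_stress_gp(target, dt=1.0, n_frames=1 << 19, volume=100.0,
                               temperature=600.0, seed=4)
        assert relaxation_modulus(s).g0 == pytest.approx(target.g0, rel=0.05)

    def test_stationarity_between_halves(self):
        target = PronySeries(((30.0, 20.0),))
        s = generate_stress_gp(target, dt=1.0, n_frames=1 << 18, volume=100.0,
                               temperature=600.0, seed=6)
        half = s.n_frames // 2
        from dendrorelax.stress import StressSeries

        halves = [
            StressSeries(s.dt, s.components[:half], s.volume, s.temperature),
            StressSeries(s.dt, s.components[half:], s.volume, s.temperature),
        ]
        c1, c2 = (relaxation_modulus(h) for h in halves)
        sel = c1.values / c1.g0 > 0.1
        assert np.allclose(c1.values[sel], c2.values[sel],
                           rtol=0.15, atol=0.05 * c1.g0)

    def test_undersampled_mode_flagged(self):
        target = PronySeries(((10.0, 1.0),))
        s = generate_stress_gp(target, dt=1.0, n_frames=64, volume=10.0,
                               temperature=300.0, seed=0)
        assert "undersampled-mode" in s.flags

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="not realizable"):
            PronySeries(((-1.0, 10.0),))

    def test_seeded_determinism(self):
        target = PronySeries(((10.0, 5.0),))
        a = generate_stress_gp(target, 1.0, 256, 10.0, 300.0, seed=5)
        b = generate_stress_gp(target, 1.0, 256, 10.0, 300.0, seed=5)
        c = generate_stress_gp(target, 1.0, 256, 10.0, 300.0, seed=6)
        assert np.array_equal(a.components, b.components)
        assert not np.array_equal(a.components, c.components)

    def test_powerlaw_prony_tracks_power_law(self):
        target = prony_from_powerlaw(-0.45, (10.0, 1000.0), amplitude=100.0)
        t = np.geomspace(10, 1000, 60)
        ratio = target(t) / (100.0 * (t / 10.0) ** -0.45)
        assert np.max(np.abs(ratio - 1)) < 0.01

    def test_powerlaw_requires_negative_exponent(self):
        with pytest.raises(ValueError, match="exponent"):
            prony_from_powerlaw(0.45, (1.0, 100.0))


class TestRotationalSeries:
    def test_frozen_at_zero_diffusion(self):
        vs = generate_rotational_series(0.0, dt=1.0, n_frames=50, n_molecules=3, seed=1)
        assert np.allclose(vs.u, vs.u[0])

    def test_unit_norm_every_frame(self):
        vs = generate_rotational_series(0.1, dt=0.1, n_frames=500, n_molecules=5, seed=2)
        assert np.max(np.abs(np.linalg.norm(vs.u, axis=2) - 1)) < 1e-12

    def test_tau_rot_recovered_within_5pct(self):
        # D = 0.05/ps -> tau_rot = 1/(2D) = 10 ps
        from dendrorelax.trajectory import rotational_acf

        vs = generate_rotational_series(0.05, dt=0.1, n_frames=40000,
                                        n_molecules=32, seed=0)
        acf = rotational_acf(vs)
        assert acf.tau_rot == pytest.approx(10.0, rel=0.05)


class TestPlantedHBonds:
    def test_geometry_is_exact(self):
        fr = plant_hbond_configuration(4, [(0, 1, 0.3, 20.0)], box=8.0, seed=4)
        donor = next(i for i in range(fr.n_beads)
                     if fr.elements[i] == "N" and fr.molecule_id[i] == 0)
        acceptor = next(i for i in range(fr.n_beads) if fr.elements[i] == "O")
        d = fr.coords[0, acceptor] - fr.coords[0, donor]
        assert np.linalg.norm(d) == pytest.approx(0.3, abs=1e-12)
        h = donor + 1
        vh = fr.coords[0, h] - fr.coords[0, donor]
        cos = vh @ d / np.linalg.norm(vh) / np.linalg.norm(d)
        assert np.degrees(np.arccos(cos)) == pytest.approx(20.0, abs=1e-9)

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            plant_hbond_configuration(2, [(0, 1, 5.0, 0.0)], box=8.0)
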