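"""Coarse-grained force field, energies vs brute-force oracles, integrator."""

import numpy as np
import pytest

from condensaxs import cgsim
from condensaxs.cgsim import (KB, COULOMB, CGSystem, ForceField, SimConfig,
                              bonded_energy, compute_energy_forces, dh_energy,
                              init_lattice, kappa_from_salt, run_langevin,
                              wang_frenkel_energy, wf_minimum_location,
                              wf_potential)


@pytest.fixture(scope="module")
def ff():
    return ForceField.load(kappa=0.126)


def brute_force_energies(system, ff):
    """Pure-python reference for all three energy terms."""
    tidx = ff.type_index(system.bead_types)
    q = ff.charges[tidx]
    pos = system.positions
    box = system.box_edge
    n = len(pos)
    bonds = system.bonds()

    def mi(d):
        return d - box * np.round(d / box)

    e_bond = 0.0
    for i, j in bonds:
        r = np.linalg.norm(mi(pos[i] - pos[j]))
        rref = ff.rref[ff.classes[tidx[i]]]
        e_bond += ff.K * (r - rref) ** 2
    e_dh = e_wf = 0.0
    bonded = {(int(i), int(j)) for i, j in bonds}
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            r = np.linalg.norm(mi(pos[i] - pos[j]))
            if q[i] * q[j] != 0 and r < ff.coulomb_cutoff:
                e_dh += COULOMB / ff.epsilon_r * q[i] * q[j] / r * np.exp(-ff.kappa * r)
            ti, tj = tidx[i], tidx[j]
            if r < ff.wf_rc[ti, tj]:
                e_wf += float(wf_potential(r, ff.wf_eps[ti, tj], ff.wf_sigma[ti, tj],
                                           ff.wf_mu, ff.wf_nu, ff.wf_rc[ti, tj]))
    return e_bond, e_dh, e_wf


class TestKappa:
    def test_paper_salt_points(self):
        assert kappa_from_salt(0.6) == pytest.approx(0.253, abs=0.001)
        assert kappa_from_salt(0.15) == pytest.approx(0.126, abs=0.001)

    def test_zero_salt_unscreened(self):
        assert kappa_from_salt(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            kappa_from_salt(-0.1)


class TestBondedEnergy:
    def _dimer(self, r, types=("U", "U")):
        return CGSystem(positions=[[0, 0, 0], [r, 0, 0]], bead_types=list(types),
                        chain_ids=np.array([0, 0]), box_edge=100.0)

    def test_minimum_is_zero(self, ff):
        assert bonded_energy(self._dimer(5.0), ff) == pytest.approx(0.0, abs=1e-12)

    def test_one_angstrom_stretch(self, ff):
        assert bonded_energy(self._dimer(6.0), ff) == pytest.approx(9.6, rel=1e-9)

    def test_amino_reference_length(self, ff):
        assert bonded_energy(self._dimer(3.81, ("R", "P")), ff) == \
            pytest.approx(0.0, abs=1e-12)

    def test_multichain_matches_loop_oracle(self, ff, rng):
        sys10 = init_lattice(5, 5, 6, 80.0, conformation="coil")
        sys10.positions += rng.normal(0, 0.5, sys10.positions.shape)
        e = bonded_energy(sys10, ff)
        ref, _, _ = brute_force_energies(sys10, ff)
        assert e == pytest.approx(ref, abs=1e-10)


class TestDHEnergy:
    def test_unscreened_coulomb_limit(self):
        ff0 = ForceField.load(kappa=0.0)
        sys2 = CGSystem(positions=[[0, 0, 0], [8.0, 0, 0]], bead_types=["U", "R"],
                        chain_ids=np.array([0, 1]), box_edge=200.0)
        e = dh_energy(sys2, ff0)
        assert e == pytest.approx(-COULOMB / 80.0 / 8.0, rel=1e-12)

    def test_sign_symmetry(self, ff):
        pair = CGSystem(positions=[[0, 0, 0], [7.0, 0, 0]], bead_types=["U", "R"],
                        chain_ids=np.array([0, 1]), box_edge=200.0)
        like = CGSystem(positions=[[0, 0, 0], [7.0, 0, 0]], bead_types=["R", "R"],
                        chain_ids=np.array([0, 1]), box_edge=200.0)
        assert dh_energy(pair, ff) < 0
        assert dh_energy(like, ff) == pytest.approx(-dh_energy(pair, ff), rel=1e-12)

    def test_random_box_matches_brute_force(self, ff, rng):
        n = 50
        pos = rng.uniform(0, 40, size=(n, 3))
        types = list(rng.choice(["A", "U", "R", "P"], size=n))
        sysn = CGSystem(positions=pos, bead_types=types,
                        chain_ids=np.arange(n), box_edge=40.0)
        _, ref_dh, ref_wf = brute_force_energies(sysn, ff)
        assert dh_energy(sysn, ff) == pytest.approx(ref_dh, rel=1e-9)
        assert wang_frenkel_energy(sysn, ff) == pytest.approx(ref_wf, rel=1e-9)

    def test_overlap_rejected(self, ff):
        sys2 = CGSystem(positions=[[0, 0, 0], [0, 0, 1e-8]], bead_types=["U", "R"],
                        chain_ids=np.array([0, 1]), box_edge=50.0)
        with pytest.raises(FloatingPointError):
            dh_energy(sys2, ff)


class TestWangFrenkel:
    def test_zero_at_cutoff(self):
        assert wf_potential(3.0 * 6.8, 1.0, 6.8) == 0.0
        assert wf_potential(25.0, 1.0, 6.8) == 0.0

    def test_minimum_depth_is_eps(self):
        from scipy.optimize import minimize_scalar

        for sigma, eps in [(6.8, 3.5), (5.6, 0.5)]:
            rmin = wf_minimum_location(sigma)
            assert wf_potential(rmin, eps, sigma) == pytest.approx(-eps, abs=1e-9)
            res = minimize_scalar(lambda r: float(wf_potential(r, eps, sigma)),
                                  bounds=(0.8 * sigma, 3 * sigma), method="bounded")
            assert res.fun == pytest.approx(-eps, abs=1e-9)
            assert res.x == pytest.approx(rmin, abs=1e-4)

    def test_adenine_well_deeper_than_uracil(self, ff):
        names = ff.type_names
        a, u, c = names.index("A"), names.index("U"), names.index("C")
        assert ff.wf_eps[a, a] > ff.wf_eps[u, u]
        assert ff.wf_eps[a, a] > ff.wf_eps[c, c]


class TestInitLattice:
    def test_eight_chains_cubic(self):
        sys8 = init_lattice(4, 4, 2, 100.0)
        centers = np.array([sys8.positions[sys8.chain_ids == c].mean(0)
                            for c in range(8)])
        expected = np.array([[(i + 0.5) * 50, (j + 0.5) * 50, (k + 0.5) * 50]
                             for k in range(2) for j in range(2) for i in range(2)])
        assert np.allclose(np.sort(centers, axis=0), np.sort(expected, axis=0))

    def test_single_chain_centered(self):
        sys1 = init_lattice(1, 0, 4, 60.0)
        assert np.allclose(sys1.positions.mean(0), [30.0, 30.0, 30.0], atol=1e-9)

    def test_no_close_interchain_contacts(self):
        for conf in ("straight", "coil"):
            sysn = init_lattice(6, 12, 12, 300.0 if conf == "straight" else 100.0,
                                conformation=conf)
            from scipy.spatial import cKDTree

            tree = cKDTree(sysn.positions, boxsize=sysn.box_edge)
            for i, j in tree.query_pairs(2.0):
                assert sysn.chain_ids[i] == sysn.chain_ids[j]

    def test_overfilled_box_rejected(self):
        with pytest.raises(ValueError):
            init_lattice(100, 100, 30, 20.0)


class TestLangevin:
    def test_thermostat_equipartition(self):
        """Free beads thermalize to within 5% of 298 K."""
        ff = ForceField.load()
        n = 30
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 200, size=(n, 3))
        sysn = CGSystem(positions=pos, bead_types=["U"] * n,
                        chain_ids=np.arange(n), box_edge=200.0)
        cfg = SimConfig(box_edge=200.0, n_steps=20000, relaxation_ps=5.0,
                        c_na=0.15, seed=3, save_stride=100)
        traj = run_langevin(sysn, ff, cfg)
        t_mean = float(np.mean(traj.temperatures[20:]))
        assert t_mean == pytest.approx(298.0, rel=0.05)

    def test_damped_dimer_relaxes_to_bond_length(self):
        ff = ForceField.load()
        sys2 = CGSystem(positions=[[0, 0, 0], [7.0, 0, 0]], bead_types=["P", "P"],
                        chain_ids=np.array([0, 0]), box_edge=100.0)
        cfg = SimConfig(box_edge=100.0, n_steps=20000, dt_fs=10.0, temperature=0.0,
                        relaxation_ps=1.0, c_na=0.15, seed=0, save_stride=20000)
        traj = run_langevin(sys2, ff, cfg, velocities=np.zeros((2, 3)))
        d = np.linalg.norm(traj.frames[-1][0] - traj.frames[-1][1])
        assert d == pytest.approx(ff.rref["amino"], abs=1e-3)

    def test_zero_friction_conserves_energy(self):
        """With no thermostat the integrator is velocity Verlet: the total
        energy of a bonded dimer drifts by < 1% over 1e5 steps at 1 fs."""
        ff = ForceField.load(kappa=0.126)
        sys2 = CGSystem(positions=[[0, 0, 0], [5.6, 0, 0]], bead_types=["U", "U"],
                        chain_ids=np.array([0, 0]), box_edge=100.0)
        v0 = np.array([[0.05, 0.0, 0.0], [-0.05, 0.0, 0.0]])
        tidx = ff.type_index(sys2.bead_types)
        m = ff.masses[tidx]

        def total_energy(pos, vel):
            s = CGSystem(pos, sys2.bead_types, sys2.chain_ids, 100.0)
            e, _ = compute_energy_forces(s, ff)
            return sum(e.values()) + 0.5 * float(np.sum(m[:, None] * vel**2))

        e0 = total_energy(sys2.positions, v0)
        c_na = (0.126 * 3.06) ** 2  # reproduces kappa = 0.126 1/A
        cfg2 = SimConfig(box_edge=100.0, n_steps=100_000, dt_fs=1.0,
                         relaxation_ps=0.0, c_na=c_na, seed=0, save_stride=1000)
        traj2 = run_langevin(sys2, ff, cfg2, velocities=v0)
        kin = KB * 3.0 * traj2.temperatures * 2 / 2.0  # 2 beads, 3/2 kT each
        pots = []
        for fr in traj2.frames:
            s = CGSystem(fr, sys2.bead_types, sys2.chain_ids, 100.0)
            e, _ = compute_energy_forces(s, ff)
            pots.append(sum(e.values()))
        total = np.array(pots) + kin
        assert np.max(np.abs(total - e0)) < 0.01 * max(abs(e0), np.abs(total).max())

    def test_random_impulse_zero_mean(self):
        """Free-particle velocity under the thermostat has zero mean (3 sigma)."""
        ff = ForceField.load()
        sys1 = CGSystem(positions=[[50.0, 50, 50]], bead_types=["A"],
                        chain_ids=np.array([0]), box_edge=100.0)
        cfg = SimConfig(box_edge=100.0, n_steps=40000, relaxation_ps=1.0,
                        c_na=0.15, seed=5, save_stride=40)
        traj = run_langevin(sys1, ff, cfg)
        disp = np.diff(traj.frames[:, 0, :], axis=0)
        disp -= 100.0 * np.round(disp / 100.0)
        mean = disp.mean(axis=0)
        se = disp.std(axis=0) / np.sqrt(disp.shape[0])
        assert np.all(np.abs(mean) < 3 * se + 1e-9)

    def test_bound_pair_lifetime_decreases_with_salt(self):
        """A +1/-1 dimer stays bound longer at low salt (5-seed median)."""
        ff = ForceField.load()

        def bound_fraction(salt, seed):
            sys2 = CGSystem(positions=[[30.0, 30, 30], [36.0, 30, 30]],
                            bead_types=["U", "R"], chain_ids=np.array([0, 1]),
                            box_edge=60.0)
            cfg = SimConfig(box_edge=60.0, n_steps=50000, relaxation_ps=5.0,
                            c_na=salt, seed=seed, save_stride=50)
            traj = run_langevin(sys2, ff, cfg)
            d = traj.frames[:, 0, :] - traj.frames[:, 1, :]
            d -= 60.0 * np.round(d / 60.0)
            return float(np.mean(np.linalg.norm(d, axis=1) < 10.0))

        low = np.median([bound_fraction(0.0, s) for s in range(5)])
        high = np.median([bound_fraction(0.6, s) for s in range(5)])
        assert low >= high

    def test_force_blowup_aborts(self):
        ff = ForceField.load()
        sys2 = CGSystem(positions=[[0, 0, 0], [0.5, 0, 0]], bead_types=["A", "A"],
                        chain_ids=np.array([0, 1]), box_edge=50.0)
        cfg = SimConfig(box_edge=50.0, n_steps=100, relaxation_ps=5.0,
                        c_na=0.15, seed=0, save_stride=10)
        with pytest.raises(FloatingPointError):
            run_langevin(sys2, ff, cfg)


class TestTrajectoryIO:
    def test_xyz_round_trip(self, tmp_path):
        ff = ForceField.load()
        sysn = init_lattice(2, 2, 3, 60.0, conformation="coil")
        cfg = SimConfig(box_edge=60.0, n_steps=200, relaxation_ps=5.0,
                        c_na=0.15, seed=1, save_stride=100)
        traj = run_langevin(sysn, ff, cfg)
        traj.write_xyz(tmp_path / "t.xyz")
        back = cgsim.Trajectory.read_xyz(tmp_path / "t.xyz")
        assert back.frames.shape == traj.frames.shape
        assert np.allclose(back.frames, traj.frames, atol=1e-5)
        assert back.box_edge == traj.box_edge
        assert np.array_equal(back.chain_ids, traj.chain_ids)

    def test_hdf5_round_trip(self, tmp_path):
        traj = cgsim.Trajectory(frames=np.zeros((2, 3, 3)),
                                chain_ids=np.array([0, 0, 1]), box_edge=50.0,
                                times=np.array([0.0, 1.0]),
                                bead_types=["A", "A", "R"])
        traj.write_hdf5(tmp_path / "t.h5")
        back = cgsim.Trajectory.read_hdf5(tmp_path / "t.h5")
        assert np.array_equal(back.frames, traj.frames)
        assert back.bead_types == traj.bead_types
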