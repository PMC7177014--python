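"""Force correctness, integrator behavior, thermostat and tension."""
import numpy as np
import pytest

from memthin import (
    RunSettings,
    Simulation,
    ThinningFieldParams,
    ZoneGeometry,
    build_bilayer,
    compute_forces,
    measure_lateral_tension,
)
from memthin.dynamics import NeighborList, minimize
from memthin.system import MembraneSystem
from memthin.units import KB

GEOM = ZoneGeometry(X_box=12.0, A_thin=3.0, A_buffer=2.0)


def membrane(seed=1, apl=0.255):
    s = build_bilayer(
        GEOM, {"POPC": 1.0}, area_per_lipid=apl, seed=seed, box_y=3.6, box_z=9.0
    )
    minimize(s, n_steps=250)
    return s


def free_beads(n=64, box=6.0, seed=0):
    """Non-interacting point beads (ideal gas)."""
    rng = np.random.default_rng(seed)
    t = 1
    return MembraneSystem(
        pos=rng.uniform(0, box, (n, 3)),
        vel=np.zeros((n, 3)),
        mass=np.full(n, 18.0),
        box=np.full(3, float(box)),
        ptype=np.zeros(n, np.int64),
        mol_id=np.arange(n),
        is_tail=np.zeros(n, bool),
        is_head=np.zeros(n, bool),
        leaflet=np.zeros(n, np.int8),
        lipid_id=np.full(n, -1),
        species_of_lipid=np.array([]),
        type_sigma=np.full(t, 0.01),
        pair_eps=np.zeros((t, t)),
        pair_sigma=np.full((t, t), 0.01),
        attraction_width=0.1,
        bonds=np.empty((0, 2), np.int64),
        bond_k=np.empty(0),
        bond_r0=np.empty(0),
        angles=np.empty((0, 3), np.int64),
        angle_k=np.empty(0),
        geom=ZoneGeometry(6.0, 2.0, 1.0),
    )


class TestForces:
    def test_forces_are_energy_gradient(self):
        """Analytic forces match -dE/dx by central differences."""
        s = membrane()
        nl = NeighborList(s, 0.5)
        rep = compute_forces(s, nlist=nl)
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(6):
            i = int(rng.integers(0, s.n_beads))
            d = int(rng.integers(0, 3))
            p0 = s.pos[i, d]
            s.pos[i, d] = p0 + h
            ep = compute_forces(s, nlist=nl).epot
            s.pos[i, d] = p0 - h
            em = compute_forces(s, nlist=nl).epot
            s.pos[i, d] = p0
            fnum = -(ep - em) / (2 * h)
            assert rep.forces[i, d] == pytest.approx(fnum, abs=2e-4, rel=1e-5)

    def test_newtons_third_law(self):
        """Internal forces sum to zero; the external field breaks it by
        exactly the sum of the per-bead thinning forces."""
        s = membrane()
        rep = compute_forces(s)
        np.testing.assert_allclose(rep.forces.sum(axis=0), 0.0, atol=1e-9)
        field = ThinningFieldParams(k=20.0, D=0.6)
        rep2 = compute_forces(s, field=field)
        total = rep2.forces.sum(axis=0)
        assert total[0] == pytest.approx(0.0, abs=1e-9)
        assert total[1] == pytest.approx(0.0, abs=1e-9)
        assert total[2] == pytest.approx(rep2.field_force_sum, abs=1e-9)

    def test_bonded_pair_at_rest_length(self):
        s = membrane()
        # move one bond to its exact rest geometry and confirm zero force
        i, j = s.bonds[0]
        rep = compute_forces(s)
        # instead: potential-only check via a two-bead toy
        toy = free_beads(n=2)
        toy.bonds = np.array([[0, 1]])
        toy.bond_k = np.array([800.0])
        toy.bond_r0 = np.array([0.5])
        toy.pos[0] = [1.0, 1.0, 1.0]
        toy.pos[1] = [1.5, 1.0, 1.0]
        rep = compute_forces(toy)
        np.testing.assert_allclose(rep.forces, 0.0, atol=1e-10)

    def test_nonfinite_positions_raise(self):
        s = membrane()
        s.pos[5, 2] = np.nan
        with pytest.raises(RuntimeError):
            compute_forces(s)


class TestIntegrator:
    def test_ballistic_limit(self):
        """No forces, no friction, no noise: straight-line motion."""
        s = free_beads()
        rng = np.random.default_rng(3)
        s.vel = rng.normal(0, 0.1, s.vel.shape)
        v0 = s.vel.copy()
        x0 = s.pos.copy()
        sim = Simulation(s, RunSettings(dt=0.01, T=1e-9, friction=0.0, seed=1))
        sim.step(100)
        np.testing.assert_allclose(s.vel, v0, atol=1e-9)
        expect = (x0 + v0 * 100 * 0.01) % s.box
        np.testing.assert_allclose(s.pos, expect, atol=1e-9)

    def test_deterministic_trajectory(self):
        runs = []
        for _ in range(2):
            s = membrane(seed=4)
            sim = Simulation(s, RunSettings(seed=9))
            sim.step(50)
            runs.append(s.pos.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_energy_conservation_without_thermostat(self):
        s = membrane()
        sim = Simulation(s, RunSettings(dt=0.005, friction=0.0, seed=2))
        e0 = sim.kinetic_energy() + sim.report.epot
        sim.step(800)
        e1 = sim.kinetic_energy() + sim.report.epot
        assert abs(e1 - e0) < 0.002 * abs(e0)

    def test_equipartition_field_off(self):
        """Mean kinetic energy per DOF ~ kBT/2 under the thermostat."""
        s = free_beads(n=400)
        sim = Simulation(s, RunSettings(dt=0.01, T=310.0, friction=1.0, seed=7))
        sim.step(300)
        temps = []
        for _ in range(60):
            sim.step(10)
            temps.append(sim.instantaneous_T())
        t = np.asarray(temps)
        se = t.std(ddof=1) / np.sqrt(t.size)
        # serial correlation inflates the naive SE; allow 3x margin
        assert abs(t.mean() - 310.0) < max(3 * 3 * se, 6.0)

    def test_field_with_zero_k_matches_field_off(self):
        """k = 0 must be bitwise identical to no field at all (null test)."""
        a = membrane(seed=6)
        b = membrane(seed=6)
        sim_a = Simulation(a, RunSettings(seed=13), field=None)
        sim_b = Simulation(
            b, RunSettings(seed=13), field=ThinningFieldParams(k=0.0, D=0.6)
        )
        sim_a.step(60)
        sim_b.step(60)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_blowup_detected(self):
        s = membrane()
        s.vel[0] = [0.0, 0.0, 500.0]
        sim = Simulation(s, RunSettings(dt=0.01, seed=1))
        with pytest.raises(RuntimeError, match="blow-up"):
            sim.step(5)


class TestLateralTension:
    def test_ideal_gas_is_tensionless(self):
        s = free_beads(n=400)
        sim = Simulation(s, RunSettings(dt=0.01, friction=1.0, seed=5))
        sim.step(300)
        series = []
        for _ in range(40):
            sim.step(10)
            series.append(sim.instantaneous_tension())
        g, se = measure_lateral_tension(np.asarray(series))
        assert abs(g) < max(5 * se, 5.0)

    def test_sign_tracks_area(self):
        """Compressed membrane -> negative tension; stretched -> positive."""
        out = {}
        for apl in (0.22, 0.30):
            s = membrane(seed=2, apl=apl)
            sim = Simulation(s, RunSettings(seed=3))
            sim.step(4000)
            series = []
            for _ in range(20):
                sim.step(100)
                series.append(sim.instantaneous_tension())
            out[apl], _ = measure_lateral_tension(np.asarray(series))
        assert out[0.22] < 0 < out[0.30]

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            measure_lateral_tension(np.arange(5.0), n_blocks=10)
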