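"""Engine physics: forces, switching function, integrator, barostat."""

import numpy as np
import pytest

from conftest import brute_force_reference
from lnpsim.engine import (
    ForceCalculator,
    RunConfig,
    StabilityError,
    compute_energy_forces,
    run_simulation,
    step_langevin,
)
from lnpsim.system import (
    SystemSpec,
    SystemState,
    build_system,
    compile_system,
    minimize_energy,
)
from lnpsim.topology import BeadSpec, MoleculeTopology
from lnpsim.units import KB


def _pair_state(tables, r, box=4.0, bead_type="C1"):
    bead = MoleculeTopology("probe", [BeadSpec("X", bead_type)],
                           reference_positions=np.zeros((1, 3)))
    topo = compile_system([bead, bead], tables)
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    return SystemState(pos, np.zeros_like(pos), box, topo)


class TestLJPair:
    def test_energy_zero_at_sigma(self, tables):
        state = _pair_state(tables, 0.47)
        _, rep = compute_energy_forces(state, tables)
        assert rep.lj == pytest.approx(0.0, abs=1e-12)

    def test_zero_beyond_cutoff(self, tables):
        state = _pair_state(tables, 1.5)
        forces, rep = compute_energy_forces(state, tables)
        assert rep.lj == 0.0
        assert np.all(forces == 0.0)

    def test_switch_is_c1_continuous(self, tables):
        """Force equals the numerical derivative of the pair energy
        across the switch region and both endpoints."""
        def pair_energy(r):
            _, rep = compute_energy_forces(_pair_state(tables, r), tables)
            return rep.lj

        for r in (0.9, 0.999, 1.0, 1.001, 1.2, 1.399, 1.41):
            h = 1e-6
            f_num = -(pair_energy(r + h) - pair_energy(r - h)) / (2 * h)
            forces, _ = compute_energy_forces(_pair_state(tables, r), tables)
            assert forces[1, 0] == pytest.approx(f_num, rel=1e-4, abs=1e-6)

    def test_potential_continuous_at_switch_start(self, tables):
        e = lambda r: compute_energy_forces(_pair_state(tables, r), tables)[1].lj
        assert e(1.0 - 1e-9) == pytest.approx(e(1.0 + 1e-9), abs=1e-6)


class TestForceOracle:
    def test_neighbor_list_matches_brute_force_water(self, tables, water_box_topology, rng):
        calc = ForceCalculator(water_box_topology, tables)
        for _ in range(20):
            pos = rng.uniform(0, 3.0, size=(50, 3))
            calc.invalidate()
            forces, part = calc.compute(pos, 3.0)
            e_ref, f_ref = brute_force_reference(pos, 3.0, water_box_topology)
            scale = max(np.abs(f_ref).max(), 1.0)
            assert np.abs(forces - f_ref).max() / scale < 1e-9
            assert part.potential == pytest.approx(e_ref, rel=1e-9)

    def test_cell_list_path_matches_brute_force(self, tables, rng):
        """Big enough box to take the cell-list code path (includes
        bonded molecules, angles and ring restraints)."""
        spec = SystemSpec(2, 1, 150, 15, 5.4, seed=9, name="cells")
        state = build_system(spec, tables=tables)
        calc = ForceCalculator(state.topology, tables)
        assert int(state.box / (0.5 * calc.r_list)) >= 5
        forces, part = calc.compute(state.positions, state.box)
        e_ref, f_ref = brute_force_reference(state.positions, state.box, state.topology)
        assert np.abs(forces - f_ref).max() / np.abs(f_ref).max() < 1e-9
        assert part.potential == pytest.approx(e_ref, rel=1e-9)

    def test_translation_invariance(self, tables, small_mixed_state):
        state = small_mixed_state
        _, rep0 = compute_energy_forces(state, tables)
        shifted = state.copy()
        shifted.positions += np.array([1.234, -0.777, 2.5])
        shifted.wrap()
        _, rep1 = compute_energy_forces(shifted, tables)
        for term in ("bond", "angle", "lj"):
            assert getattr(rep1, term) == pytest.approx(
                getattr(rep0, term), rel=1e-9, abs=1e-9
            )

    def test_newtons_third_law(self, tables, small_mixed_state):
        forces, _ = compute_energy_forces(small_mixed_state, tables)
        scale = np.abs(forces).max()
        assert np.abs(forces.sum(axis=0)).max() / scale < 1e-9

    def test_energy_report_sums(self, tables, small_mixed_state):
        _, rep = compute_energy_forces(small_mixed_state, tables)
        assert rep.total == pytest.approx(
            rep.bond + rep.angle + rep.lj + rep.kinetic, rel=1e-12
        )
        assert rep.instantaneous_temperature >= 0


class TestIntegrator:
    def test_zero_force_fixed_point(self, tables):
        """gamma=0, isolated pair at the LJ minimum, zero velocities:
        nothing moves."""
        state = _pair_state(tables, 2 ** (1 / 6) * 0.47)
        cfg = RunConfig(n_steps=0, thermostat_gamma=0.0, seed=0)
        before = state.positions.copy()
        out = state
        for _ in range(50):
            out = step_langevin(out, cfg, tables)
        assert np.allclose(out.positions, before, atol=1e-10)

    def test_nve_reduces_to_velocity_verlet_energy_conservation(self, tables):
        spec = SystemSpec(4, 0, 120, 12, 3.6, seed=21, name="nve-small")
        state = build_system(spec, tables=tables)
        state = minimize_energy(state, tables, max_steps=600, tol=20.0)
        # brief thermalization, then an NVE segment
        run_simulation(state, RunConfig(n_steps=500, seed=21, output_stride=500), tables)
        cfg = RunConfig(n_steps=2000, thermostat_gamma=0.0, seed=21,
                        output_stride=2000, series_stride=10)
        traj = run_simulation(state, cfg, tables)
        e = np.asarray(traj.series["total"])
        ke = np.asarray(traj.series["kinetic"])
        drift = abs(np.mean(e[-20:]) - np.mean(e[:20]))
        assert drift < 0.005 * np.mean(ke)

    def test_empty_run_returns_initial_frame(self, tables, small_mixed_state):
        traj = run_simulation(small_mixed_state, RunConfig(n_steps=0, seed=0), tables)
        assert traj.n_frames == 1
        assert traj.frames[0].time_ps == 0.0

    def test_seeded_determinism_bit_identical(self, tables):
        spec = SystemSpec(2, 0, 80, 8, 3.4, seed=13, name="det")
        cfg = RunConfig(n_steps=300, barostat=True, seed=13, output_stride=100)
        results = []
        for _ in range(2):
            state = build_system(spec, tables=tables)
            traj = run_simulation(state, cfg, tables)
            results.append((state.positions.copy(), state.box, traj.series["total"][-1]))
        assert np.array_equal(results[0][0], results[1][0])
        assert results[0][1] == results[1][1]
        assert results[0][2] == results[1][2]

    def test_oversized_step_raises_stability_error(self, tables, small_mixed_state):
        state = small_mixed_state.copy()
        state.velocities[:] = 50.0  # nm/ps, absurd
        cfg = RunConfig(n_steps=10, thermostat_gamma=0.0, seed=0)
        with pytest.raises(StabilityError) as err:
            run_simulation(state, cfg, tables)
        assert err.value.step is not None

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            RunConfig(dt=-1.0)
        with pytest.raises(ValueError):
            RunConfig(lj_switch_start=1.5, lj_cutoff=1.4)
        with pytest.raises(ValueError):
            RunConfig(neighbor_skin=0.0)


class TestPressureAndBarostat:
    def test_dilute_gas_pressure_near_ideal(self, tables, rng):
        """Virial pressure of a dilute LJ gas approaches N kT / V."""
        from lnpsim.topology import build_water_bead

        topo = compile_system([build_water_bead("P4")] * 64, tables)
        L = 12.0
        g = (np.arange(4) + 0.5) * (L / 4)
        pos = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
        state = SystemState(pos, np.zeros((64, 3)), L, topo)
        state.velocities = rng.normal(size=(64, 3)) * np.sqrt(KB * 310 / 72.0)
        _, rep = compute_energy_forces(state, tables)
        from lnpsim.units import pressure_to_atm

        p_ideal = pressure_to_atm(2 * state.kinetic_energy() / (3 * L**3))
        assert rep.instantaneous_pressure == pytest.approx(p_ideal, rel=0.01)

    def test_barostat_keeps_box_stable_on_bulk_water(self, tables):
        spec = SystemSpec(0, 0, 300, 30, 3.6, seed=17, name="npt")
        state = build_system(spec, tables=tables)
        state = minimize_energy(state, tables, max_steps=500, tol=30.0)
        cfg = RunConfig(n_steps=12000, barostat=True, seed=17,
                        output_stride=12000, series_stride=40)
        traj = run_simulation(state, cfg, tables)
        box = np.asarray(traj.series["box"])
        second_half = box[box.size // 2:]
        # no monotonic drift over the final half
        thirds = np.array_split(second_half, 3)
        means = [t.mean() for t in thirds]
        assert not (means[0] < means[1] < means[2]) or abs(means[2] - means[0]) < 0.05
        assert not (means[0] > means[1] > means[2]) or abs(means[0] - means[2]) < 0.05
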