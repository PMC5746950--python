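"""Structural observables: shape, clusters, interior water, coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnpsim import analysis
from lnpsim.system import SystemState, compile_system
from lnpsim.topology import BeadSpec, MoleculeTopology


def _octahedron():
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )


def _rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestRadiusOfGyration:
    def test_single_bead_is_zero(self):
        assert analysis.radius_of_gyration(np.array([[3.0, 1.0, 2.0]])) == 0.0

    def test_symmetric_dimer_half_separation(self):
        pos = np.array([[0.0, 0, 0], [1.8, 0, 0]])
        assert analysis.radius_of_gyration(pos, [72, 72]) == pytest.approx(0.9)

    def test_mass_weighting_shifts_com(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        rg = analysis.radius_of_gyration(pos, [3.0, 1.0])
        # COM at 0.25; Rg^2 = (3*0.0625 + 1*0.5625)/4
        assert rg == pytest.approx(np.sqrt(0.1875))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            analysis.radius_of_gyration(np.empty((0, 3)))


class TestAsphericity:
    def test_isotropic_octahedron_is_spherical(self):
        assert analysis.asphericity(_octahedron()).delta == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 12])
    def test_collinear_rod_limit(self, n):
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * 0.37
        res = analysis.asphericity(pos)
        assert res.delta == pytest.approx(1.0, abs=1e-9)
        assert res.principal_radii[1] == pytest.approx(0.0, abs=1e-7)

    def test_planar_configuration_degenerate_not_error(self):
        pos = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float)
        res = analysis.asphericity(pos)
        assert res.principal_radii[2] == pytest.approx(0.0, abs=1e-9)
        assert 0.0 <= res.delta <= 1.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_rg_squared_equals_sum_of_principal_radii(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(size=(12, 3))
        masses = rng.uniform(1, 5, size=12)
        res = analysis.asphericity(pos, masses)
        assert res.rg**2 == pytest.approx(sum(r**2 for r in res.principal_radii),
                                          rel=1e-9)
        assert res.rg == pytest.approx(analysis.radius_of_gyration(pos, masses),
                                       rel=1e-9)
        assert 0.0 <= res.delta <= 1.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_delta_invariant_under_rigid_motion_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(size=(15, 3))
        d0 = analysis.asphericity(pos).delta
        moved = 2.7 * (pos @ _rotation(rng).T) + rng.normal(size=3)
        assert analysis.asphericity(moved).delta == pytest.approx(d0, abs=1e-9)

    def test_matches_independent_tensor_construction(self, rng):
        """Eigenvalues recomputed from an explicitly assembled outer-
        product tensor agree with the production path."""
        for _ in range(50):
            pos = rng.normal(size=(10, 3))
            m = rng.uniform(1, 3, size=10)
            res = analysis.asphericity(pos, m)
            com = (m[:, None] * pos).sum(0) / m.sum()
            t = np.zeros((3, 3))
            for i in range(10):
                d = pos[i] - com
                t += m[i] * np.outer(d, d)
            t /= m.sum()
            radii = np.sqrt(np.clip(np.linalg.eigvalsh(t), 0, None))[::-1]
            rm = radii.mean()
            delta_ref = 1.5 * np.sum((radii - rm) ** 2) / radii.sum() ** 2
            assert res.delta == pytest.approx(delta_ref, abs=1e-9)


class TestLipidNumberDensity:
    def test_closed_form(self):
        assert analysis.lipid_number_density(1, 1.0) == pytest.approx(
            3 / (4 * np.pi), rel=1e-12
        )

    @pytest.mark.parametrize(
        "n, rg, expected", [(64, 2.5, 0.98), (216, 3.7, 1.02), (392, 4.6, 0.96)]
    )
    def test_published_table_values(self, n, rg, expected):
        assert analysis.lipid_number_density(n, rg, ndigits=2) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            analysis.lipid_number_density(10, 0.0)
        with pytest.raises(ValueError):
            analysis.lipid_number_density(0, 1.0)


# ---------------------------------------------------------------------------
# cluster detection


def _point_molecule_state(positions, box, species="tripalmitin", tables=None):
    """One single-bead molecule per position, labelled as the given
    species (test scaffolding for cluster/coverage fixtures)."""
    from lnpsim.forcefield import default_forcefield

    tables = tables or default_forcefield()
    mol = MoleculeTopology(species, [BeadSpec("X", "C1")],
                          reference_positions=np.zeros((1, 3)))
    topo = compile_system([mol] * len(positions), tables)
    pos = np.mod(np.asarray(positions, dtype=float), box)
    return SystemState(pos, np.zeros_like(pos), box, topo)


class TestClusters:
    def test_isolated_molecules_form_singletons(self):
        pos = [[1, 1, 1], [3, 3, 3], [5, 5, 5]]
        state = _point_molecule_state(pos, 7.0)
        res = analysis.detect_aggregates(state, contact_cutoff=0.6)
        assert res.n_clusters == 3
        assert res.largest_cluster_size == 1

    def test_contact_through_periodic_boundary(self):
        state = _point_molecule_state([[0.1, 1, 1], [6.9, 1, 1]], 7.0)
        res = analysis.detect_aggregates(state, contact_cutoff=0.6)
        assert res.n_clusters == 1

    def test_matches_brute_force_union_find(self, rng):
        """Connected components identical to an all-pairs union-find on
        random 20-molecule configurations."""
        for _ in range(25):
            box = 5.0
            pos = rng.uniform(0, box, size=(20, 3))
            state = _point_molecule_state(pos, box)
            res = analysis.detect_aggregates(state, contact_cutoff=0.8)
            parent = list(range(20))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for i in range(20):
                for j in range(i + 1, 20):
                    d = pos[i] - pos[j]
                    d -= box * np.rint(d / box)
                    if np.linalg.norm(d) < 0.8:
                        parent[find(i)] = find(j)
            ref = [find(i) for i in range(20)]
            got = res.labels
            # same partition: label pairs agree
            for i in range(20):
                for j in range(i + 1, 20):
                    assert (ref[i] == ref[j]) == (got[i] == got[j])

    def test_cutoff_must_be_positive(self):
        state = _point_molecule_state([[1, 1, 1]], 5.0)
        with pytest.raises(ValueError):
            analysis.detect_aggregates(state, contact_cutoff=0.0)


def test_make_whole_restores_bonds_across_boundary(tables):
    from lnpsim.topology import build_tripalmitin

    topo = compile_system([build_tripalmitin(tables)], tables)
    ref = build_tripalmitin(tables).reference_positions.copy()
    box = 4.0
    shifted = np.mod(ref + np.array([box - 0.4, 0.0, 0.0]), box)  # split in x
    state = SystemState(shifted, np.zeros_like(shifted), box, topo)
    whole = analysis.make_whole(state.positions, box, topo)
    for (i, j), r0 in zip(topo.bonds, topo.bond_r0):
        d = np.linalg.norm(whole[i] - whole[j])
        assert d < 1.0, "bond should be contiguous after make_whole"


# ---------------------------------------------------------------------------
# interior water


def _fibonacci_sphere(n, radius):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return radius * np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def _hollow_sphere_state(k_inside, n_outside, tables, radius=1.8, box=7.0, seed=0):
    """Closed shell of lipid-labelled beads with known interior/exterior
    water placement (synthetic fixture with an exact answer)."""
    rng = np.random.default_rng(seed)
    n_shell = int(4 * np.pi * radius**2 / 0.22**2 * 0.55)
    shell = _fibonacci_sphere(n_shell, radius) + box / 2

    inside = rng.uniform(-0.55, 0.55, size=(k_inside, 3)) + box / 2
    out_dirs = _fibonacci_sphere(n_outside, 1.0)
    outside = out_dirs * rng.uniform(radius + 1.0, box / 2 - 0.3,
                                     size=(n_outside, 1)) + box / 2

    lipid = MoleculeTopology("tripalmitin", [BeadSpec("S", "C1")],
                            reference_positions=np.zeros((1, 3)))
    water = MoleculeTopology("water_p4", [BeadSpec("W", "P4")],
                            reference_positions=np.zeros((1, 3)))
    af = MoleculeTopology("water_af", [BeadSpec("W", "AF")],
                         reference_positions=np.zeros((1, 3)))
    n_af_in = max(1, k_inside // 5)
    mols = (
        [lipid] * n_shell
        + [water] * (k_inside - n_af_in) + [af] * n_af_in
        + [water] * n_outside
    )
    topo = compile_system(mols, tables)
    pos = np.vstack([shell, inside[: k_inside - n_af_in],
                     inside[k_inside - n_af_in:], outside])
    state = SystemState(np.mod(pos, box), np.zeros_like(pos), box, topo)
    return state, n_af_in


class TestInteriorWater:
    @pytest.mark.parametrize("voxel", [0.2, 0.35, 0.5])
    def test_hollow_sphere_recovers_exact_count(self, tables, voxel):
        k = 17
        state, n_af_in = _hollow_sphere_state(k, 40, tables, seed=3)
        part = analysis.classify_interior_water(state, voxel=voxel)
        assert part.n_inside == k
        assert part.n_outside == 40
        assert part.n_af_inside == n_af_in
        assert part.n_p4_inside == k - n_af_in
        assert part.n_inside + part.n_outside == part.water_bead_ids.size

    def test_enclosed_bead_inside_bulk_bead_outside(self, tables):
        state, _ = _hollow_sphere_state(1, 1, tables, seed=4)
        part = analysis.classify_interior_water(state, voxel=0.3)
        assert part.n_inside == 1 and part.n_outside == 1

    def test_invariant_under_box_translation(self, tables):
        state, _ = _hollow_sphere_state(9, 30, tables, seed=5)
        base = analysis.classify_interior_water(state, voxel=0.3)
        moved = state.copy()
        moved.positions += np.array([2.31, -1.17, 4.05])
        moved.wrap()
        shifted = analysis.classify_interior_water(moved, voxel=0.3)
        assert shifted.n_inside == base.n_inside
        assert np.array_equal(shifted.inside, base.inside)

    def test_voxel_size_validation(self, tables):
        state, _ = _hollow_sphere_state(2, 5, tables)
        for bad in (0.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                analysis.classify_interior_water(state, voxel=bad)


class TestExchangeEvents:
    def test_constant_labels_no_events(self):
        labels = np.ones((10, 4), dtype=bool)
        assert analysis.exchange_events_from_labels(labels, 2) == []

    def test_scripted_outbound_event(self):
        # in, in, out, out, out with debounce 2 -> one outbound event at
        # the third frame
        labels = np.array([[1], [1], [0], [0], [0]], dtype=bool)
        events = analysis.exchange_events_from_labels(labels, 2)
        assert len(events) == 1
        assert events[0].direction == "out"
        assert events[0].frame == 2

    def test_transient_flip_suppressed(self):
        labels = np.array([[1], [0], [1], [1], [1]], dtype=bool)
        assert analysis.exchange_events_from_labels(labels, 2) == []

    def test_round_trip_counted_twice(self):
        labels = np.array([[1], [0], [0], [1], [1]], dtype=bool)
        events = analysis.exchange_events_from_labels(labels, 2)
        assert [e.direction for e in events] == ["out", "in"]

    def test_debounce_validation(self):
        with pytest.raises(ValueError):
            analysis.exchange_events_from_labels(np.ones((3, 1), bool), 0)


# ---------------------------------------------------------------------------
# surfactant coverage


class TestCoverage:
    def test_uniform_sphere_fully_covered(self, rng):
        dirs = _fibonacci_sphere(500, 2.0)
        cov = analysis.coverage_map(dirs, n_patches=32)
        assert cov.covered_fraction == 1.0
        assert cov.coefficient_of_variation < 0.5
        assert cov.counts.sum() == 500

    def test_hemisphere_covers_at_most_half_plus_slack(self):
        dirs = _fibonacci_sphere(600, 2.0)
        dirs = dirs[dirs[:, 2] > 0]
        cov = analysis.coverage_map(dirs, n_patches=32)
        assert cov.covered_fraction <= 0.5 + 1.0 / 32

    def test_single_cluster_is_inhomogeneous(self):
        dirs = np.tile([[0.0, 0.0, 2.0]], (50, 1))
        cov = analysis.coverage_map(dirs, n_patches=32)
        assert cov.covered_fraction == pytest.approx(1 / 32)
        assert cov.coefficient_of_variation > 2.0

    def test_equal_area_partition_exact(self):
        from lnpsim.analysis import _equal_area_bands

        for n in (8, 32, 50, 7):
            bands, sect = _equal_area_bands(n)
            assert bands * sect == n

    def test_no_surfactant_flagged_empty(self, tables):
        state = _point_molecule_state([[1, 1, 1], [1.4, 1, 1]], 5.0)
        cov = analysis.surface_coverage(state, n_patches=16)
        assert cov.empty
        assert cov.covered_fraction == 0.0

    def test_surfacted_aggregate_counts_shell_beads(self, tables):
        """Synthetic core+shell: all surfactant beads within the shell
        are binned; hemispherical placement leaves bare patches."""
        rng = np.random.default_rng(8)
        box = 8.0
        core = rng.normal(scale=0.5, size=(60, 3)) + box / 2
        shell_dirs = _fibonacci_sphere(80, 1.0)
        shell_dirs = shell_dirs[shell_dirs[:, 2] > 0]
        surf = shell_dirs * 1.9 + box / 2

        lipid = MoleculeTopology("tripalmitin", [BeadSpec("S", "C1")],
                                reference_positions=np.zeros((1, 3)))
        tween = MoleculeTopology("tween20", [BeadSpec("T", "P3")],
                                reference_positions=np.zeros((1, 3)))
        topo = compile_system([lipid] * len(core) + [tween] * len(surf), tables)
        pos = np.vstack([core, surf])
        state = SystemState(np.mod(pos, box), np.zeros_like(pos), box, topo)
        cov = analysis.surface_coverage(state, n_patches=32, shell=1.5,
                                        contact_cutoff=1.2)
        assert not cov.empty
        assert cov.covered_fraction <= 0.5 + 1.0 / 32
        assert cov.coefficient_of_variation > 0.5


class TestCoreVsTotalRg:
    def test_no_surfactant_selections_identical(self, tables):
        state = _point_molecule_state(
            [[3, 3, 3], [3.4, 3, 3], [3, 3.4, 3]], 7.0
        )
        rg_core, rg_total = analysis.core_vs_total_rg(state)
        assert rg_core == pytest.approx(rg_total)

    def test_surfactant_shell_increases_total(self, tables):
        rng = np.random.default_rng(9)
        box = 8.0
        core = rng.normal(scale=0.4, size=(40, 3)) + box / 2
        surf = _fibonacci_sphere(60, 1.8) + box / 2
        lipid = MoleculeTopology("tripalmitin", [BeadSpec("S", "C1")],
                                reference_positions=np.zeros((1, 3)))
        tween = MoleculeTopology("tween20", [BeadSpec("T", "P3")],
                                reference_positions=np.zeros((1, 3)))
        topo = compile_system([lipid] * 40 + [tween] * 60, tables)
        pos = np.vstack([core, surf])
        state = SystemState(np.mod(pos, box), np.zeros_like(pos), box, topo)
        rg_core, rg_total = analysis.core_vs_total_rg(state, contact_cutoff=1.5)
        assert rg_total > rg_core


def test_track_exchange_events_on_synthetic_trajectory(tables):
    """A water bead teleported from the droplet interior to the bulk
    (persistently) produces exactly one outbound event."""
    from lnpsim.engine import Frame, Trajectory

    state, _ = _hollow_sphere_state(5, 20, tables, seed=6)
    topo = state.topology
    water_ids = analysis._water_bead_ids(topo)
    mover = int(water_ids[0])  # an interior bead by construction
    box = state.box

    traj = Trajectory(topology=topo)
    for f in range(6):
        pos = state.positions.copy()
        if f >= 2:  # bead leaves the droplet at frame 2 and stays out
            pos[mover] = np.mod(np.array([0.3, 0.3, 0.3]), box)
        traj.frames.append(Frame(pos, box, float(f), None))

    part = analysis.track_exchange_events(traj, debounce=2, voxel=0.35)
    assert len(part.events) == 1
    assert part.events[0].direction == "out"
    assert part.events[0].frame == 2
    assert part.events[0].bead_id == mover
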