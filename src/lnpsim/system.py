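"""System construction: compositions, solvated starting states, minimization.

A simulated system is a cubic periodic box containing a periodic array of
solute molecules (tripalmitin, optionally Tween 20) surrounded by CG
water (P4 + AF beads).  Presets ``s1``..``s5`` reproduce the published
compositions of the five study systems; ``desk`` is a reduced system
(24 lipids, thin water shell) sized for a single CPU core.

The builder is fully seeded: identical spec + seed gives a bit-identical
starting state.  Placement guarantees a minimum inter-bead distance of
0.3 nm so that energy minimization always starts from finite forces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import BEAD_TYPES, ForceFieldTables, default_forcefield
from .topology import MoleculeTopology, build_tripalmitin, build_tween20, build_water_bead
from .units import KB

#: clearance required between any two placed beads, nm
MIN_PLACEMENT_DISTANCE = 0.3
_WATER_CLEARANCE = 0.40   # lattice sites closer than this to a solute are skipped
_WATER_JITTER = 0.03      # max per-axis jitter of water lattice sites, nm
_SOLUTE_GAP = 0.5         # gap between molecule bounding boxes in the array, nm


class PlacementError(RuntimeError):
    """Raised when molecules cannot be placed without overlap."""


@dataclass(frozen=True)
class SystemSpec:
    """Composition and thermodynamic conditions of one system."""

    n_lipid: int
    n_surfactant: int
    n_p4: int
    n_af: int
    box_side: float          # nm, initial (equilibrium value from the study)
    temperature: float = 310.0  # K
    pressure: float = 1.0       # atm
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        if min(self.n_lipid, self.n_surfactant, self.n_p4, self.n_af) < 0:
            raise ValueError("molecule counts must be non-negative")
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")

    @property
    def n_molecules(self) -> int:
        return self.n_lipid + self.n_surfactant + self.n_p4 + self.n_af

    def scaled(self, scale: float) -> "SystemSpec":
        """Multiply all counts by ``scale`` (rounded) and the box side by
        ``scale**(1/3)`` so the density is preserved."""
        if not 0 < scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        if scale == 1.0:
            return self
        return replace(
            self,
            n_lipid=int(round(self.n_lipid * scale)),
            n_surfactant=int(round(self.n_surfactant * scale)),
            n_p4=int(round(self.n_p4 * scale)),
            n_af=int(round(self.n_af * scale)),
            box_side=self.box_side * scale ** (1.0 / 3.0),
        )


#: Published compositions of the five study systems (counts of lipids,
#: surfactants, P4 water beads, AF beads and the equilibrium box side).
PRESETS: dict[str, SystemSpec] = {
    "s1": SystemSpec(64, 0, 4176, 462, 9.2, name="s1"),
    "s2": SystemSpec(216, 0, 28003, 3143, 16.9, name="s2"),
    "s3": SystemSpec(392, 0, 60210, 6627, 21.5, name="s3"),
    "s4": SystemSpec(216, 3, 22268, 2420, 15.6, name="s4"),
    "s5": SystemSpec(216, 221, 31826, 3518, 17.9, name="s5"),
    # reduced desk-scale system: 16 lipids with a water shell thick enough
    # that the assembled droplet (diameter ~4.1 nm) clears its periodic
    # images by at least the LJ cutoff; sized so the full self-assembly
    # protocol finishes on a single CPU core.  The barostat relaxes the
    # box from the slightly dilute initial side to the liquid density.
    "desk": SystemSpec(16, 0, 1090, 109, 5.8, name="desk"),
}

#: Published equilibrium radii of gyration (nm) of the lipid aggregates,
#: used as reference values when evaluating the density formula on the
#: study compositions.
REFERENCE_RG = {"s1": 2.5, "s2": 3.7, "s3": 4.6}
#: Published core/total radii of gyration for the fully surfacted system.
REFERENCE_RG_S5 = {"core": 3.9, "total": 4.9}


def get_preset(name: str, scale: float = 1.0, seed: int = 0) -> SystemSpec:
    spec = PRESETS[name.lower()]
    return replace(spec.scaled(scale), seed=seed)


# ---------------------------------------------------------------------------
# compiled topology + state


@dataclass
class SystemTopology:
    """Flat per-bead/per-term arrays compiled for the force kernels.

    Effective bead types double the base types: index ``2*t + ring`` so
    that fine-mapped ring beads get their smaller sigma against each
    other.  ``sigma`` / ``eps`` are dense matrices over effective types.
    """

    species_names: list[str]
    type_idx: np.ndarray       # (n,) effective type per bead
    base_type_idx: np.ndarray  # (n,) index into BEAD_TYPES
    is_ring: np.ndarray        # (n,) bool
    masses: np.ndarray         # (n,)
    molecule_id: np.ndarray    # (n,)
    species_id: np.ndarray     # (n,) per bead
    mol_indptr: np.ndarray     # (n_mol+1,) bead ranges per molecule
    mol_species: np.ndarray    # (n_mol,)
    bonds: np.ndarray          # (M,2)
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray         # (K,3)
    angle_cos0: np.ndarray
    angle_k: np.ndarray
    excl_indptr: np.ndarray    # CSR exclusions (1-2 and 1-3 neighbours)
    excl_idx: np.ndarray
    sigma: np.ndarray          # (n_eff, n_eff)
    eps: np.ndarray

    @property
    def n_beads(self) -> int:
        return self.type_idx.size

    @property
    def n_molecules(self) -> int:
        return self.mol_indptr.size - 1

    def molecule_slice(self, m: int) -> slice:
        return slice(int(self.mol_indptr[m]), int(self.mol_indptr[m + 1]))

    def beads_of_species(self, name: str) -> np.ndarray:
        sid = self.species_names.index(name)
        return np.nonzero(self.species_id == sid)[0]


@dataclass
class SystemState:
    """Positions, velocities and box of one configuration."""

    positions: np.ndarray   # (n,3) nm, wrapped into [0, L)
    velocities: np.ndarray  # (n,3) nm/ps
    box: float              # cubic side L, nm
    topology: SystemTopology

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.box, self.topology
        )

    def wrap(self) -> None:
        np.mod(self.positions, self.box, out=self.positions)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def kinetic_energy(self) -> float:
        m = self.topology.masses
        return 0.5 * float(np.sum(m * np.sum(self.velocities**2, axis=1)))

    def instantaneous_temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (3.0 * self.n_beads * KB)


def compile_system(
    molecules: list[MoleculeTopology], tables: ForceFieldTables
) -> SystemTopology:
    """Concatenate molecule topologies into flat kernel-ready arrays."""
    species_names: list[str] = []
    type_idx, base_idx, ring, masses, mol_id, spec_id = [], [], [], [], [], []
    bonds, bond_r0, bond_k = [], [], []
    angles, angle_cos0, angle_k = [], [], []
    mol_indptr = [0]
    mol_species = []
    offset = 0
    for m, topo in enumerate(molecules):
        if topo.species_name not in species_names:
            species_names.append(topo.species_name)
        sid = species_names.index(topo.species_name)
        mol_species.append(sid)
        for b in topo.beads:
            t = BEAD_TYPES.index(b.bead_type)
            base_idx.append(t)
            ring.append(b.is_ring)
            type_idx.append(2 * t + int(b.is_ring))
            masses.append(b.mass)
            mol_id.append(m)
            spec_id.append(sid)
        for bd in topo.bonds:
            bonds.append((bd.i + offset, bd.j + offset))
            bond_r0.append(bd.r0)
            bond_k.append(bd.k)
        for c in topo.constraints:
            bonds.append((c.i + offset, c.j + offset))
            bond_r0.append(c.r0)
            bond_k.append(tables.bonded.ring_constraint_k)
        for an in topo.angles:
            angles.append((an.i + offset, an.j + offset, an.k + offset))
            angle_cos0.append(np.cos(np.radians(an.theta0)))
            angle_k.append(an.ktheta)
        offset += topo.n_beads
        mol_indptr.append(offset)

    n = offset
    # LJ exclusions: every pair carrying an explicit bonded term (chain
    # bonds, ring edges, ring restraints) — the standard Martini nrexcl=1
    # convention.  Second neighbours keep their LJ hard core, which is
    # what prevents chains from folding back onto themselves at branch
    # points that carry no angle term.
    excl: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        excl[i].add(j)
        excl[j].add(i)
    excl_indptr = np.zeros(n + 1, dtype=np.int64)
    excl_lists = [np.fromiter(sorted(e), dtype=np.int64) for e in excl]
    for i, e in enumerate(excl_lists):
        excl_indptr[i + 1] = excl_indptr[i] + e.size
    excl_idx = (
        np.concatenate(excl_lists) if excl_indptr[-1] else np.empty(0, dtype=np.int64)
    )

    n_eff = 2 * len(BEAD_TYPES)
    sigma = np.zeros((n_eff, n_eff))
    eps = np.zeros((n_eff, n_eff))
    for a, ta in enumerate(BEAD_TYPES):
        for b, tb in enumerate(BEAD_TYPES):
            for ra in (0, 1):
                for rb in (0, 1):
                    s, e = tables.pair(ta, tb, ring=bool(ra and rb))
                    sigma[2 * a + ra, 2 * b + rb] = s
                    eps[2 * a + ra, 2 * b + rb] = e

    def arr(x, dtype=float):
        return np.asarray(x, dtype=dtype)

    return SystemTopology(
        species_names=species_names,
        type_idx=arr(type_idx, np.int64),
        base_type_idx=arr(base_idx, np.int64),
        is_ring=arr(ring, bool),
        masses=arr(masses),
        molecule_id=arr(mol_id, np.int64),
        species_id=arr(spec_id, np.int64),
        mol_indptr=arr(mol_indptr, np.int64),
        mol_species=arr(mol_species, np.int64),
        bonds=arr(bonds, np.int64).reshape(-1, 2),
        bond_r0=arr(bond_r0),
        bond_k=arr(bond_k),
        angles=arr(angles, np.int64).reshape(-1, 3),
        angle_cos0=arr(angle_cos0),
        angle_k=arr(angle_k),
        excl_indptr=excl_indptr,
        excl_idx=excl_idx,
        sigma=sigma,
        eps=eps,
    )


# ---------------------------------------------------------------------------
# building


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at the target temperature with the
    centre-of-mass drift removed."""
    sig = np.sqrt(KB * temperature / masses)[:, None]
    v = rng.normal(size=(masses.size, 3)) * sig
    p = (masses[:, None] * v).sum(axis=0)
    v -= p / masses.sum()
    return v


def _molecule_half_extent(topo: MoleculeTopology) -> np.ndarray:
    ref = topo.reference_positions
    return 0.5 * (ref.max(axis=0) - ref.min(axis=0))


def build_system(
    spec: SystemSpec,
    scale: float = 1.0,
    tables: ForceFieldTables | None = None,
    with_velocities: bool = True,
) -> SystemState:
    """Construct a solvated periodic starting configuration.

    Solutes are laid out on a cubic lattice; water lattice sites (with a
    small seeded jitter) fill the remaining volume; AF beads are randomly
    interspersed among the water sites at the composition's ratio.

    Raises
    ------
    PlacementError
        If a solute molecule or the requested water count cannot be
        placed with at least 0.3 nm clearance.
    """
    tables = tables or default_forcefield()
    spec = spec.scaled(scale)
    rng = np.random.default_rng(spec.seed)

    lipid = build_tripalmitin(tables)
    tween = build_tween20(tables)
    solutes: list[MoleculeTopology] = [lipid] * spec.n_lipid + [tween] * spec.n_surfactant

    # Solutes form a compact central array (molecule bounding box plus a
    # fixed gap) inside the solvation box, mirroring the study protocol
    # of an array "inside a big solvation box".  If the nominal box
    # cannot also hold the requested water, the initial box is enlarged
    # (up to 60%) and the barostat relaxes it back to the liquid density.
    spacing = 0.0
    m = 0
    if solutes:
        n_mol = len(solutes)
        m = int(np.ceil(n_mol ** (1.0 / 3.0)))
        bbox = max(2.0 * float(_molecule_half_extent(t).max()) for t in solutes)
        spacing = bbox + _SOLUTE_GAP

    def _try_place(L: float):
        placed: list[np.ndarray] = []
        if solutes:
            extent = m * spacing
            if extent > L:
                raise PlacementError(
                    f"cannot place molecule 0 ({solutes[0].species_name}): solute "
                    f"array of extent {extent:.2f} nm exceeds the {L:.2f} nm box"
                )
            offset = 0.5 * (L - extent)
            sites = [
                offset + (np.array([i, j, k], dtype=float) + 0.5) * spacing
                for i in range(m)
                for j in range(m)
                for k in range(m)
            ]
            for idx, topo in enumerate(solutes):
                centre = 0.5 * (
                    topo.reference_positions.max(axis=0)
                    + topo.reference_positions.min(axis=0)
                )
                placed.append(np.mod(topo.reference_positions - centre + sites[idx], L))
        solute_pos = np.vstack(placed) if placed else np.empty((0, 3))

        n_water = spec.n_p4 + spec.n_af
        if n_water == 0:
            return solute_pos, np.empty((0, 3))
        # water lattice: densest allowed spacing keeps >= 0.3 nm after jitter
        min_spacing = MIN_PLACEMENT_DISTANCE + 2.0 * _WATER_JITTER * np.sqrt(3.0)
        mw = int(np.ceil((1.25 * n_water) ** (1.0 / 3.0)))
        tree = cKDTree(solute_pos, boxsize=L) if solute_pos.size else None
        while True:
            a = L / mw
            if a < min_spacing:
                return None  # box too small for this many waters
            g = (np.arange(mw) + 0.5) * a
            sites_w = np.stack(
                np.meshgrid(g, g, g, indexing="ij"), axis=-1
            ).reshape(-1, 3)
            if tree is not None:
                blocked = tree.query_ball_point(sites_w, r=_WATER_CLEARANCE)
                sites_w = sites_w[[not b for b in blocked]]
            if sites_w.shape[0] >= n_water:
                break
            mw += 1
        # stratified site selection (every k-th site of the lattice
        # traversal) keeps the solvent density isotropic across the box;
        # jitter and AF placement carry the seeded randomness
        n_avail = sites_w.shape[0]
        pick = np.floor(np.arange(n_water) * (n_avail / n_water)).astype(np.int64)
        pick = (pick + int(rng.integers(n_avail))) % n_avail
        jitter = rng.uniform(-_WATER_JITTER, _WATER_JITTER, size=(n_water, 3))
        return solute_pos, np.mod(sites_w[pick] + jitter, L)

    L = spec.box_side
    n_water = spec.n_p4 + spec.n_af
    result = None
    while result is None:
        result = _try_place(L)
        if result is None:
            if L > 1.6 * spec.box_side:
                raise PlacementError(
                    f"cannot place {n_water} water beads around the solute array "
                    f"even after enlarging the box to {L:.2f} nm"
                )
            L *= 1.05
    solute_pos, water_pos = result

    af_slots = rng.choice(n_water, size=spec.n_af, replace=False) if n_water else []
    af_mask = np.zeros(n_water, dtype=bool)
    af_mask[af_slots] = True
    waters = [build_water_bead("AF" if af else "P4") for af in af_mask]

    molecules = solutes + waters
    topo = compile_system(molecules, tables)
    positions = np.vstack([solute_pos, water_pos]) if n_water else solute_pos
    if positions.shape[0] != topo.n_beads:
        raise AssertionError("bead count mismatch between placement and topology")

    velocities = (
        maxwell_boltzmann_velocities(topo.masses, spec.temperature, rng)
        if with_velocities
        else np.zeros_like(positions)
    )
    state = SystemState(np.ascontiguousarray(positions), velocities, L, topo)
    state.wrap()
    return state


def min_image_distances_ok(state: SystemState, dmin: float = MIN_PLACEMENT_DISTANCE) -> bool:
    """Check the placement contract: no pair closer than ``dmin`` under
    the minimum-image convention."""
    tree = cKDTree(np.mod(state.positions, state.box), boxsize=state.box)
    return len(tree.query_pairs(r=dmin * (1 - 1e-12))) == 0


# ---------------------------------------------------------------------------
# minimization


class MinimizationError(RuntimeError):
    pass


def minimize_energy(
    state: SystemState,
    tables: ForceFieldTables | None = None,
    max_steps: int = 2000,
    tol: float = 10.0,
) -> SystemState:
    """Steepest-descent energy minimization with step backtracking.

    Moves along the force direction with an adaptive trust radius (the
    maximum per-bead displacement); the step shrinks on energy increase
    and grows on success.  Terminates when the largest force component
    drops below ``tol`` (kJ/mol/nm) or after ``max_steps`` iterations.
    Deterministic; never increases the potential energy.
    """
    from .engine import ForceCalculator  # deferred: engine depends on this module

    tables = tables or default_forcefield()
    calc = ForceCalculator(state.topology, tables)
    x = state.positions.copy()
    L = state.box
    forces, report = calc.compute(x, L)
    energy = report.potential
    if not np.isfinite(energy):
        raise MinimizationError("non-finite energy at input state (hard overlap)")

    step = 0.02  # nm, max per-bead displacement
    for _ in range(max_steps):
        fmax = np.abs(forces).max()
        if fmax < tol:
            break
        trial = np.mod(x + forces * (step / fmax), L)
        f_new, rep_new = calc.compute(trial, L)
        if np.isfinite(rep_new.potential) and rep_new.potential <= energy:
            x, forces, energy = trial, f_new, rep_new.potential
            step = min(step * 1.2, 0.1)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    out = state.copy()
    out.positions = x
    return out
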