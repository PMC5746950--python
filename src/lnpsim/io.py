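"""File input/output.

Structure and trajectory files go through MDAnalysis (GRO, PDB, XYZ,
DCD); energy/box time series are written as tab-separated text.
Internal units are nm; files use the native unit of each format
(Angstrom for GRO/PDB/DCD coordinates handled by MDAnalysis).
"""

from __future__ import annotations

import warnings

import numpy as np

from .forcefield import BEAD_TYPES
from .system import SystemState, SystemTopology
from .topology import MoleculeTopology

_RESNAMES = {
    "tripalmitin": "TRP",
    "tween20": "TW20",
    "water_p4": "W",
    "water_af": "WAF",
}


def _universe_from_topology(topo: SystemTopology):
    import MDAnalysis as mda

    n_mol = topo.n_molecules
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=topo.n_beads,
            n_residues=n_mol,
            atom_resindex=topo.molecule_id,
            trajectory=True,
        )
        names = [BEAD_TYPES[t] for t in topo.base_type_idx]
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("types", names)
        u.add_TopologyAttr("elements", ["C"] * topo.n_beads)  # placeholder for PDB
        resnames = [
            _RESNAMES.get(topo.species_names[s], topo.species_names[s][:4].upper())
            for s in topo.mol_species
        ]
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", np.arange(1, n_mol + 1))
        u.add_TopologyAttr("masses", topo.masses)
    return u


def _load_universe(state: SystemState):
    u = _universe_from_topology(state.topology)
    u.atoms.positions = state.positions * 10.0  # nm -> Angstrom
    L = state.box * 10.0
    u.dimensions = [L, L, L, 90.0, 90.0, 90.0]
    return u


def write_structure(state: SystemState, path) -> None:
    """Write the configuration as GRO/PDB/XYZ (format from extension)."""
    u = _load_universe(state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_molecule(topo: MoleculeTopology, path) -> None:
    """Write one molecule's reference conformation (GRO/PDB/XYZ)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms=topo.n_beads, n_residues=1,
                               atom_resindex=[0] * topo.n_beads, trajectory=True)
        u.add_TopologyAttr("names", [b.name for b in topo.beads])
        u.add_TopologyAttr("types", [b.bead_type for b in topo.beads])
        u.add_TopologyAttr("elements", ["C"] * topo.n_beads)
        u.add_TopologyAttr(
            "resnames", [_RESNAMES.get(topo.species_name, topo.species_name[:4])]
        )
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("masses", [b.mass for b in topo.beads])
        u.atoms.positions = topo.reference_positions * 10.0
        span = float(topo.reference_positions.max() + 1.0) * 10.0
        u.dimensions = [span, span, span, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def read_coordinates(path, topology: SystemTopology | None = None) -> SystemState:
    """Load a coordinate file for analysis-only use.

    If a compiled topology is given its bead count must match; otherwise
    a minimal single-species topology-free state is not supported and a
    ValueError is raised.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    pos = u.atoms.positions / 10.0
    if u.dimensions is None or not np.any(u.dimensions[:3]):
        box = float(pos.max() - pos.min() + 1.0)
    else:
        box = float(u.dimensions[0]) / 10.0
    if topology is None:
        raise ValueError("a compiled SystemTopology is required to interpret beads")
    if topology.n_beads != pos.shape[0]:
        raise ValueError(
            f"coordinate file has {pos.shape[0]} beads, topology {topology.n_beads}"
        )
    state = SystemState(
        pos.astype(float), np.zeros_like(pos, dtype=float), box, topology
    )
    state.wrap()
    return state


class XYZTrajectoryWriter:
    """Frame sink writing an XYZ trajectory (one snapshot per frame)."""

    def __init__(self, path, topology: SystemTopology):
        self.path = str(path)
        self.names = [BEAD_TYPES[t] for t in topology.base_type_idx]
        self._fh = open(self.path, "w")

    def write_frame(self, state: SystemState, time_ps: float) -> None:
        pos = state.positions * 10.0
        self._fh.write(f"{len(self.names)}\n")
        self._fh.write(f"t= {time_ps:.4f} ps, box= {state.box:.5f} nm\n")
        for name, (x, y, z) in zip(self.names, pos):
            self._fh.write(f"{name} {x:.4f} {y:.4f} {z:.4f}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class DCDTrajectoryWriter:
    """Frame sink writing a DCD trajectory with a PDB topology sidecar."""

    def __init__(self, path, state: SystemState, pdb_sidecar=None):
        import MDAnalysis as mda

        self._u = _load_universe(state)
        if pdb_sidecar is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._u.atoms.write(str(pdb_sidecar))
        self._writer = mda.Writer(str(path), n_atoms=state.n_beads)

    def write_frame(self, state: SystemState, time_ps: float) -> None:
        self._u.atoms.positions = state.positions * 10.0
        L = state.box * 10.0
        self._u.dimensions = [L, L, L, 90.0, 90.0, 90.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._writer.write(self._u.atoms)

    def close(self) -> None:
        self._writer.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_trajectory(path, topology: SystemTopology, top=None):
    """Load a stored trajectory (XYZ, or DCD with a PDB topology
    sidecar passed as ``top``) into a :class:`~lnpsim.engine.Trajectory`
    of coordinate frames (no energies)."""
    import MDAnalysis as mda

    from .engine import Frame, Trajectory

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(top), str(path)) if top else mda.Universe(str(path))
    if len(u.atoms) != topology.n_beads:
        raise ValueError(
            f"trajectory has {len(u.atoms)} beads, topology {topology.n_beads}"
        )
    traj = Trajectory(topology=topology)
    for ts in u.trajectory:
        if ts.dimensions is not None and np.any(ts.dimensions[:3]):
            box = float(ts.dimensions[0]) / 10.0
        else:
            box = float(ts.positions.max() - ts.positions.min() + 10.0) / 10.0
        traj.frames.append(
            Frame(
                positions=np.mod(ts.positions.astype(float) / 10.0, box),
                box=box,
                time_ps=float(ts.frame),
                report=None,
            )
        )
    return traj


def save_checkpoint(path, state: SystemState, rng: np.random.Generator,
                    step: int = 0) -> None:
    """Checkpoint the full dynamic state: positions, velocities, box,
    step counter and the RNG bit-generator state."""
    import json

    rng_state = json.dumps(rng.bit_generator.state)
    np.savez(
        path,
        positions=state.positions,
        velocities=state.velocities,
        box=state.box,
        step=step,
        rng_state=np.frombuffer(rng_state.encode(), dtype=np.uint8),
    )


def load_checkpoint(path, topology: SystemTopology):
    """Restore a checkpoint; returns ``(state, rng, step)`` where the
    generator continues the saved random stream exactly."""
    import json

    data = np.load(path)
    if data["positions"].shape[0] != topology.n_beads:
        raise ValueError("checkpoint bead count does not match topology")
    state = SystemState(
        data["positions"].copy(),
        data["velocities"].copy(),
        float(data["box"]),
        topology,
    )
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(bytes(data["rng_state"]).decode())
    return state, rng, int(data["step"])


def write_energy_series(trajectory, path) -> None:
    """Tab-separated scalar series (time, energies, T, P, box)."""
    s = trajectory.series
    keys = ["time_ps", "total", "potential", "kinetic", "temperature", "pressure", "box"]
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in zip(*(s[k] for k in keys)):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
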