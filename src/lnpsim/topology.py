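"""Coarse-grain molecule topologies.

Three species are built in:

* **tripalmitin** — triglyceride of palmitic acid, mapped at ~4 heavy
  atoms per bead to 19 beads: 16 apolar C1 (three tails of four beads
  plus a four-bead glycerol/linker region) and 3 Na ester beads.
* **Tween 20** (polysorbate 20) — nonionic surfactant, 30 beads: a
  five-bead fine-mapped sorbitan ring (held near-rigid), four PEG-like
  arms of polar P3 beads, and a lauric tail (one Na ester + three C1).
* **CG water** — single P4 beads (four real waters each) mixed with
  antifreeze AF beads, one AF per ten P4.

Every bead has a mass of 72 amu irrespective of type.  Each topology
carries a compact reference conformation (beads folded onto a 0.46 nm
grid) used by the system builder; energy minimization relaxes it before
dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceFieldTables
from .units import BEAD_MASS

#: grid spacing of the folded reference conformations, nm
_GRID = 0.46


@dataclass(frozen=True)
class BeadSpec:
    """One interaction centre of a CG molecule."""

    name: str
    bead_type: str  # one of C1, Na, P3, P4, AF
    mass: float = BEAD_MASS
    is_ring: bool = False


@dataclass
class Bond:
    i: int
    j: int
    r0: float  # nm
    k: float   # kJ/mol/nm^2


@dataclass
class Angle:
    i: int
    j: int
    k: int
    theta0: float  # degrees
    ktheta: float  # kJ/mol (cosine-harmonic)


@dataclass
class Constraint:
    """Distance restraint maintaining ring geometry (stiff harmonic)."""

    i: int
    j: int
    r0: float


@dataclass
class MoleculeTopology:
    species_name: str
    beads: list[BeadSpec]
    bonds: list[Bond] = field(default_factory=list)
    angles: list[Angle] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    reference_positions: np.ndarray | None = None  # (n_beads, 3) nm

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def mass(self) -> float:
        return sum(b.mass for b in self.beads)

    def count_type(self, bead_type: str) -> int:
        return sum(1 for b in self.beads if b.bead_type == bead_type)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.beads]
        for b in self.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        return adj

    def is_connected(self) -> bool:
        if not self.beads:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_beads

    def validate(self) -> None:
        n = self.n_beads
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n and b.i != b.j):
                raise ValueError(f"bond ({b.i},{b.j}) references missing beads")
        for a in self.angles:
            if not all(0 <= x < n for x in (a.i, a.j, a.k)):
                raise ValueError("angle references missing beads")
        if not self.is_connected():
            raise ValueError(f"bond graph of {self.species_name} is not connected")


def _chain_angles(path: list[int], theta0: float, ktheta: float) -> list[Angle]:
    return [
        Angle(path[m], path[m + 1], path[m + 2], theta0, ktheta)
        for m in range(len(path) - 2)
    ]


def build_tripalmitin(tables: ForceFieldTables) -> MoleculeTopology:
    """19-bead tripalmitin: 16 C1 + 3 Na.

    Glycerol/linker region: chain GL1-GL2-GL3 (plus GL4 on GL2), each of
    GL1..GL3 carrying one Na ester bead, each ester continuing into a
    four-bead C1 tail.  The bond graph is a tree.
    """
    bd = tables.bonded
    beads: list[BeadSpec] = []
    coords: list[tuple[int, int, int]] = []

    def add(name: str, btype: str, cell: tuple[int, int, int]) -> int:
        beads.append(BeadSpec(name, btype))
        coords.append(cell)
        return len(beads) - 1

    gl = [
        add("GL1", "C1", (0, 0, 0)),
        add("GL2", "C1", (1, 0, 0)),
        add("GL3", "C1", (2, 0, 0)),
        add("GL4", "C1", (1, 1, 0)),
    ]
    esters = [
        add("ES1", "Na", (0, 0, 1)),
        add("ES2", "Na", (1, 0, 1)),
        add("ES3", "Na", (2, 0, 1)),
    ]
    tail_cells = [
        [(0, 1, 1), (0, 2, 1), (0, 2, 2), (0, 1, 2)],
        [(1, 0, 2), (1, 1, 2), (1, 2, 2), (1, 2, 1)],
        [(2, 1, 1), (2, 2, 1), (2, 2, 2), (2, 1, 2)],
    ]
    tails = [
        [add(f"T{t + 1}{m + 1}", "C1", cell) for m, cell in enumerate(cells)]
        for t, cells in enumerate(tail_cells)
    ]

    bonds = [
        Bond(gl[0], gl[1], bd.bond_r0, bd.bond_k),
        Bond(gl[1], gl[2], bd.bond_r0, bd.bond_k),
        Bond(gl[1], gl[3], bd.bond_r0, bd.bond_k),
    ]
    angles: list[Angle] = []
    for t in range(3):
        path = [gl[t], esters[t], *tails[t]]
        for m in range(len(path) - 1):
            bonds.append(Bond(path[m], path[m + 1], bd.bond_r0, bd.bond_k))
        angles += _chain_angles(path[1:], bd.angle_theta0, bd.angle_k)

    topo = MoleculeTopology(
        species_name="tripalmitin",
        beads=beads,
        bonds=bonds,
        angles=angles,
        reference_positions=np.asarray(coords, dtype=float) * _GRID,
    )
    topo.validate()
    return topo


def build_tween20(tables: ForceFieldTables) -> MoleculeTopology:
    """30-bead Tween 20: fine-mapped 5-bead sorbitan ring (2 Na + 3 C1,
    flagged ``is_ring``), four P3 arms (5, 5, 5 and 6 beads), and a
    lauric-ester tail (1 Na + 3 C1) on the long arm.

    The ring is a regular pentagon of stiff bonds; its five chords are
    distance restraints, so the ring subgraph is the only cycle.
    """
    bd = tables.bonded
    beads: list[BeadSpec] = []
    pos: list[np.ndarray] = []

    r_ring = bd.ring_bond_r0 / (2.0 * math.sin(math.pi / 5.0))
    centre = np.array([_GRID, _GRID, 0.0])
    ring_types = ["Na", "C1", "Na", "C1", "C1"]
    ring: list[int] = []
    for m, btype in enumerate(ring_types):
        theta = math.pi / 2 + 2 * math.pi * m / 5
        beads.append(BeadSpec(f"R{m + 1}", btype, is_ring=True))
        pos.append(centre + r_ring * np.array([math.cos(theta), math.sin(theta), 0.0]))
        ring.append(len(beads) - 1)

    def add(name: str, btype: str, cell: tuple[int, int, int]) -> int:
        beads.append(BeadSpec(name, btype))
        pos.append(np.asarray(cell, dtype=float) * _GRID)
        return len(beads) - 1

    arm_cells = [
        [(0, 0, 1), (1, 0, 1), (2, 0, 1), (2, 1, 1), (1, 1, 1)],
        [(0, 1, 1), (0, 2, 1), (1, 2, 1), (2, 2, 1), (2, 2, 2)],
        [(1, 2, 2), (0, 2, 2), (0, 1, 2), (0, 0, 2), (1, 0, 2)],
        [(1, 1, 2), (2, 1, 2), (2, 0, 2), (2, 0, 3), (2, 1, 3), (2, 2, 3)],
    ]
    tail_cells = [(1, 2, 3), (1, 1, 3), (1, 0, 3), (0, 0, 3)]

    bonds: list[Bond] = []
    angles: list[Angle] = []
    for a, cells in enumerate(arm_cells):
        arm = [add(f"E{a + 1}{m + 1}", "P3", c) for m, c in enumerate(cells)]
        path = [ring[a], *arm]
        if a == 3:  # long arm continues into the lauric ester + C12 tail
            path.append(add("EST", "Na", tail_cells[0]))
            path += [add(f"L{m + 1}", "C1", c) for m, c in enumerate(tail_cells[1:])]
        for m in range(len(path) - 1):
            bonds.append(Bond(path[m], path[m + 1], bd.bond_r0, bd.bond_k))
        angles += _chain_angles(path, bd.angle_theta0, bd.angle_k)

    # ring edges as stiff bonds, chords as distance restraints
    chord = 2.0 * r_ring * math.sin(2 * math.pi / 5)
    constraints: list[Constraint] = []
    for m in range(5):
        bonds.append(Bond(ring[m], ring[(m + 1) % 5], bd.ring_bond_r0, bd.ring_bond_k))
        constraints.append(Constraint(ring[m], ring[(m + 2) % 5], chord))

    topo = MoleculeTopology(
        species_name="tween20",
        beads=beads,
        bonds=bonds,
        angles=angles,
        constraints=constraints,
        reference_positions=np.vstack(pos),
    )
    topo.validate()
    return topo


def build_water_bead(kind: str = "P4") -> MoleculeTopology:
    """Single-bead CG water molecule of type P4 or AF."""
    if kind not in ("P4", "AF"):
        raise ValueError(f"water bead kind must be P4 or AF, got {kind!r}")
    return MoleculeTopology(
        species_name=f"water_{kind.lower()}",
        beads=[BeadSpec("W", kind)],
        reference_positions=np.zeros((1, 3)),
    )


def water_composition(
    n_p4: int, af_per_p4_ratio: float = 0.1, waters_per_p4: int = 4
) -> tuple[int, int, int]:
    """Water-model bookkeeping: one P4 bead = four real waters, one AF
    bead per ten P4 beads.

    Returns ``(n_p4, n_af, n_real_waters)``.
    """
    if n_p4 < 0:
        raise ValueError(f"n_p4 must be non-negative, got {n_p4}")
    n_af = int(round(n_p4 * af_per_p4_ratio))
    return n_p4, n_af, waters_per_p4 * n_p4


def write_itp(topo: MoleculeTopology, path) -> None:
    """Export one species as a GROMACS ITP-dialect topology file."""
    lines = [
        f"; {topo.species_name} coarse-grain topology",
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        f"{topo.species_name}  1",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr  charge  mass",
    ]
    for n, b in enumerate(topo.beads, start=1):
        lines.append(
            f"{n:5d}  {b.bead_type:<4s}  1  {topo.species_name[:4].upper():<4s}  "
            f"{b.name:<5s} {n:4d}  0.000  {b.mass:.1f}"
        )
    if topo.bonds:
        lines += ["", "[ bonds ]", ";  i   j  funct  r0(nm)  k"]
        for b in topo.bonds:
            lines.append(f"{b.i + 1:4d} {b.j + 1:4d}  1  {b.r0:.4f}  {b.k:.1f}")
    if topo.angles:
        lines += ["", "[ angles ]", ";  i   j   k  funct  theta0  ktheta"]
        for a in topo.angles:
            lines.append(
                f"{a.i + 1:4d} {a.j + 1:4d} {a.k + 1:4d}  2  {a.theta0:.1f}  {a.ktheta:.1f}"
            )
    if topo.constraints:
        lines += ["", "[ constraints ]", ";  i   j  funct  r0(nm)"]
        for c in topo.constraints:
            lines.append(f"{c.i + 1:4d} {c.j + 1:4d}  1  {c.r0:.4f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
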