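"""Structural observables of self-assembled lipid nanoparticles.

Implements the study's analysis toolbox: mass-weighted radius of
gyration, gyration-tensor asphericity, lipid number density
3N/(4 pi Rg^3), contact-based aggregate detection, voxel flood-fill
classification of interior water, debounced water exchange events, and
equal-area surfactant surface-coverage maps.

Shape observables assume an unwrapped (made-whole) selection; the
helpers :func:`make_whole` and :func:`unwrap_cluster` reconstruct
connected aggregates across the periodic boundaries.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .system import SystemState, SystemTopology

__all__ = [
    "ShapeResult", "ClusterResult", "WaterPartition", "CoverageMap",
    "radius_of_gyration", "gyration_tensor", "asphericity",
    "lipid_number_density", "detect_aggregates", "make_whole",
    "unwrap_cluster", "classify_interior_water", "exchange_events_from_labels",
    "track_exchange_events", "surface_coverage", "core_vs_total_rg",
    "aggregate_shape",
]

SOLUTE_SPECIES = ("tripalmitin", "tween20")


# ---------------------------------------------------------------------------
# shape observables


@dataclass(frozen=True)
class ShapeResult:
    """Size and shape of one molecule selection in one frame.

    ``rg`` is the mass-weighted radius of gyration; ``principal_radii``
    are the square roots of the gyration-tensor eigenvalues sorted
    descending (R1 >= R2 >= R3, with rg^2 = R1^2 + R2^2 + R3^2); and
    ``delta`` is the asphericity, 0 for a perfect sphere and 1 for a rod.
    """

    rg: float
    principal_radii: tuple[float, float, float]
    delta: float
    frame_time: float = 0.0  # ns, nominal
    selection: str = ""


def _weights(positions: np.ndarray, masses) -> np.ndarray:
    n = positions.shape[0]
    if n == 0:
        raise ValueError("empty selection")
    if masses is None:
        return np.full(n, 1.0 / n)
    masses = np.asarray(masses, dtype=float)
    return masses / masses.sum()


def radius_of_gyration(positions: np.ndarray, masses=None) -> float:
    """Mass-weighted RMS distance of beads from their centre of mass:

        Rg^2 = sum_i m_i |r_i - r_CM|^2 / sum_i m_i
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    w = _weights(positions, masses)
    com = w @ positions
    d2 = np.sum((positions - com) ** 2, axis=1)
    return float(np.sqrt(w @ d2))


def gyration_tensor(positions: np.ndarray, masses=None) -> np.ndarray:
    """Mass-weighted second-moment tensor about the centre of mass."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    w = _weights(positions, masses)
    d = positions - w @ positions
    return (w[:, None] * d).T @ d


def asphericity(
    positions: np.ndarray,
    masses=None,
    frame_time: float = 0.0,
    selection: str = "",
) -> ShapeResult:
    """Principal radii and asphericity from the gyration tensor.

    Delta = (3/2) sum_i (R_i - Rm)^2 / (R1 + R2 + R3)^2 with
    Rm = (R1 + R2 + R3)/3; eigenvalues are clipped at zero so collinear
    and planar selections yield exact degenerate radii rather than
    errors.  A single bead has Delta = 0 by convention.
    """
    tensor = gyration_tensor(positions, masses)
    eigvals = np.clip(np.linalg.eigvalsh(tensor), 0.0, None)
    radii = np.sqrt(eigvals)[::-1]  # descending
    rsum = radii.sum()
    if rsum == 0.0:
        delta = 0.0
    else:
        rm = rsum / 3.0
        delta = 1.5 * float(np.sum((radii - rm) ** 2)) / rsum**2
    return ShapeResult(
        rg=float(np.sqrt(eigvals.sum())),
        principal_radii=(float(radii[0]), float(radii[1]), float(radii[2])),
        delta=float(delta),
        frame_time=frame_time,
        selection=selection,
    )


def lipid_number_density(n_lipids: int, rg: float, ndigits: int | None = None) -> float:
    """Number of lipids per unit aggregate volume: 3N / (4 pi Rg^3).

    ``ndigits`` applies display rounding (two decimals in the study's
    result tables); ``None`` returns full precision.
    """
    if n_lipids < 1:
        raise ValueError("n_lipids must be >= 1")
    if rg <= 0:
        raise ValueError("rg must be positive")
    rho = 3.0 * n_lipids / (4.0 * np.pi * rg**3)
    return round(rho, ndigits) if ndigits is not None else rho


# ---------------------------------------------------------------------------
# aggregates and unwrapping


@dataclass
class ClusterResult:
    """Connected components of the molecule contact graph."""

    molecule_ids: np.ndarray   # molecules considered
    labels: np.ndarray         # component label per considered molecule
    contact_cutoff: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def cluster_members(self, label: int) -> np.ndarray:
        return self.molecule_ids[self.labels == label]

    @property
    def largest_cluster(self) -> np.ndarray:
        if not self.labels.size:
            return np.empty(0, dtype=np.int64)
        counts = np.bincount(self.labels)
        return self.cluster_members(int(np.argmax(counts)))

    @property
    def largest_cluster_size(self) -> int:
        return int(self.largest_cluster.size)

    def contains_all(self, molecule_ids: np.ndarray) -> bool:
        return bool(np.isin(molecule_ids, self.largest_cluster).all())


def detect_aggregates(
    state: SystemState,
    contact_cutoff: float = 0.6,
    species: tuple[str, ...] = SOLUTE_SPECIES,
) -> ClusterResult:
    """Cluster solute molecules by bead-bead contacts.

    Two molecules are connected when any inter-molecular bead pair lies
    within ``contact_cutoff`` under the minimum image; clusters are the
    connected components of that graph.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    topo = state.topology
    keep = [s for s in species if s in topo.species_names]
    sids = [topo.species_names.index(s) for s in keep]
    bead_mask = np.isin(topo.species_id, sids)
    bead_ids = np.nonzero(bead_mask)[0]
    mol_ids = np.unique(topo.molecule_id[bead_ids])
    if mol_ids.size == 0:
        return ClusterResult(mol_ids, np.empty(0, dtype=np.int64), contact_cutoff)

    mol_index = {m: k for k, m in enumerate(mol_ids)}
    parent = np.arange(mol_ids.size)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pos = np.mod(state.positions[bead_ids], state.box)
    tree = cKDTree(pos, boxsize=state.box)
    for a, b in tree.query_pairs(r=contact_cutoff):
        ma = mol_index[int(topo.molecule_id[bead_ids[a]])]
        mb = mol_index[int(topo.molecule_id[bead_ids[b]])]
        if ma != mb:
            ra, rb = find(ma), find(mb)
            if ra != rb:
                parent[rb] = ra

    roots = np.array([find(k) for k in range(mol_ids.size)])
    _, labels = np.unique(roots, return_inverse=True)
    return ClusterResult(mol_ids, labels.astype(np.int64), contact_cutoff)


def _bond_adjacency(topo: SystemTopology) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = defaultdict(list)
    for i, j in topo.bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    return adj


def make_whole(positions: np.ndarray, box: float, topo: SystemTopology) -> np.ndarray:
    """Undo periodic wrapping inside each molecule by walking its bond
    graph from a reference bead."""
    out = positions.copy()
    adj = _bond_adjacency(topo)
    for m in range(topo.n_molecules):
        sl = topo.molecule_slice(m)
        if sl.stop - sl.start == 1:
            continue
        seen = {sl.start}
        queue = deque([sl.start])
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if nb not in seen:
                    d = out[nb] - out[cur]
                    out[nb] = out[cur] + d - box * np.rint(d / box)
                    seen.add(nb)
                    queue.append(nb)
    return out


def unwrap_cluster(
    state: SystemState,
    mol_ids: np.ndarray,
    contact_cutoff: float = 0.6,
) -> np.ndarray:
    """Return positions in which the given molecules form one connected,
    unwrapped aggregate (molecule-graph traversal from a reference
    molecule, shifting whole molecules by box vectors)."""
    topo = state.topology
    box = state.box
    whole = make_whole(state.positions, box, topo)
    mol_ids = np.asarray(mol_ids, dtype=np.int64)
    if mol_ids.size == 0:
        return whole

    bead_ids = np.nonzero(np.isin(topo.molecule_id, mol_ids))[0]
    pos = np.mod(state.positions[bead_ids], box)
    tree = cKDTree(pos, boxsize=box)
    adj: dict[int, set[int]] = defaultdict(set)
    for a, b in tree.query_pairs(r=contact_cutoff):
        ma = int(topo.molecule_id[bead_ids[a]])
        mb = int(topo.molecule_id[bead_ids[b]])
        if ma != mb:
            adj[ma].add(mb)
            adj[mb].add(ma)

    masses = topo.masses

    def com(m: int) -> np.ndarray:
        sl = topo.molecule_slice(m)
        w = masses[sl]
        return (w[:, None] * whole[sl]).sum(axis=0) / w.sum()

    coms = {int(m): com(int(m)) for m in mol_ids}
    placed: set[int] = set()
    for root in map(int, mol_ids):
        if root in placed:
            continue
        placed.add(root)
        queue = deque([root])
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if nb not in placed:
                    shift = -box * np.rint((coms[nb] - coms[cur]) / box)
                    sl = topo.molecule_slice(nb)
                    whole[sl] += shift
                    coms[nb] += shift
                    placed.add(nb)
                    queue.append(nb)
    return whole


def aggregate_shape(
    state: SystemState,
    species: tuple[str, ...] = ("tripalmitin",),
    contact_cutoff: float = 0.6,
    frame_time: float = 0.0,
) -> ShapeResult:
    """Shape of the largest aggregate of the given species, made whole
    across the periodic boundaries first."""
    clusters = detect_aggregates(state, contact_cutoff, species)
    members = clusters.largest_cluster
    pos = unwrap_cluster(state, members, contact_cutoff)
    topo = state.topology
    beads = np.nonzero(np.isin(topo.molecule_id, members))[0]
    return asphericity(
        pos[beads], topo.masses[beads], frame_time=frame_time,
        selection="+".join(species),
    )


# ---------------------------------------------------------------------------
# interior water


@dataclass
class WaterPartition:
    """Inside/outside classification of every water bead in one frame."""

    water_bead_ids: np.ndarray
    inside: np.ndarray  # bool, aligned with water_bead_ids
    n_p4_inside: int
    n_af_inside: int
    events: list = field(default_factory=list)

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def n_outside(self) -> int:
        return int(self.inside.size - self.inside.sum())


def _water_bead_ids(topo: SystemTopology) -> np.ndarray:
    sids = [
        topo.species_names.index(s)
        for s in ("water_p4", "water_af")
        if s in topo.species_names
    ]
    return np.nonzero(np.isin(topo.species_id, sids))[0]


def classify_interior_water(
    state: SystemState,
    voxel: float = 0.35,
    block_radius: float = 0.264,
    contact_cutoff: float = 0.6,
    blocking_species: tuple[str, ...] = ("tripalmitin",),
) -> WaterPartition:
    """Voxel flood-fill partition of water into interior and exterior.

    The box is voxelized; voxels whose cube can intersect a sphere of
    ``block_radius`` around any lipid bead are blocked; a flood fill
    from the box faces (after recentring the aggregate) marks the
    exterior.  Water beads in unreached open voxels are interior; a
    water bead inside a blocked voxel (e.g. the droplet's first
    solvation shell) inherits the label of its nearest open voxel, so
    surface-shell water is not miscounted as interior.
    Deterministic for a given voxel size.
    """
    box = state.box
    if voxel <= 0 or voxel > box / 4.0:
        raise ValueError(f"voxel size must be in (0, box/4], got {voxel}")
    topo = state.topology

    clusters = detect_aggregates(state, contact_cutoff, blocking_species)
    members = clusters.largest_cluster
    unwrapped = unwrap_cluster(state, members, contact_cutoff)
    lipid_beads = np.nonzero(np.isin(topo.molecule_id, members))[0]
    if lipid_beads.size == 0:
        raise ValueError("no aggregate present to classify against")
    w = topo.masses[lipid_beads]
    com = (w[:, None] * unwrapped[lipid_beads]).sum(axis=0) / w.sum()
    shift = 0.5 * box - com
    pos = np.mod(state.positions + shift, box)

    ngrid = int(np.ceil(box / voxel))
    h = box / ngrid
    centres_1d = (np.arange(ngrid) + 0.5) * h
    blocked = np.zeros((ngrid, ngrid, ngrid), dtype=bool)
    # conservative cover: block every voxel whose cube may touch the bead
    reach = block_radius + 0.5 * h * np.sqrt(3.0)
    grid = np.stack(
        np.meshgrid(centres_1d, centres_1d, centres_1d, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    tree = cKDTree(grid, boxsize=box)
    hits = tree.query_ball_point(pos[lipid_beads], r=reach)
    for lst in hits:
        flat = np.asarray(lst, dtype=np.int64)
        blocked.reshape(-1)[flat] = True

    open_vox = ~blocked
    labels, _ = ndimage.label(open_vox)
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels |= set(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)
    exterior = np.isin(labels, sorted(boundary_labels))
    # blocked voxels inherit the exterior/interior label of the nearest
    # open voxel
    if blocked.any() and open_vox.any():
        _, nearest = ndimage.distance_transform_edt(blocked, return_indices=True)
        exterior = exterior[nearest[0], nearest[1], nearest[2]]

    water_ids = _water_bead_ids(topo)
    vox_idx = np.clip((pos[water_ids] / h).astype(int), 0, ngrid - 1)
    reached = exterior[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]]
    inside = ~reached

    p4_idx = topo.species_names.index("water_p4") if "water_p4" in topo.species_names else -1
    af_idx = topo.species_names.index("water_af") if "water_af" in topo.species_names else -1
    n_p4 = int(np.sum(inside & (topo.species_id[water_ids] == p4_idx)))
    n_af = int(np.sum(inside & (topo.species_id[water_ids] == af_idx)))
    return WaterPartition(water_ids, inside, n_p4, n_af)


@dataclass(frozen=True)
class ExchangeEvent:
    bead_id: int
    direction: str  # "in" or "out"
    frame: int


def exchange_events_from_labels(labels: np.ndarray, debounce: int) -> list[ExchangeEvent]:
    """Detect persistent inside<->outside flips in a (n_frames, n_beads)
    boolean label array (True = inside).  A flip at frame f counts only
    if the new label persists for at least ``debounce`` frames."""
    if debounce < 1:
        raise ValueError("debounce must be >= 1")
    labels = np.atleast_2d(np.asarray(labels, dtype=bool))
    n_frames, n_beads = labels.shape
    events: list[ExchangeEvent] = []
    for b in range(n_beads):
        committed = labels[0, b]
        f = 1
        while f < n_frames:
            if labels[f, b] != committed and f + debounce <= n_frames:
                window = labels[f : f + debounce, b]
                if np.all(window == labels[f, b]):
                    committed = labels[f, b]
                    events.append(
                        ExchangeEvent(b, "in" if committed else "out", f)
                    )
            f += 1
    events.sort(key=lambda e: (e.frame, e.bead_id))
    return events


def track_exchange_events(
    trajectory,
    debounce: int = 3,
    voxel: float = 0.35,
    **classify_kwargs,
) -> WaterPartition:
    """Classify interior water on every frame of a trajectory and emit
    debounced exchange events.  Returns the final frame's partition with
    the event list attached."""
    if debounce < 1:
        raise ValueError("debounce must be >= 1")
    topo = trajectory.topology
    label_rows = []
    last = None
    for frame in trajectory.frames:
        state = SystemState(
            frame.positions.copy(),
            np.zeros_like(frame.positions),
            frame.box,
            topo,
        )
        last = classify_interior_water(state, voxel=voxel, **classify_kwargs)
        label_rows.append(last.inside.copy())
    labels = np.asarray(label_rows)
    events = exchange_events_from_labels(labels, debounce)
    # report bead ids in system numbering
    events = [
        ExchangeEvent(int(last.water_bead_ids[e.bead_id]), e.direction, e.frame)
        for e in events
    ]
    last.events = events
    return last


# ---------------------------------------------------------------------------
# surfactant coverage


@dataclass
class CoverageMap:
    """Equal-area angular patches around the aggregate centre of mass."""

    counts: np.ndarray        # (n_bands, sectors_per_band)
    n_patches: int
    covered_fraction: float
    coefficient_of_variation: float
    n_beads_in_shell: int
    empty: bool = False


def _equal_area_bands(n_patches: int) -> tuple[int, int]:
    """Factor n_patches into (bands, sectors) with exactly equal patch
    areas; bands are equal slices in cos(theta)."""
    best = 1
    target = np.sqrt(n_patches / 2.0)
    for d in range(1, n_patches + 1):
        if n_patches % d == 0 and abs(d - target) < abs(best - target):
            best = d
    return best, n_patches // best


def coverage_map(
    directions: np.ndarray, n_patches: int = 32
) -> CoverageMap:
    """Bin unit(ish) direction vectors into equal-area patches."""
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    n_bands, n_sect = _equal_area_bands(n_patches)
    counts = np.zeros((n_bands, n_sect), dtype=np.int64)
    if directions.shape[0]:
        r = np.linalg.norm(directions, axis=1)
        r[r == 0] = 1.0
        z = np.clip(directions[:, 2] / r, -1.0, 1.0)
        band = np.minimum(((z + 1.0) / 2.0 * n_bands).astype(int), n_bands - 1)
        phi = np.arctan2(directions[:, 1], directions[:, 0])  # [-pi, pi)
        sect = np.minimum(
            ((phi + np.pi) / (2 * np.pi) * n_sect).astype(int), n_sect - 1
        )
        np.add.at(counts, (band, sect), 1)
    total = int(counts.sum())
    covered = float(np.count_nonzero(counts)) / n_patches
    mean = counts.mean()
    cv = float(counts.std() / mean) if mean > 0 else 0.0
    return CoverageMap(
        counts=counts,
        n_patches=n_patches,
        covered_fraction=covered,
        coefficient_of_variation=cv,
        n_beads_in_shell=total,
        empty=total == 0,
    )


def surface_coverage(
    state: SystemState,
    n_patches: int = 32,
    shell: float = 1.5,
    contact_cutoff: float = 0.6,
) -> CoverageMap:
    """Angular distribution of surfactant beads around the aggregate.

    Surfactant beads within ``shell`` nm beyond the lipid aggregate's
    outermost bead are binned into ``n_patches`` equal-area patches
    centred on the aggregate COM.  ``covered_fraction`` is the fraction
    of patches holding at least one bead; the coefficient of variation
    of patch counts summarizes inhomogeneity.  A system without
    surfactant returns an empty, flagged map.
    """
    topo = state.topology
    if "tween20" not in topo.species_names:
        return CoverageMap(
            counts=np.zeros(_equal_area_bands(n_patches), dtype=np.int64),
            n_patches=n_patches,
            covered_fraction=0.0,
            coefficient_of_variation=0.0,
            n_beads_in_shell=0,
            empty=True,
        )
    clusters = detect_aggregates(state, contact_cutoff, SOLUTE_SPECIES)
    members = clusters.largest_cluster
    pos = unwrap_cluster(state, members, contact_cutoff)
    beads = np.nonzero(np.isin(topo.molecule_id, members))[0]
    lipid_sid = (
        topo.species_names.index("tripalmitin")
        if "tripalmitin" in topo.species_names
        else -1
    )
    lipid_beads = beads[topo.species_id[beads] == lipid_sid]
    surf_sid = topo.species_names.index("tween20")
    surf_beads = beads[topo.species_id[beads] == surf_sid]

    ref = lipid_beads if lipid_beads.size else surf_beads
    w = topo.masses[ref]
    com = (w[:, None] * pos[ref]).sum(axis=0) / w.sum()
    d_surf = pos[surf_beads] - com
    if lipid_beads.size:
        r_agg = float(np.linalg.norm(pos[lipid_beads] - com, axis=1).max())
        keep = np.linalg.norm(d_surf, axis=1) <= r_agg + shell
        d_surf = d_surf[keep]
    return coverage_map(d_surf, n_patches)


def core_vs_total_rg(
    state: SystemState, contact_cutoff: float = 0.6
) -> tuple[float, float]:
    """Radius of gyration of the lipid core vs the whole aggregate
    (lipids + adsorbed surfactant)."""
    topo = state.topology
    clusters = detect_aggregates(state, contact_cutoff, SOLUTE_SPECIES)
    members = clusters.largest_cluster
    pos = unwrap_cluster(state, members, contact_cutoff)
    beads = np.nonzero(np.isin(topo.molecule_id, members))[0]
    lipid_sid = topo.species_names.index("tripalmitin")
    lipid_beads = beads[topo.species_id[beads] == lipid_sid]
    rg_total = radius_of_gyration(pos[beads], topo.masses[beads])
    rg_core = radius_of_gyration(pos[lipid_beads], topo.masses[lipid_beads])
    return rg_core, rg_total
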