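"""Molecular-dynamics engine: switched-LJ forces, BAOAB Langevin
integration, and a Monte-Carlo isotropic barostat.

Conditions of the study protocol: 20 fs time step, Lennard-Jones
truncated at 1.4 nm with a C1 switching function from 1.0 nm, periodic
boundaries, Langevin thermostat at 310 K, pressure controlled at 1 atm.
With friction gamma = 0 the integrator reduces exactly to velocity
Verlet (NVE).  All randomness comes from a single seeded generator, so
a run is bit-reproducible on one platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceFieldTables, default_forcefield
from .system import SystemState, SystemTopology
from .units import FS, KB, pressure_from_atm, pressure_to_atm


class IntegrationHazardError(RuntimeError):
    """Non-finite forces (typically a hard bead overlap)."""


class StabilityError(RuntimeError):
    """A bead moved farther than the neighbour skin in one step."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass
class RunConfig:
    """Integration parameters.  ``dt`` is in femtoseconds (default 20)."""

    dt: float = 20.0
    n_steps: int = 0
    thermostat_gamma: float = 1.0   # ps^-1; 0 disables the thermostat (NVE)
    target_T: float = 310.0         # K
    target_P: float = 1.0           # atm
    barostat: bool = False
    lj_cutoff: float = 1.4          # nm
    lj_switch_start: float = 1.0    # nm
    neighbor_skin: float = 0.3      # nm
    seed: int = 0
    output_stride: int = 1000       # steps between stored frames
    series_stride: int = 100        # steps between scalar log entries
    barostat_stride: int = 40       # steps between MC volume attempts

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.lj_switch_start >= self.lj_cutoff:
            raise ValueError("lj_switch_start must be below lj_cutoff")
        if self.neighbor_skin <= 0:
            raise ValueError("neighbor_skin must be positive")

    @property
    def dt_ps(self) -> float:
        return self.dt * FS


@dataclass
class EnergyReport:
    """Energy decomposition of one configuration (kJ/mol)."""

    bond: float
    angle: float
    lj: float
    kinetic: float
    instantaneous_temperature: float  # K
    instantaneous_pressure: float     # atm

    @property
    def potential(self) -> float:
        return self.bond + self.angle + self.lj

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.lj + self.kinetic


class ForceCalculator:
    """Force/energy evaluation with a self-maintaining Verlet list.

    The pair list covers ``cutoff + skin`` and is rebuilt whenever any
    bead has moved more than half the skin since the last build (or when
    the box changed).
    """

    def __init__(
        self,
        topology: SystemTopology,
        tables: ForceFieldTables | None = None,
        lj_cutoff: float = 1.4,
        lj_switch_start: float = 1.0,
        skin: float = 0.3,
    ):
        if lj_switch_start >= lj_cutoff:
            raise ValueError("lj_switch_start must be below lj_cutoff")
        self.topology = topology
        self.tables = tables or default_forcefield()
        self.r_cut = lj_cutoff
        self.r_on = lj_switch_start
        self.skin = skin
        self._inv_denom = 1.0 / (lj_cutoff**2 - lj_switch_start**2) ** 3
        self._pairs: tuple[np.ndarray, np.ndarray] | None = None
        self._ref_pos: np.ndarray | None = None
        self._ref_box: float | None = None

    @property
    def r_list(self) -> float:
        return self.r_cut + self.skin

    def invalidate(self) -> None:
        self._pairs = None

    def _needs_rebuild(self, positions: np.ndarray, box: float) -> bool:
        if self._pairs is None or self._ref_box != box:
            return True
        d = positions - self._ref_pos
        d -= box * np.rint(d / box)
        return float(np.max(np.einsum("ij,ij->i", d, d))) > (0.5 * self.skin) ** 2

    def _rebuild(self, positions: np.ndarray, box: float) -> None:
        topo = self.topology
        # the half-cutoff cell grid needs nc >= 2*reach + 1 to avoid
        # double counting through the periodic wrap
        if int(box / (0.5 * self.r_list)) >= 5:
            pi, pj = _kernels.build_pairs_cells(
                positions, box, self.r_list, topo.molecule_id,
                topo.excl_indptr, topo.excl_idx,
            )
        else:
            pi, pj = _kernels.build_pairs_n2(
                positions, box, self.r_list**2, topo.molecule_id,
                topo.excl_indptr, topo.excl_idx,
            )
        ti = topo.type_idx[pi]
        tj = topo.type_idx[pj]
        self._pairs = (pi, pj, topo.sigma[ti, tj] ** 2, topo.eps[ti, tj])
        self._ref_pos = positions.copy()
        self._ref_box = box

    def compute(self, positions: np.ndarray, box: float):
        """Return ``(forces, partial)`` where ``partial`` carries the
        potential-energy terms and the pair virial (kJ/mol)."""
        if self._needs_rebuild(positions, box):
            self._rebuild(positions, box)
        topo = self.topology
        forces = np.zeros_like(positions)
        pi, pj, psig2, peps = self._pairs
        e_lj, w_lj = _kernels.lj_energy_forces(
            positions, box, pi, pj, psig2, peps,
            self.r_on**2, self.r_cut**2, self._inv_denom, forces,
        )
        e_bond, w_bond = _kernels.bond_energy_forces(
            positions, box, topo.bonds, topo.bond_r0, topo.bond_k, forces
        )
        e_ang, w_ang = _kernels.angle_energy_forces(
            positions, box, topo.angles, topo.angle_cos0, topo.angle_k, forces
        )
        if not np.all(np.isfinite(forces)):
            bad = np.nonzero(~np.isfinite(forces).all(axis=1))[0]
            raise IntegrationHazardError(
                f"non-finite force on beads {bad[:4].tolist()} (overlapping beads?)"
            )
        return forces, _PartialEnergies(e_bond, e_ang, e_lj, w_lj + w_bond + w_ang)


@dataclass(frozen=True)
class _PartialEnergies:
    bond: float
    angle: float
    lj: float
    virial: float

    @property
    def potential(self) -> float:
        return self.bond + self.angle + self.lj


def _full_report(
    state: SystemState, partial: _PartialEnergies
) -> EnergyReport:
    kinetic = state.kinetic_energy()
    n = state.n_beads
    temp = 2.0 * kinetic / (3.0 * n * KB)
    volume = state.box**3
    p_internal = (2.0 * kinetic + partial.virial) / (3.0 * volume)
    return EnergyReport(
        bond=partial.bond,
        angle=partial.angle,
        lj=partial.lj,
        kinetic=kinetic,
        instantaneous_temperature=temp,
        instantaneous_pressure=pressure_to_atm(p_internal),
    )


def compute_energy_forces(
    state: SystemState,
    tables: ForceFieldTables | None = None,
    config: RunConfig | None = None,
) -> tuple[np.ndarray, EnergyReport]:
    """One-shot force and energy evaluation for a configuration."""
    cfg = config or RunConfig()
    calc = ForceCalculator(
        state.topology, tables, cfg.lj_cutoff, cfg.lj_switch_start, cfg.neighbor_skin
    )
    forces, partial = calc.compute(state.positions, state.box)
    return forces, _full_report(state, partial)


@dataclass
class Frame:
    positions: np.ndarray
    box: float
    time_ps: float   # nominal time = step * dt
    report: EnergyReport


@dataclass
class Trajectory:
    """Ordered frames plus scalar time series from one run."""

    topology: SystemTopology
    frames: list[Frame] = field(default_factory=list)
    series: dict[str, list[float]] = field(
        default_factory=lambda: {
            "time_ps": [], "total": [], "potential": [], "kinetic": [],
            "temperature": [], "pressure": [], "box": [],
        }
    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])

    def log(self, time_ps: float, report: EnergyReport, box: float) -> None:
        s = self.series
        s["time_ps"].append(time_ps)
        s["total"].append(report.total)
        s["potential"].append(report.potential)
        s["kinetic"].append(report.kinetic)
        s["temperature"].append(report.instantaneous_temperature)
        s["pressure"].append(report.instantaneous_pressure)
        s["box"].append(box)


class LangevinIntegrator:
    """BAOAB splitting of Langevin dynamics.

    B: half kick from forces; A: half drift; O: exact
    Ornstein-Uhlenbeck update ``v <- c1 v + c2 sqrt(kT/m) xi`` with
    ``c1 = exp(-gamma dt)`` and ``c2 = sqrt(1 - c1^2)``, which satisfies
    fluctuation-dissipation at the target temperature.  gamma = 0 gives
    plain velocity Verlet.
    """

    def __init__(
        self,
        state: SystemState,
        config: RunConfig,
        tables: ForceFieldTables | None = None,
        rng: np.random.Generator | None = None,
        calc: ForceCalculator | None = None,
    ):
        self.state = state
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.calc = calc or ForceCalculator(
            state.topology, tables, config.lj_cutoff,
            config.lj_switch_start, config.neighbor_skin,
        )
        self.forces, self.partial = self.calc.compute(state.positions, state.box)
        dt = config.dt_ps
        g = config.thermostat_gamma
        self._c1 = math.exp(-g * dt)
        self._c2 = math.sqrt(max(0.0, 1.0 - self._c1 * self._c1))
        self._vsig = np.sqrt(KB * config.target_T / state.topology.masses)[:, None]
        self._inv_m = (1.0 / state.topology.masses)[:, None]

    def step(self) -> EnergyReport:
        st = self.state
        cfg = self.config
        dt = cfg.dt_ps
        x, v = st.positions, st.velocities
        v += 0.5 * dt * self.forces * self._inv_m
        dx = 0.5 * dt * v
        if cfg.thermostat_gamma > 0.0:
            v *= self._c1
            v += self._c2 * self._vsig * self.rng.standard_normal(size=v.shape)
        dx += 0.5 * dt * v
        max_disp = float(np.sqrt(np.max(np.einsum("ij,ij->i", dx, dx))))
        if max_disp > cfg.neighbor_skin:
            raise StabilityError(
                f"bead displacement {max_disp:.3f} nm exceeds the neighbour skin "
                f"{cfg.neighbor_skin} nm; the time step is too large for the "
                "current forces"
            )
        x += dx
        np.mod(x, st.box, out=x)
        self.forces, self.partial = self.calc.compute(x, st.box)
        v += 0.5 * dt * self.forces * self._inv_m
        return _full_report(st, self.partial)

    # -- Monte-Carlo isotropic volume moves ---------------------------------

    def attempt_volume_move(self, dv: float) -> bool:
        """Propose V -> V + U(-dv, dv) with isotropic coordinate scaling;
        accept with the NPT Metropolis criterion.  Returns acceptance."""
        st = self.state
        cfg = self.config
        kt = KB * cfg.target_T
        p_int = pressure_from_atm(cfg.target_P)
        v_old = st.box**3
        v_new = v_old + self.rng.uniform(-dv, dv)
        if v_new <= 0:
            return False
        s = (v_new / v_old) ** (1.0 / 3.0)
        x_new = st.positions * s
        box_new = st.box * s
        saved = (self.calc._pairs, self.calc._ref_pos, self.calc._ref_box)
        self.calc.invalidate()
        try:
            f_new, part_new = self.calc.compute(x_new, box_new)
        except IntegrationHazardError:
            self.calc._pairs, self.calc._ref_pos, self.calc._ref_box = saved
            return False
        du = part_new.potential - self.partial.potential
        n = st.n_beads
        arg = -(du + p_int * (v_new - v_old)) / kt + n * math.log(v_new / v_old)
        if math.log(self.rng.random() + 1e-300) < arg:
            st.positions[:] = x_new
            st.box = box_new
            self.forces, self.partial = f_new, part_new
            return True
        # rejected: the cached forces and pair list are still valid
        self.calc._pairs, self.calc._ref_pos, self.calc._ref_box = saved
        return False


def step_langevin(
    state: SystemState,
    config: RunConfig,
    tables: ForceFieldTables | None = None,
    rng: np.random.Generator | None = None,
) -> SystemState:
    """Advance one Langevin (BAOAB) step and return the new state."""
    new = state.copy()
    LangevinIntegrator(new, config, tables, rng=rng).step()
    return new


def run_simulation(
    state: SystemState,
    config: RunConfig,
    tables: ForceFieldTables | None = None,
    sinks: list | None = None,
) -> Trajectory:
    """Integrate ``config.n_steps`` steps, applying the MC barostat when
    enabled, storing frames every ``output_stride`` steps (nominal time =
    step * dt) and scalar series every ``series_stride`` steps.

    ``sinks`` are objects with ``write_frame(state, time_ps)``; they
    receive every stored frame.  Stability failures propagate as
    :class:`StabilityError` carrying the step index.
    """
    integ = LangevinIntegrator(state, config, tables)
    traj = Trajectory(topology=state.topology)

    def emit(step: int, report: EnergyReport) -> None:
        t = step * config.dt_ps
        traj.frames.append(
            Frame(state.positions.copy(), state.box, t, report)
        )
        for sink in sinks or []:
            sink.write_frame(state, t)

    report = _full_report(state, integ.partial)
    emit(0, report)
    traj.log(0.0, report, state.box)

    dv = 0.002 * state.box**3  # adaptive MC volume-move width
    for step in range(1, config.n_steps + 1):
        try:
            report = integ.step()
        except StabilityError as err:
            raise StabilityError(f"step {step}: {err}", step=step) from None
        if config.barostat and step % config.barostat_stride == 0:
            accepted = integ.attempt_volume_move(dv)
            dv = min(max(dv * (1.05 if accepted else 0.95), 1e-4), 0.05 * state.box**3)
            report = _full_report(state, integ.partial)
        if step % config.series_stride == 0:
            traj.log(step * config.dt_ps, report, state.box)
        if step % config.output_stride == 0:
            emit(step, report)
    return traj
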