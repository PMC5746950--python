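"""Reproducible experiment presets: build, minimize, run, analyze, report.

An :class:`ExperimentPreset` ties a system composition to integration
settings and an analysis plan.  :func:`run_experiment` executes the full
protocol — solvated build, energy minimization, thermostatted/barostatted
dynamics, equilibrium-window detection, and the structural observables —
and returns a :class:`RunReport` whose every average names its frame
window.  Identical presets and seeds give identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from . import analysis
from .engine import RunConfig, Trajectory, run_simulation
from .forcefield import ForceFieldTables, default_forcefield
from .system import SystemSpec, SystemState, build_system, get_preset, minimize_energy

__version_tag__ = "lnpsim-0.1.0"


@dataclass
class ExperimentPreset:
    """Named, fully specified experiment."""

    name: str
    spec: SystemSpec
    run: RunConfig
    scale: float = 1.0
    contact_cutoff: float = 0.6     # nm, aggregate detection
    voxel: float = 0.35             # nm, interior-water grid
    n_patches: int = 32             # coverage map resolution
    analyze_water: bool = True
    minimize_steps: int = 1500
    minimize_tol: float = 50.0      # kJ/mol/nm


def desk_preset(seed: int = 0, n_steps: int = 200_000) -> ExperimentPreset:
    """Default desk-scale preset: 16 lipids in a thin water shell,
    sized to show single-cluster self-assembly on one CPU core."""
    return ExperimentPreset(
        name="desk",
        spec=get_preset("desk", seed=seed),
        run=RunConfig(
            n_steps=n_steps,
            barostat=True,
            seed=seed,
            output_stride=max(1, n_steps // 40),
            series_stride=max(1, n_steps // 400),
        ),
    )


def named_preset(name: str, scale: float = 1.0, seed: int = 0,
                 n_steps: int = 200_000) -> ExperimentPreset:
    if name.lower() == "desk":
        return desk_preset(seed=seed, n_steps=n_steps)
    return ExperimentPreset(
        name=name.lower(),
        spec=get_preset(name, seed=seed),
        run=RunConfig(
            n_steps=n_steps,
            barostat=True,
            seed=seed,
            output_stride=max(1, n_steps // 40),
            series_stride=max(1, n_steps // 400),
        ),
        scale=scale,
    )


@dataclass
class EquilibriumWindow:
    """Trailing-window stationarity check on total energy and box side.

    The trailing half of the logged series is accepted as equilibrated
    when linear fits of total energy and box side over it have slopes
    indistinguishable from zero at 95% confidence."""

    start_frame: int
    n_frames: int
    equilibrated: bool
    energy_slope_p: float
    box_slope_p: float


def detect_equilibrium_window(trajectory: Trajectory) -> EquilibriumWindow:
    s = trajectory.series
    t = np.asarray(s["time_ps"])
    n = t.size
    start = n // 2
    if n - start < 3:
        return EquilibriumWindow(start, n - start, False, 0.0, 0.0)

    def slope_p(y: np.ndarray) -> float:
        y = y[start:]
        if np.allclose(y, y[0]):
            return 1.0
        res = stats.linregress(t[start:], y)
        return float(res.pvalue)

    p_e = slope_p(np.asarray(s["total"]))
    p_b = slope_p(np.asarray(s["box"]))
    frame_times = trajectory.times()
    frame_start = int(np.searchsorted(frame_times, t[start]))
    return EquilibriumWindow(
        start_frame=frame_start,
        n_frames=trajectory.n_frames - frame_start,
        equilibrated=bool(p_e > 0.05 and p_b > 0.05),
        energy_slope_p=p_e,
        box_slope_p=p_b,
    )


@dataclass
class RunReport:
    """Observables averaged over the detected equilibrium window."""

    preset: str
    seed: int
    assembled: bool
    largest_cluster_size: int
    n_lipids: int
    window_start_frame: int
    window_n_frames: int
    equilibrated: bool
    rg_mean: float
    delta_mean: float
    density_mean: float      # lipids / nm^3, from 3N/(4 pi Rg^3)
    rg_core: float | None
    rg_total: float | None
    n_p4_inside: int | None
    n_af_inside: int | None
    covered_fraction: float | None
    coverage_cv: float | None
    mean_temperature: float
    mean_box: float
    provenance: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)


def _config_hash(preset: ExperimentPreset) -> str:
    payload = json.dumps(
        {"spec": asdict(preset.spec), "run": asdict(preset.run),
         "scale": preset.scale}, sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(
    preset: ExperimentPreset,
    tables: ForceFieldTables | None = None,
    sinks: list | None = None,
    return_trajectory: bool = False,
):
    """Execute the full protocol for one preset.

    Build -> minimize -> dynamics -> equilibrium-window detection ->
    observables.  If self-assembly is incomplete at run end (largest
    cluster smaller than the lipid count) the report is flagged
    ``assembled=False`` and all analyses are still emitted.
    """
    tables = tables or default_forcefield()
    state = build_system(preset.spec, scale=preset.scale, tables=tables)
    state = minimize_energy(
        state, tables, max_steps=preset.minimize_steps, tol=preset.minimize_tol
    )
    traj = run_simulation(state, preset.run, tables, sinks=sinks)
    window = detect_equilibrium_window(traj)
    report = analyze_trajectory(traj, preset, window, state)
    report.provenance = {
        "config_hash": _config_hash(preset),
        "seed": preset.run.seed,
        "code_version": __version_tag__,
    }
    if return_trajectory:
        return report, traj
    return report


def analyze_trajectory(
    traj: Trajectory,
    preset: ExperimentPreset,
    window: EquilibriumWindow | None = None,
    final_state: SystemState | None = None,
) -> RunReport:
    """Compute the report observables from an existing trajectory."""
    window = window or detect_equilibrium_window(traj)
    topo = traj.topology
    spec = preset.spec.scaled(preset.scale)
    n_lipids = spec.n_lipid
    cutoff = preset.contact_cutoff

    frames = traj.frames[window.start_frame:] or traj.frames[-1:]
    rgs, deltas = [], []
    for fr in frames:
        st = SystemState(fr.positions.copy(), np.zeros_like(fr.positions), fr.box, topo)
        shape = analysis.aggregate_shape(st, ("tripalmitin",), cutoff,
                                         frame_time=fr.time_ps / 1000.0)
        rgs.append(shape.rg)
        deltas.append(shape.delta)
    rg_mean = float(np.mean(rgs))
    delta_mean = float(np.mean(deltas))
    density = analysis.lipid_number_density(n_lipids, rg_mean) if n_lipids else float("nan")

    last = traj.frames[-1]
    st_last = SystemState(
        last.positions.copy(), np.zeros_like(last.positions), last.box, topo
    )
    clusters = analysis.detect_aggregates(st_last, cutoff, ("tripalmitin",))
    assembled = clusters.largest_cluster_size == n_lipids and n_lipids > 0

    rg_core = rg_total = None
    covered = cov_cv = None
    if "tween20" in topo.species_names and spec.n_surfactant > 0:
        rg_core, rg_total = analysis.core_vs_total_rg(st_last, cutoff)
        cov = analysis.surface_coverage(st_last, preset.n_patches, contact_cutoff=cutoff)
        covered, cov_cv = cov.covered_fraction, cov.coefficient_of_variation

    n_p4_in = n_af_in = None
    if preset.analyze_water and spec.n_p4 > 0 and n_lipids > 0:
        part = analysis.classify_interior_water(
            st_last, voxel=preset.voxel, contact_cutoff=cutoff
        )
        n_p4_in, n_af_in = part.n_p4_inside, part.n_af_inside

    s = traj.series
    half = len(s["temperature"]) // 2
    return RunReport(
        preset=preset.name,
        seed=preset.run.seed,
        assembled=assembled,
        largest_cluster_size=clusters.largest_cluster_size,
        n_lipids=n_lipids,
        window_start_frame=window.start_frame,
        window_n_frames=len(frames),
        equilibrated=window.equilibrated,
        rg_mean=rg_mean,
        delta_mean=delta_mean,
        density_mean=float(density),
        rg_core=rg_core,
        rg_total=rg_total,
        n_p4_inside=n_p4_in,
        n_af_inside=n_af_in,
        covered_fraction=covered,
        coverage_cv=cov_cv,
        mean_temperature=float(np.mean(s["temperature"][half:])) if s["temperature"] else 0.0,
        mean_box=float(np.mean(s["box"][half:])) if s["box"] else 0.0,
    )
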