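"""Time integration of the coupled heart-tube / red-blood-cell system.

Each step solves the instantaneous Stokes problem (moving walls, membrane
force layers), advects the membrane nodes with a Heun predictor-corrector,
and periodically redistributes membrane nodes at equal arc length.  Wall
shear stress, cross-section fluxes and membrane trajectories are sampled at
a fixed cadence; an initial transient of whole beats is discarded before
any statistics, because phase averaging downstream assumes statistical
periodicity.

With no cells the flow has no state of its own (Stokes flow is
instantaneous), so the simulator just evaluates the wall solution at the
sampling times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import h5py
from shapely.geometry import Polygon, box

from .wall_kinematics import (TubeGeometry, WallMotionModel, two_chamber_preset,
                              wall_position)
from .rbc_membrane import (MembraneParams, MembraneState, make_ellipse,
                           elastic_forces, repulsion_forces, reparameterize,
                           enclosed_area)
from . import stokes_solver as ss

__all__ = [
    "SimulationConfig",
    "WSSRecord",
    "TrajectoryRecord",
    "FluxRecord",
    "run",
    "seed_membranes",
    "concentration_profile",
    "depleted_regions",
]


log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Desk-scale defaults: sized so that n_rbc <= 20 runs in minutes."""

    geometry: TubeGeometry = None
    motion: WallMotionModel = None
    membrane: MembraneParams = field(default_factory=MembraneParams)
    n_rbc: int = 0
    seed: int = 0
    seeding_region: Optional[tuple] = None     # x-interval; default: moving span
    n_wall: int = 128
    eps_factor: float = 0.5
    membrane_eps_factor: float = 1.0
    steps_per_beat: int = 200
    n_beats: int = 8
    discard_beats: int = 2
    samples_per_beat: int = 100
    reparam_every: int = 20                    # steps between node redistributions
    mu: float = 1.0
    flux_stations: Optional[tuple] = None      # x positions; default: chamber mids + AVC
    max_energy_growth: float = 1e4

    def __post_init__(self):
        if self.geometry is None or self.motion is None:
            geometry, motion = two_chamber_preset(self.geometry)
            self.geometry = geometry
            if self.motion is None:
                self.motion = motion
        if self.n_rbc < 0:
            raise ValueError("n_rbc must be non-negative")
        if self.n_beats <= self.discard_beats:
            raise ValueError("need more beats than discarded transients")
        if self.steps_per_beat % self.samples_per_beat:
            raise ValueError("steps_per_beat must be a multiple of samples_per_beat")
        if self.flux_stations is None:
            g = self.geometry
            self.flux_stations = (0.5 * sum(g.atrium), g.avc_center,
                                  0.5 * sum(g.ventricle))
        for x in self.flux_stations:
            if not (0 <= x < self.geometry.length):
                raise ValueError("flux stations must lie in [0, tube length)")


@dataclass
class WSSRecord:
    """Wall shear stress tau(t) and normal traction at every wall station."""

    times: np.ndarray            # (n_samples,)
    tau: np.ndarray              # (n_samples, n_stations)
    normal: np.ndarray           # (n_samples, n_stations)
    station_x: np.ndarray        # (n_stations,)
    station_side: np.ndarray     # 0 = lower, 1 = upper
    period: float
    beats_retained: int
    samples_per_beat: int

    def station_series(self, x: float, side: str = "upper") -> np.ndarray:
        idx = self.station_index(x, side)
        return self.tau[:, idx]

    def station_index(self, x: float, side: str = "upper") -> int:
        want = 1 if side == "upper" else 0
        cand = np.where(self.station_side == want)[0]
        return int(cand[np.argmin(np.abs(self.station_x[cand] - x))])


@dataclass
class TrajectoryRecord:
    times: np.ndarray                 # (n_samples,)
    centroids: np.ndarray             # (n_samples, n_rbc, 2)
    areas: np.ndarray                 # (n_samples, n_rbc)
    outlines: list                    # [(time, [(n_nodes, 2), ...]), ...]
    n_rbc: int


@dataclass
class FluxRecord:
    times: np.ndarray
    flux: np.ndarray                  # (n_samples, n_flux_stations)
    station_x: np.ndarray


def seed_membranes(config: SimulationConfig) -> list[MembraneState]:
    """Rejection-sampled non-overlapping seeding along the heart tube."""
    rng = np.random.default_rng(config.seed)
    g, m = config.geometry, config.membrane
    # default: the whole moving span; narrow throats reject automatically
    region = config.seeding_region or (g.atrium[0], g.ventricle[1])
    a = max(m.semi_axes)
    states: list[MembraneState] = []
    polys: list[Polygon] = []
    margin = a + m.repulsion_cutoff
    tries = 0
    while len(states) < config.n_rbc:
        tries += 1
        if tries > 50000:
            raise SimulationError("could not place all RBCs in the seeding region")
        x = rng.uniform(region[0] + a, region[1] - a)
        # keep clear of the fully contracted wall at this station
        h_min = (g.rest_half_width(x) - config.motion.amplitude(x))
        ymax = h_min - margin
        if ymax <= 0:
            continue
        y = rng.uniform(-ymax, ymax)
        angle = rng.uniform(0, 2 * np.pi)
        cand = make_ellipse(np.array([x, y]), m, angle=angle)
        poly = Polygon(cand.positions)
        # exact outline-to-outline clearance, not circumscribed circles
        if any(poly.distance(p) <= m.repulsion_cutoff for p in polys):
            continue
        states.append(cand)
        polys.append(poly)
    return states


def _membrane_layers(states, forces, eps_m):
    pts = np.vstack([s.positions for s in states])
    frc = np.vstack(forces)
    return [(pts, frc, eps_m)]


def _wall_gap_fn(model, geometry, t):
    def gap(points):
        yu = wall_position(model, geometry, points[:, 0], t, "upper")
        yl = wall_position(model, geometry, points[:, 0], t, "lower")
        return yu - points[:, 1], points[:, 1] - yl
    return gap


def _solve_at(config, t, states, operator_cache=None):
    """Wall solve at time t with current membrane states; returns solution."""
    mesh = ss.build_wall_mesh(config.motion, config.geometry, t,
                              config.n_wall, config.eps_factor)
    A = None
    if operator_cache is not None:
        key = round(t / (config.motion.period / config.steps_per_beat))
        if key in operator_cache:
            A = operator_cache[key]
        else:
            A = ss.assemble_system(mesh, config.mu)
            operator_cache.clear()
            operator_cache[key] = A
    membranes = []
    mem_vel = None
    if states:
        gap = _wall_gap_fn(config.motion, config.geometry, t)
        f_el = [elastic_forces(s, config.membrane) for s in states]
        f_rep = repulsion_forces(states, config.membrane, wall_gap=gap)
        forces = [fe + fr for fe, fr in zip(f_el, f_rep)]
        spacing = np.mean([np.mean(np.linalg.norm(
            np.roll(s.positions, -1, axis=0) - s.positions, axis=1)) for s in states])
        eps_m = config.membrane_eps_factor * spacing
        membranes = _membrane_layers(states, forces, eps_m)
        mem_vel = ss._layer_velocity(mesh.points, membranes[0][0], membranes[0][1],
                                     mesh.length, eps_m, config.mu)
    sol = ss.solve_wall_forces(mesh, mu=config.mu, membrane_velocity=mem_vel,
                               membranes=membranes, operator=A)
    return sol


def _advance(config, states, t, dt, cache):
    """One Heun step of all membrane nodes; returns solution at time t."""
    sol1 = _solve_at(config, t, states, cache)
    pts0 = [s.positions.copy() for s in states]
    u1 = sol1.velocity_at(np.vstack(pts0))
    u1 = np.split(u1, np.cumsum([len(p) for p in pts0])[:-1])
    pred = []
    for s, p, u in zip(states, pts0, u1):
        sp = s.copy()
        sp.positions = p + dt * u
        pred.append(sp)
    sol2 = _solve_at(config, t + dt, pred, cache)
    u2 = sol2.velocity_at(np.vstack([s.positions for s in pred]))
    u2 = np.split(u2, np.cumsum([len(p) for p in pts0])[:-1])
    for s, p, ua, ub in zip(states, pts0, u1, u2):
        s.positions = p + 0.5 * dt * (ua + ub)
    return sol1


def _check_states(config, states, t):
    for i, s in enumerate(states):
        yu = wall_position(config.motion, config.geometry, s.positions[:, 0], t, "upper")
        yl = wall_position(config.motion, config.geometry, s.positions[:, 0], t, "lower")
        if np.any(s.positions[:, 1] >= yu) or np.any(s.positions[:, 1] <= yl):
            raise SimulationError(
                f"membrane {i} penetrated a wall at t={t:.4f}; state dump: "
                f"centroid={s.centroid}, use a smaller time step or stronger repulsion")


def run(config: SimulationConfig):
    """Run the simulation; returns (WSSRecord, TrajectoryRecord, FluxRecord)."""
    T = config.motion.period
    dt = T / config.steps_per_beat
    sample_every = config.steps_per_beat // config.samples_per_beat
    n_steps = config.n_beats * config.steps_per_beat
    discard_steps = config.discard_beats * config.steps_per_beat

    states = seed_membranes(config) if config.n_rbc else []
    E0 = None
    if states:
        from .rbc_membrane import elastic_energy
        E0 = sum(elastic_energy(s, config.membrane) for s in states) + 1e-12

    times, taus, norms, fluxes, cents, areas = [], [], [], [], [], []
    outlines = []
    cache: dict = {}

    # fixed recording stations (collocation points move with the wall shape)
    L = config.geometry.length
    x_st = np.linspace(0.0, L, config.n_wall, endpoint=False)
    station_x = np.concatenate([x_st, x_st])
    station_side = np.concatenate([np.zeros(config.n_wall, int),
                                   np.ones(config.n_wall, int)])

    def record(sol, t, step):
        tau, sn = ss.wall_shear_stress(sol)
        row_t = np.empty(2 * config.n_wall)
        row_n = np.empty(2 * config.n_wall)
        for lab in (0, 1):
            m = sol.mesh.side == lab
            xs = sol.mesh.x[m]
            order = np.argsort(xs)
            dst = slice(0, config.n_wall) if lab == 0 else slice(config.n_wall, None)
            row_t[dst] = np.interp(x_st, xs[order], tau[m][order], period=L)
            row_n[dst] = np.interp(x_st, xs[order], sn[m][order], period=L)
        times.append(t)
        taus.append(row_t)
        norms.append(row_n)
        fluxes.append([sol.flux(xs) for xs in config.flux_stations])
        if states:
            cents.append([s.centroid for s in states])
            areas.append([enclosed_area(s.positions) for s in states])
            if step % (sample_every * 10) == 0:
                outlines.append((t, [s.positions.copy() for s in states]))

    if not states:
        # Stokes flow is instantaneous: no advected state, sample directly
        for step in range(discard_steps, n_steps):
            if step % sample_every:
                continue
            t = step * dt
            sol = _solve_at(config, t, states)
            record(sol, t, step)
    else:
        from .rbc_membrane import elastic_energy
        for step in range(n_steps):
            t = step * dt
            sol = _advance(config, states, t, dt, cache)
            if step >= discard_steps and step % sample_every == 0:
                record(sol, t, step)
            if (step + 1) % config.reparam_every == 0:
                # a transiently tangled cell keeps its nodes this cycle; the
                # elastic forces act to unfold it and the next cycle retries
                fresh = []
                for s in states:
                    try:
                        fresh.append(reparameterize(s))
                    except ValueError:
                        log.warning("skipping node redistribution of a "
                                    "self-intersecting membrane at t=%.3f", t)
                        fresh.append(s)
                states = fresh
            _check_states(config, states, t + dt)
            E = sum(elastic_energy(s, config.membrane) for s in states)
            if E0 and E / E0 > config.max_energy_growth:
                raise SimulationError(
                    f"elastic energy grew by {E / E0:.1e} at t={t:.4f}: time-step "
                    "instability; reduce the step size")

    wss = WSSRecord(
        times=np.asarray(times), tau=np.asarray(taus), normal=np.asarray(norms),
        station_x=station_x, station_side=station_side, period=T,
        beats_retained=config.n_beats - config.discard_beats,
        samples_per_beat=config.samples_per_beat,
    )
    traj = TrajectoryRecord(
        times=np.asarray(times),
        centroids=np.asarray(cents) if cents else np.zeros((len(times), 0, 2)),
        areas=np.asarray(areas) if areas else np.zeros((len(times), 0)),
        outlines=outlines, n_rbc=config.n_rbc,
    )
    flux = FluxRecord(times=np.asarray(times), flux=np.asarray(fluxes),
                      station_x=np.asarray(config.flux_stations))
    return wss, traj, flux


def trace_tracers(config: SimulationConfig, points, t_start: float,
                  t_end: float, n_steps: int) -> np.ndarray:
    """Advect passive tracers through the no-RBC flow with Heun steps.

    ``t_end < t_start`` integrates the time-reversed motion; by kinematic
    reversibility of Stokes flow, reversing the wall motion must retrace
    the trajectories.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    dt = (t_end - t_start) / n_steps
    for k in range(n_steps):
        t = t_start + k * dt
        sol1 = _solve_at(config, t, [])
        u1 = sol1.velocity_at(pts)
        sol2 = _solve_at(config, t + dt, [])
        u2 = sol2.velocity_at(pts + dt * u1)
        pts = pts + 0.5 * dt * (u1 + u2)
    return pts


def concentration_profile(traj: TrajectoryRecord, geometry: TubeGeometry,
                          bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged RBC area per unit axial length, per axial bin.

    Returns (bin_centers, concentration); summing concentration * bin_width
    over bins recovers the mean total cell area.  Cell outlines are clipped
    exactly against the bin strips (periodic in x).
    """
    if bins <= 0:
        raise ValueError("need a positive number of bins")
    L = geometry.length
    edges = np.linspace(0.0, L, bins + 1)
    width = L / bins
    acc = np.zeros(bins)
    n_snap = 0
    for t, polys in _outline_iter(traj):
        n_snap += 1
        for pts in polys:
            shift = L * np.round(np.mean(pts[:, 0]) / L - 0.5)
            poly = Polygon(np.column_stack([pts[:, 0] - shift, pts[:, 1]]))
            if not poly.is_valid:
                poly = poly.buffer(0)
            x0, _, x1, _ = poly.bounds
            b0 = max(int(np.floor(x0 / width)), -bins)
            b1 = min(int(np.floor(x1 / width)), 2 * bins - 1)
            for b in range(b0, b1 + 1):
                strip = box(edges[0] + b * width, -1e9, edges[0] + (b + 1) * width, 1e9)
                a = poly.intersection(strip).area
                acc[b % bins] += a
    if n_snap == 0:
        return 0.5 * (edges[:-1] + edges[1:]), np.zeros(bins)
    return 0.5 * (edges[:-1] + edges[1:]), acc / (n_snap * width)


def _outline_iter(traj: TrajectoryRecord):
    if traj.outlines:
        yield from traj.outlines
    elif traj.n_rbc == 0:
        return


def depleted_regions(bin_centers: np.ndarray, concentration: np.ndarray,
                     threshold: float) -> list[tuple[float, float]]:
    """Maximal axial intervals where concentration < threshold * spatial mean."""
    mean = concentration.mean()
    if mean == 0:
        return []
    low = concentration < threshold * mean
    intervals = []
    width = bin_centers[1] - bin_centers[0] if len(bin_centers) > 1 else 0.0
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = bin_centers[i] - width / 2
        elif not flag and start is not None:
            intervals.append((start, bin_centers[i - 1] + width / 2))
            start = None
    if start is not None:
        intervals.append((start, bin_centers[-1] + width / 2))
    return intervals


def save_records(path, wss: WSSRecord, traj: TrajectoryRecord, flux: FluxRecord,
                 config: SimulationConfig) -> None:
    """Checkpoint all records (and the config provenance) to HDF5."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("wss")
        for name in ("times", "tau", "normal", "station_x", "station_side"):
            g.create_dataset(name, data=getattr(wss, name))
        g.attrs["period"] = wss.period
        g.attrs["beats_retained"] = wss.beats_retained
        g.attrs["samples_per_beat"] = wss.samples_per_beat
        g = fh.create_group("trajectories")
        g.create_dataset("times", data=traj.times)
        g.create_dataset("centroids", data=traj.centroids)
        g.create_dataset("areas", data=traj.areas)
        g.attrs["n_rbc"] = traj.n_rbc
        for i, (t, polys) in enumerate(traj.outlines):
            snap = g.create_group(f"outlines/{i:05d}")
            snap.attrs["time"] = t
            for j, pts in enumerate(polys):
                snap.create_dataset(f"{j:04d}", data=pts)
        g = fh.create_group("flux")
        g.create_dataset("times", data=flux.times)
        g.create_dataset("flux", data=flux.flux)
        g.create_dataset("station_x", data=flux.station_x)
        fh.attrs["seed"] = config.seed
        fh.attrs["n_rbc"] = config.n_rbc


def load_wss(path) -> WSSRecord:
    with h5py.File(path, "r") as fh:
        g = fh["wss"]
        return WSSRecord(
            times=g["times"][:], tau=g["tau"][:], normal=g["normal"][:],
            station_x=g["station_x"][:], station_side=g["station_side"][:],
            period=g.attrs["period"], beats_retained=int(g.attrs["beats_retained"]),
            samples_per_beat=int(g.attrs["samples_per_beat"]),
        )
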