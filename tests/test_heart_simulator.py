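import numpy as np
import pytest

from valvemorph.heart_simulator import (
    SimulationConfig, TrajectoryRecord, run, seed_membranes,
    concentration_profile, depleted_regions, save_records, load_wss,
)
from valvemorph.rbc_membrane import MembraneParams, make_ellipse, enclosed_area
from valvemorph.wall_kinematics import TubeGeometry, WallMotionModel


def _still_tube():
    geometry = TubeGeometry()
    motion = WallMotionModel.from_tables(geometry.length, [0, 5], [0, 0], [0, 0])
    return geometry, motion


def test_motionless_tube_without_cells_is_quiescent():
    geometry, motion = _still_tube()
    cfg = SimulationConfig(geometry=geometry, motion=motion, n_rbc=0,
                           n_wall=48, steps_per_beat=20, samples_per_beat=10,
                           n_beats=2, discard_beats=1)
    wss, traj, flux = run(cfg)
    assert np.abs(wss.tau).max() < 1e-10
    assert np.abs(flux.flux).max() < 1e-10


def test_identical_config_and_seed_reproduce_bit_identical_records():
    kwargs = dict(n_rbc=2, seed=42, n_wall=48, steps_per_beat=30,
                  samples_per_beat=15, n_beats=2, discard_beats=1)
    out1 = run(SimulationConfig(**kwargs))
    out2 = run(SimulationConfig(**kwargs))
    assert np.array_equal(out1[0].tau, out2[0].tau)
    assert np.array_equal(out1[1].centroids, out2[1].centroids)
    assert np.array_equal(out1[2].flux, out2[2].flux)


def test_seeding_is_non_overlapping_and_inside_the_tube():
    from shapely.geometry import Polygon
    cfg = SimulationConfig(n_rbc=15, seed=1)
    states = seed_membranes(cfg)
    assert len(states) == 15
    polys = [Polygon(s.positions) for s in states]
    for i in range(15):
        for j in range(i + 1, 15):
            assert polys[i].distance(polys[j]) > 0
    centers = np.array([s.centroid for s in states])
    h = cfg.geometry.rest_half_width(centers[:, 0])
    assert np.all(np.abs(centers[:, 1]) < h)


def test_cell_areas_conserved_during_coupled_run():
    cfg = SimulationConfig(n_rbc=2, seed=5, n_wall=64, steps_per_beat=60,
                           samples_per_beat=20, n_beats=2, discard_beats=0)
    wss, traj, flux = run(cfg)
    drift = np.abs(traj.areas[-1] / traj.areas[0] - 1.0)
    assert drift.max() < 0.01


def test_mirror_symmetric_pump_loads_both_walls_equally(norbc_run):
    wss = norbc_run["wss"]
    n = norbc_run["config"].n_wall
    # same +x tangent convention on both walls: mirror symmetry makes the
    # shear traction equal station by station
    np.testing.assert_allclose(wss.tau[:, :n], wss.tau[:, n:], atol=1e-8)


def test_concentration_profile_of_static_cell_integrates_to_its_area():
    geometry = TubeGeometry()
    params = MembraneParams()
    cell = make_ellipse((2.5, 0.0), params)
    traj = TrajectoryRecord(times=np.array([0.0]),
                            centroids=np.array([[[2.5, 0.0]]]),
                            areas=np.array([[enclosed_area(cell.positions)]]),
                            outlines=[(0.0, [cell.positions])], n_rbc=1)
    centers, conc = concentration_profile(traj, geometry, bins=40)
    width = geometry.length / 40
    total = conc.sum() * width
    assert total == pytest.approx(enclosed_area(cell.positions), rel=1e-6)
    # localized: only bins overlapping the cell are nonzero
    nz = centers[conc > 0]
    assert nz.min() > 2.5 - 0.5 and nz.max() < 2.5 + 0.5


def test_uniform_seeding_gives_uniform_profile_within_sampling_error():
    geometry = TubeGeometry()
    rng = np.random.default_rng(0)
    params = MembraneParams(semi_axes=(0.08, 0.08))
    n_cells, n_snap = 60, 30
    outlines = []
    for k in range(n_snap):
        cells = []
        for _ in range(n_cells):
            c = (rng.uniform(0, geometry.length), rng.uniform(-0.3, 0.3))
            cells.append(make_ellipse(c, params).positions)
        outlines.append((float(k), cells))
    traj = TrajectoryRecord(times=np.arange(n_snap, dtype=float),
                            centroids=np.zeros((n_snap, n_cells, 2)),
                            areas=np.zeros((n_snap, n_cells)),
                            outlines=outlines, n_rbc=n_cells)
    centers, conc = concentration_profile(traj, geometry, bins=10)
    expect = n_cells * np.pi * 0.08 ** 2 / geometry.length
    # binomial sampling error of ~180 cells per bin across snapshots
    assert np.abs(conc / expect - 1.0).max() < 0.2


def test_depleted_regions_found_by_threshold():
    centers = np.linspace(0.5, 9.5, 10)
    conc = np.ones(10)
    assert depleted_regions(centers, conc, 0.5) == []
    conc2 = conc.copy(); conc2[3] = 0.0
    (lo, hi), = depleted_regions(centers, conc2, 0.5)
    assert lo == pytest.approx(3.0) and hi == pytest.approx(4.0)
    conc3 = conc.copy(); conc3[[2, 3, 7]] = 0.05
    intervals = depleted_regions(centers, conc3, 0.5)
    # brute-force scan oracle
    mean = conc3.mean()
    low = conc3 < 0.5 * mean
    assert len(intervals) == 2
    assert intervals[0][0] == pytest.approx(2.0)
    assert intervals[0][1] == pytest.approx(4.0)
    assert intervals[1][0] == pytest.approx(7.0)


def test_records_round_trip_through_hdf5(tmp_path, norbc_run):
    path = tmp_path / "records.h5"
    save_records(path, norbc_run["wss"],
                 TrajectoryRecord(times=norbc_run["wss"].times,
                                  centroids=np.zeros((len(norbc_run["wss"].times), 0, 2)),
                                  areas=np.zeros((len(norbc_run["wss"].times), 0)),
                                  outlines=[], n_rbc=0),
                 norbc_run["flux"], norbc_run["config"])
    wss2 = load_wss(path)
    assert np.array_equal(wss2.tau, norbc_run["wss"].tau)
    assert wss2.period == norbc_run["wss"].period


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_beats=2, discard_beats=2)
    with pytest.raises(ValueError):
        SimulationConfig(steps_per_beat=100, samples_per_beat=33)
    with pytest.raises(ValueError):
        SimulationConfig(flux_stations=(99.0,))
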