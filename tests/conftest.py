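import numpy as np
import pytest

from valvemorph.heart_simulator import SimulationConfig, run
from valvemorph.shear_decomposition import spatial_profiles
from valvemorph.synthetic_data import PhantomSpec, make_phantom
from valvemorph import stokes_solver as ss


@pytest.fixture(scope="session")
def norbc_run():
    """Default two-chamber pump, no cells, 6 retained beats.

    Shared by the decomposition-pattern and nonperiodic-component tests;
    Stokes flow without cells is deterministic, so one run serves all.
    """
    cfg = SimulationConfig(n_rbc=0, n_wall=128, steps_per_beat=100,
                           samples_per_beat=50, n_beats=8, discard_beats=2)
    wss, traj, flux = run(cfg)
    dec = spatial_profiles(wss, n_harmonics=3, bins=50)
    return {"config": cfg, "wss": wss, "flux": flux, "dec": dec}


@pytest.fixture(scope="session")
def phantom_pair():
    """Default curved-tube phantom at both timepoints (true shortening -0.30)."""
    spec = PhantomSpec()
    img1, tr1 = make_phantom(spec, 1)
    img2, tr2 = make_phantom(spec, 2)
    return {"spec": spec, "img1": img1, "img2": img2, "tr1": tr1, "tr2": tr2}


def flat_channel_mesh(length=2.0, half_height=1.0, n=128, u_upper=0.0,
                      u_lower=0.0, eps_factor=1.0):
    """Static plane-channel mesh for closed-form solver oracles."""
    x = np.linspace(0.0, length, n, endpoint=False)
    dx = length / n
    tang = np.tile([1.0, 0.0], (2 * n, 1))
    norm = np.vstack([np.tile([0.0, -1.0], (n, 1)), np.tile([0.0, 1.0], (n, 1))])
    vel = np.vstack([np.tile([u_lower, 0.0], (n, 1)),
                     np.tile([u_upper, 0.0], (n, 1))])
    return ss.BoundaryMesh(
        x=np.concatenate([x, x]),
        y=np.concatenate([np.full(n, -half_height), np.full(n, half_height)]),
        tangents=tang, normals=norm, ds=np.full(2 * n, dx), velocity=vel,
        side=np.concatenate([np.zeros(n, int), np.ones(n, int)]),
        length=length, eps=eps_factor * dx, n_per_wall=n,
    )
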