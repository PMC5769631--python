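"""Zero-Reynolds-number flow solver for the periodic heart-tube channel.

The flow between the moving walls is represented by single layers of
regularized Stokeslets on the two walls (and, when red blood cells are
present, on each membrane).  The domain is periodic in ``x`` with period
``L``; instead of truncating an image sum, the kernel uses the closed-form
singly periodic 2D Stokeslet.  Writing ``k = 2*pi/L`` and
``w = cosh(k*y) - cos(k*x)``,

    G_xx = -Lam - (k*y/2) * sinh(k*y) / w
    G_yy = -Lam + (k*y/2) * sinh(k*y) / w
    G_xy =        (k*y/2) * sin(k*x)  / w,      Lam = log(w/2) / 2

which reduces to the free-space Stokeslet ``-delta_ij log r + r_i r_j / r^2``
as ``k*r -> 0`` (up to an additive constant on the diagonal, which only
re-gauges the indeterminate mean flow).  Near the evaluation point the
nearest periodic image is replaced by the regularized free-space Stokeslet
with blob scale ``eps``:

    G_eps = -delta_ij * log(sqrt(r^2+eps^2)) + (r_i r_j + delta_ij eps^2)/(r^2+eps^2)

and the smooth remainder ``G_periodic - G_singular`` is kept in closed form,
so periodicity is exact and no image truncation parameter exists.  Both
pieces are exactly divergence-free.

There is no inertia anywhere in this module: the zebrafish heart operates at
Re < 1 and the equations solved are the steady Stokes equations at each
instant, with time entering only through the boundary motion.

The indeterminate mean axial pressure gradient of a periodic channel is an
explicit degree of freedom: by default it is zero (pumping arises from wall
motion alone); alternatively a net flux can be imposed and the conjugate
pressure gradient is solved for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
import scipy.linalg

from .wall_kinematics import TubeGeometry, WallMotionModel, wall_position, wall_velocity

__all__ = [
    "BoundaryMesh",
    "FlowSolution",
    "build_wall_mesh",
    "assemble_system",
    "solve_wall_forces",
    "wall_shear_stress",
    "velocity_at",
    "periodic_stokeslet_blocks",
]


def periodic_stokeslet_blocks(targets, sources, length, eps):
    """Kernel blocks (Gxx, Gxy, Gyy) between target and source points.

    Returns three (n_targets, n_sources) arrays; velocities follow as
    ``u = (G @ F) / (4 pi mu)`` with point forces F.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    k = 2.0 * np.pi / length
    dx = targets[:, 0, None] - sources[None, :, 0]
    dy = targets[:, 1, None] - sources[None, :, 1]
    dx -= length * np.round(dx / length)  # nearest periodic image

    r2 = dx * dx + dy * dy
    R2 = r2 + eps * eps
    logR = 0.5 * np.log(R2)
    # regularized free-space Stokeslet of the nearest image
    gxx = -logR + (dx * dx + eps * eps) / R2
    gyy = -logR + (dy * dy + eps * eps) / R2
    gxy = dx * dy / R2

    # smooth periodic remainder: G_periodic_singular - G_singular
    ky = k * dy
    w = np.cosh(ky) - np.cos(k * dx)
    with np.errstate(divide="ignore", invalid="ignore"):
        dlog = -0.5 * np.log(w / (2.0 * np.where(r2 > 0, r2, 1.0)))
        Y = 0.5 * ky * np.sinh(ky) / w
        X = 0.5 * ky * np.sin(k * dx) / w
        dxx = dlog - Y - dx * dx / r2
        dyy = dlog + Y - dy * dy / r2
        dxy = X - dx * dy / r2
    # removable singularity at coincident points (and numerically tiny r)
    tiny = r2 < (1e-7 * length) ** 2
    if np.any(tiny):
        lim = -np.log(k / 2.0)
        dxx = np.where(tiny, lim - 1.0, dxx)
        dyy = np.where(tiny, lim, dyy)
        dxy = np.where(tiny, 0.0, dxy)

    return gxx + dxx, gxy + dxy, gyy + dyy


def _sinhc(v):
    """sinh(v)/v, stable at 0."""
    small = np.abs(v) < 1e-4
    vs = np.where(small, 1.0, v)
    return np.where(small, 1.0 + v * v / 6.0, np.sinh(vs) / vs)


def _gprime_over_v(v):
    """(v cosh v - sinh v)/v^3, stable at 0 (limit 1/3)."""
    small = np.abs(v) < 1e-3
    vs = np.where(small, 1.0, v)
    return np.where(small, 1.0 / 3.0 + v * v / 30.0,
                    (vs * np.cosh(vs) - np.sinh(vs)) / vs ** 3)


def periodic_stress_kernel(targets, sources, length, eps):
    """Fully symmetric third-order stress kernel components.

    Returns (Txxx, Txxy, Txyy, Tyyy), each (n_targets, n_sources), such that
    the stress at a target due to point forces F is
    ``sigma_ij = T_ijl F_l`` (pressure included).  Built as the regularized
    free-space stresslet of the nearest image plus the closed-form smooth
    remainder of the periodic image sum.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    k = 2.0 * np.pi / length
    dx = targets[:, 0, None] - sources[None, :, 0]
    dy = targets[:, 1, None] - sources[None, :, 1]
    dx -= length * np.round(dx / length)
    r2 = dx * dx + dy * dy
    S = r2 + eps * eps

    # regularized free-space stresslet (nearest image), pressure included
    pref = -1.0 / (2.0 * np.pi * S * S)
    e2 = eps * eps
    t_xxx = pref * (3.0 * e2 * dx + 2.0 * dx ** 3)
    t_xxy = pref * (e2 * dy + 2.0 * dx * dx * dy)
    t_xyy = pref * (e2 * dx + 2.0 * dx * dy * dy)
    t_yyy = pref * (3.0 * e2 * dy + 2.0 * dy ** 3)

    # periodic image sums of the singular stresslet, in closed form:
    # moments M_p = sum_n x_n^p / r_n^4 and W1 = sum_n x_n / r_n^2
    u, v = k * dx, k * dy
    tiny = r2 < (1e-7 * length) ** 2
    w = np.cosh(v) - np.cos(u)
    w = np.where(tiny, 1.0, w)
    g = _sinhc(v)
    W1 = 0.5 * k * np.sin(u) / w
    S2 = 0.5 * k * k * g / w                       # sum 1/r^2
    Z = np.where(tiny, 1.0, 0.5 * (u + 1j * v))
    Q = 0.25 * k * k / np.sin(Z) ** 2              # sum 1/(z - nL)^2
    M2 = 0.5 * (S2 + Q.real)
    M1 = 0.25 * k ** 3 * g * np.sin(u) / w ** 2
    M0 = 0.25 * k ** 4 * (g * g / w ** 2 - _gprime_over_v(v) / w)
    p_xxx = W1 - dy * dy * M1
    p_xxy = dy * M2
    p_xyy = dy * dy * M1
    p_yyy = dy ** 3 * M0

    # subtract the singular nearest image contained in the periodic sums
    inv_r4 = 1.0 / np.where(tiny, 1.0, r2 * r2)
    s_xxx = dx ** 3 * inv_r4
    s_xxy = dx * dx * dy * inv_r4
    s_xyy = dx * dy * dy * inv_r4
    s_yyy = dy ** 3 * inv_r4
    rem_xxx = np.where(tiny, 0.0, p_xxx - s_xxx)
    rem_xxy = np.where(tiny, 0.0, p_xxy - s_xxy)
    rem_xyy = np.where(tiny, 0.0, p_xyy - s_xyy)
    rem_yyy = np.where(tiny, 0.0, p_yyy - s_yyy)

    c = -1.0 / np.pi
    return (t_xxx + c * rem_xxx, t_xxy + c * rem_xxy,
            t_xyy + c * rem_xyy, t_yyy + c * rem_yyy)


def stress_traction(targets, normals, sources, forces, length, eps):
    """Traction sigma . n at targets induced by a layer of point forces."""
    Txxx, Txxy, Txyy, Tyyy = periodic_stress_kernel(targets, sources, length, eps)
    Fx, Fy = forces[:, 0], forces[:, 1]
    nx, ny = normals[:, 0], normals[:, 1]
    sxx = Txxx @ Fx + Txxy @ Fy
    sxy = Txxy @ Fx + Txyy @ Fy
    syy = Txyy @ Fx + Tyyy @ Fy
    tx = sxx * nx + sxy * ny
    ty = sxy * nx + syy * ny
    return np.column_stack([tx, ty])


@dataclass
class BoundaryMesh:
    """Collocation representation of the two moving walls at one instant.

    Points are ordered lower wall then upper wall, each uniform in ``x``.
    Normals point out of the fluid; tangents point toward ``+x``.
    """

    x: np.ndarray
    y: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    ds: np.ndarray
    velocity: np.ndarray
    side: np.ndarray          # 0 = lower, 1 = upper
    length: float
    eps: float
    n_per_wall: int
    time: float = 0.0

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def station_index(self, x_station, side: str) -> int:
        """Index of the collocation point nearest to x_station on a wall."""
        want = 1 if side == "upper" else 0
        mask = self.side == want
        idx = np.where(mask)[0]
        dx = np.abs(np.mod(self.x[idx] - x_station + self.length / 2, self.length)
                    - self.length / 2)
        return int(idx[np.argmin(dx)])


def build_wall_mesh(model: WallMotionModel, geometry: TubeGeometry, t: float,
                    n_per_wall: int = 128, eps_factor: float = 0.5) -> BoundaryMesh:
    """Collocation mesh on both walls at time t.

    Points are uniform in ``x`` with per-point arc-length weights ``ds``;
    the regularization scale is ``eps_factor`` times the mean spacing.
    """
    L = geometry.length
    n_fine = max(16 * n_per_wall, 1024)
    x_fine = np.linspace(0.0, L, n_fine, endpoint=False)
    dxf = L / n_fine

    xs, ys, ts_, ns_, dss, vel, side = [], [], [], [], [], [], []
    for s_lab, s_name in ((0, "lower"), (1, "upper")):
        y_fine = np.asarray(wall_position(model, geometry, x_fine, t, s_name))
        seg = np.sqrt(dxf ** 2 + np.diff(np.append(y_fine, y_fine[0])) ** 2)
        s_cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = s_cum[-1]
        # collocation uniform in arc length along the wall curve
        s_targets = np.linspace(0.0, total, n_per_wall, endpoint=False)
        xw = np.interp(s_targets, s_cum, np.append(x_fine, L))
        y = np.asarray(wall_position(model, geometry, xw, t, s_name))
        slope_fine = np.gradient(y_fine, dxf, edge_order=2)
        slope = np.interp(xw, x_fine, slope_fine, period=L)
        tg = np.column_stack([np.ones_like(slope), slope])
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        if s_name == "upper":
            nm = np.column_stack([-tg[:, 1], tg[:, 0]])   # +y-ish, out of fluid
        else:
            nm = np.column_stack([tg[:, 1], -tg[:, 0]])   # -y-ish, out of fluid
        ds = np.full(n_per_wall, total / n_per_wall)
        v = np.asarray(wall_velocity(model, geometry, xw, t, s_name))
        xs.append(xw); ys.append(y); ts_.append(tg); ns_.append(nm)
        dss.append(ds); vel.append(np.column_stack([np.zeros_like(v), v]))
        side.append(np.full(n_per_wall, s_lab))

    ds_all = np.concatenate(dss)
    eps = eps_factor * float(np.mean(ds_all))
    if eps < np.mean(ds_all) / 10.0:
        warnings.warn("regularization scale below spacing/10: system may be "
                      "ill-conditioned", stacklevel=2)
    return BoundaryMesh(
        x=np.concatenate(xs), y=np.concatenate(ys),
        tangents=np.vstack(ts_), normals=np.vstack(ns_),
        ds=ds_all, velocity=np.vstack(vel),
        side=np.concatenate(side).astype(int),
        length=L, eps=eps, n_per_wall=n_per_wall, time=t,
    )


def assemble_system(mesh: BoundaryMesh, mu: float = 1.0) -> np.ndarray:
    """Dense operator mapping wall point forces to wall velocities.

    Unknowns are point forces (density times arc weight), ordered
    ``[Fx..., Fy...]``; by kernel reciprocity the matrix is symmetric.
    """
    gxx, gxy, gyy = periodic_stokeslet_blocks(mesh.points, mesh.points,
                                              mesh.length, mesh.eps)
    A = np.block([[gxx, gxy], [gxy, gyy]]) / (4.0 * np.pi * mu)
    return A


def _flux_row(mesh: BoundaryMesh, x_station: float, mu: float, n_quad: int = 48):
    """Quadrature row computing net axial flux through a cross-section."""
    i_lo = mesh.station_index(x_station, "lower")
    i_up = mesh.station_index(x_station, "upper")
    y_lo, y_up = mesh.y[i_lo], mesh.y[i_up]
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    yq = 0.5 * (y_up - y_lo) * nodes + 0.5 * (y_up + y_lo)
    wq = 0.5 * (y_up - y_lo) * weights
    pts = np.column_stack([np.full(n_quad, x_station), yq])
    gxx, gxy, _ = periodic_stokeslet_blocks(pts, mesh.points, mesh.length, mesh.eps)
    row = np.concatenate([wq @ gxx, wq @ gxy]) / (4.0 * np.pi * mu)
    # flux of the parabolic pressure-gradient mode u = G y^2 / (2 mu)
    col_g = float(np.sum(wq * yq ** 2) / (2.0 * mu))
    return row, col_g, yq, wq


@dataclass
class FlowSolution:
    """Instantaneous Stokes solution: wall forces plus optional extras."""

    mesh: BoundaryMesh
    wall_forces: np.ndarray              # (N, 2) point forces
    mu: float = 1.0
    pressure_gradient: float = 0.0       # mean dp/dx over the period
    membranes: list = field(default_factory=list)  # (points, forces, eps)
    residual: float = 0.0

    def velocity_at(self, points) -> np.ndarray:
        """Total velocity: wall layer + membrane layers + pressure mode."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        u = _layer_velocity(points, self.mesh.points, self.wall_forces,
                            self.mesh.length, self.mesh.eps, self.mu)
        for mpts, mfrc, meps in self.membranes:
            u += _layer_velocity(points, mpts, mfrc, self.mesh.length, meps, self.mu)
        if self.pressure_gradient != 0.0:
            u[:, 0] += self.pressure_gradient * points[:, 1] ** 2 / (2.0 * self.mu)
        return u

    def flux(self, x_station: float, n_quad: int = 48) -> float:
        """Net axial volume flux through the cross-section at x_station."""
        i_lo = self.mesh.station_index(x_station, "lower")
        i_up = self.mesh.station_index(x_station, "upper")
        y_lo, y_up = self.mesh.y[i_lo], self.mesh.y[i_up]
        nodes, weights = np.polynomial.legendre.leggauss(n_quad)
        yq = 0.5 * (y_up - y_lo) * nodes + 0.5 * (y_up + y_lo)
        wq = 0.5 * (y_up - y_lo) * weights
        pts = np.column_stack([np.full(n_quad, x_station), yq])
        u = self.velocity_at(pts)
        return float(np.sum(wq * u[:, 0]))


def _layer_velocity(targets, sources, forces, length, eps, mu):
    gxx, gxy, gyy = periodic_stokeslet_blocks(targets, sources, length, eps)
    ux = gxx @ forces[:, 0] + gxy @ forces[:, 1]
    uy = gxy @ forces[:, 0] + gyy @ forces[:, 1]
    return np.column_stack([ux, uy]) / (4.0 * np.pi * mu)


def solve_wall_forces(
    mesh: BoundaryMesh,
    mu: float = 1.0,
    membrane_velocity: Optional[np.ndarray] = None,
    membranes: Optional[Sequence] = None,
    flux_constraint: Optional[float] = None,
    flux_station: float = 0.0,
    operator: Optional[np.ndarray] = None,
) -> FlowSolution:
    """Solve for wall point forces enforcing no-slip on the moving walls.

    ``membrane_velocity`` is the velocity the membrane layers induce at the
    wall collocation points (subtracted from the prescribed wall velocity).
    With ``flux_constraint`` set, the mean pressure gradient becomes an
    unknown and the net flux through ``flux_station`` is imposed; otherwise
    the mean pressure gradient is zero and pumping comes from wall motion.

    The wall layers are closed curves in the periodic strip, so densities
    proportional to the normals induce no flow; the minimum-norm least
    squares solution fixes these null components without affecting the
    tangential (shear) traction.
    """
    N = len(mesh.ds)
    b = mesh.velocity.copy()
    if membrane_velocity is not None:
        b = b - membrane_velocity
    rhs = np.concatenate([b[:, 0], b[:, 1]])
    A = assemble_system(mesh, mu) if operator is None else operator

    if flux_constraint is None:
        F, res, rank, sv = scipy.linalg.lstsq(A, rhs, lapack_driver="gelsy")
        g = 0.0
    else:
        row, col_g, _, _ = _flux_row(mesh, flux_station, mu)
        Aa = np.zeros((2 * N + 1, 2 * N + 1))
        Aa[:2 * N, :2 * N] = A
        Aa[2 * N, :2 * N] = row
        Aa[2 * N, 2 * N] = col_g
        # pressure mode contributes u_x = g y^2 / (2 mu) at wall points
        Aa[:N, 2 * N] = mesh.y ** 2 / (2.0 * mu)
        rhs_a = np.concatenate([rhs, [flux_constraint]])
        sol, res, rank, sv = scipy.linalg.lstsq(Aa, rhs_a, lapack_driver="gelsy")
        F, g = sol[:2 * N], float(sol[2 * N])

    forces = np.column_stack([F[:N], F[N:]])
    solution = FlowSolution(mesh=mesh, wall_forces=forces, mu=mu,
                            pressure_gradient=g,
                            membranes=list(membranes) if membranes else [])
    # no-slip residual of the solved linear system
    r = A @ F - rhs
    if flux_constraint is not None:
        r = Aa[:2 * N, :2 * N] @ F + Aa[:2 * N, 2 * N] * g - rhs
    den = max(float(np.linalg.norm(rhs)), 1e-30)
    solution.residual = float(np.linalg.norm(r) / den)
    return solution


def wall_shear_stress(solution: FlowSolution) -> tuple[np.ndarray, np.ndarray]:
    """Tangential (shear) and normal traction exerted by the fluid on the wall.

    The interior-side traction is evaluated from the stress field of all
    layers at the collocation points.  Evaluating the stress kernel on the
    wall's own layer yields the average of the two one-sided limits, so half
    the traction jump (the force density) is subtracted to land on the fluid
    side.  Sign convention: positive shear means the traction on the wall
    points in the +x (atrium -> ventricle) direction.
    """
    mesh = solution.mesh
    t = stress_traction(mesh.points, mesh.normals, mesh.points,
                        solution.wall_forces, mesh.length, mesh.eps)
    t += 0.5 * solution.wall_forces / mesh.ds[:, None]
    for mpts, mfrc, meps in solution.membranes:
        t += stress_traction(mesh.points, mesh.normals, mpts, mfrc,
                             mesh.length, meps)
    g = solution.pressure_gradient
    if g != 0.0:
        # stress of the parabolic pressure mode: sigma = [[-gx, gy], [gy, -gx]]
        sxx = -g * mesh.x
        sxy = g * mesh.y
        t[:, 0] += sxx * mesh.normals[:, 0] + sxy * mesh.normals[:, 1]
        t[:, 1] += sxy * mesh.normals[:, 0] + sxx * mesh.normals[:, 1]
    # Cauchy traction exerted by the fluid on the wall: sigma . n with the
    # normal pointing from the wall into the fluid = -(interior sigma) . n_out
    t = -t
    tau = np.einsum("ij,ij->i", t, mesh.tangents)
    sigma_n = np.einsum("ij,ij->i", t, mesh.normals)
    return tau, sigma_n


def velocity_at(points, solution: FlowSolution) -> np.ndarray:
    """Convenience wrapper around :meth:`FlowSolution.velocity_at`."""
    return solution.velocity_at(points)
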