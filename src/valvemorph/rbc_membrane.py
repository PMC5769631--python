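"""Elastic-shell model of a red blood cell as a closed 2D curve.

Each RBC is a closed, positively oriented polygon of ``n`` nodes carrying a
discrete elastic energy with linear stretching and linearized bending,

    E = ks/2 * sum_i (|e_i|/|e_i^ref| - 1)^2 |e_i^ref|
      + kb/2 * sum_i (kappa_i - kappa_i^ref)^2 * ds_i

where ``e_i`` are the edges, ``kappa_i = theta_i / ds_i`` is the discrete
(turning-angle) curvature at node i and ``ds_i`` the dual edge length.
Nodal forces are the exact negative gradient of E, so the force set carries
zero net force and zero net torque to round-off.  There is no viscosity
contrast between the cytosol and the plasma (lambda = 1), which keeps the
boundary-integral coupling to a single layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString

__all__ = [
    "MembraneParams",
    "MembraneState",
    "make_ellipse",
    "elastic_energy",
    "elastic_forces",
    "repulsion_forces",
    "reparameterize",
    "enclosed_area",
]


@dataclass(frozen=True)
class MembraneParams:
    """Material and numerical parameters shared by all cells."""

    k_stretch: float = 4.0          # stretching stiffness (force/length)
    k_bend: float = 0.005           # bending stiffness (force*length)
    semi_axes: tuple = (0.2, 0.1)   # rest ellipse; aspect 2, equivalent
                                    # radius ~ 0.4 x the AVC half-width
    n_nodes: int = 32
    repulsion_strength: float = 0.5
    repulsion_cutoff: float = 0.05

    def __post_init__(self):
        if self.k_stretch < 0 or self.k_bend < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.n_nodes < 16:
            raise ValueError("need at least 16 nodes per membrane")
        if self.repulsion_cutoff < 0:
            raise ValueError("repulsion cutoff must be non-negative")


@dataclass
class MembraneState:
    """Discretized membrane: node positions plus reference metrics."""

    positions: np.ndarray            # (n, 2)
    ref_lengths: np.ndarray          # (n,) reference edge lengths
    ref_curvature: np.ndarray        # (n,) spontaneous curvature (default 0)

    def __post_init__(self):
        n = len(self.positions)
        if len(self.ref_lengths) != n or len(self.ref_curvature) != n:
            raise ValueError("reference arrays must match node count")
        if enclosed_area(self.positions) <= 0:
            raise ValueError("membrane curve must be positively oriented")

    def copy(self) -> "MembraneState":
        return MembraneState(self.positions.copy(), self.ref_lengths.copy(),
                             self.ref_curvature.copy())

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def is_simple(self) -> bool:
        ring = np.vstack([self.positions, self.positions[:1]])
        return LineString(ring).is_simple


def enclosed_area(positions: np.ndarray) -> float:
    """Shoelace area of the closed polygon (positive if counterclockwise)."""
    x, y = positions[:, 0], positions[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def make_ellipse(center, params: MembraneParams, angle: float = 0.0,
                 spontaneous_curvature: bool = False) -> MembraneState:
    """Ellipse at rest: reference lengths taken from the constructed shape."""
    a, b = params.semi_axes
    t = np.linspace(0.0, 2.0 * np.pi, params.n_nodes, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    c, s = np.cos(angle), np.sin(angle)
    pts = pts @ np.array([[c, s], [-s, c]])
    pts += np.asarray(center, dtype=float)
    edges = np.roll(pts, -1, axis=0) - pts
    ref_len = np.linalg.norm(edges, axis=1)
    if spontaneous_curvature:
        kappa = _turning_angles(pts) / _dual_lengths(pts)
    else:
        kappa = np.zeros(params.n_nodes)
    return MembraneState(pts, ref_len, kappa)


def _edges(pts):
    return np.roll(pts, -1, axis=0) - pts


def _perp(v):
    return np.column_stack([-v[:, 1], v[:, 0]])


def _turning_angles(pts):
    """Exterior angle at each node (angle from incoming to outgoing edge)."""
    e = _edges(pts)
    e_prev = np.roll(e, 1, axis=0)
    cross = e_prev[:, 0] * e[:, 1] - e_prev[:, 1] * e[:, 0]
    dot = np.einsum("ij,ij->i", e_prev, e)
    return np.arctan2(cross, dot)


def _dual_lengths(pts):
    e = _edges(pts)
    ln = np.linalg.norm(e, axis=1)
    return 0.5 * (np.roll(ln, 1) + ln)


def elastic_energy(state: MembraneState, params: MembraneParams) -> float:
    pts = state.positions
    e = _edges(pts)
    ln = np.linalg.norm(e, axis=1)
    if np.any(ln == 0):
        raise ValueError("degenerate membrane segment of zero length")
    strain = ln / state.ref_lengths - 1.0
    E = 0.5 * params.k_stretch * np.sum(strain ** 2 * state.ref_lengths)
    if params.k_bend > 0:
        ds = _dual_lengths(pts)
        kappa = _turning_angles(pts) / ds
        E += 0.5 * params.k_bend * np.sum((kappa - state.ref_curvature) ** 2 * ds)
    return float(E)


def elastic_forces(state: MembraneState, params: MembraneParams) -> np.ndarray:
    """Per-node forces: exact negative gradient of the discrete energy."""
    pts = state.positions
    n = len(pts)
    e = _edges(pts)                        # e_i = x_{i+1} - x_i
    ln = np.linalg.norm(e, axis=1)
    if np.any(ln == 0):
        raise ValueError("degenerate membrane segment of zero length")
    ehat = e / ln[:, None]

    # stretching: dE/d|e_i| = ks * strain_i, applied along the edge
    tension = params.k_stretch * (ln / state.ref_lengths - 1.0)
    F = np.zeros_like(pts)
    F += tension[:, None] * ehat           # node i pulled toward i+1
    F -= np.roll(tension[:, None] * ehat, 1, axis=0)  # node i pulled toward i-1

    if params.k_bend > 0:
        e_prev = np.roll(e, 1, axis=0)
        ln_prev = np.roll(ln, 1)
        theta = _turning_angles(pts)
        ds = 0.5 * (ln_prev + ln)
        kappa = theta / ds
        dkap = kappa - state.ref_curvature
        # E_i = kb/2 * (theta_i/ds_i - kref_i)^2 * ds_i
        # dE/dtheta = kb * (kappa - kref); chain rule through kappa = theta/ds
        # dE/dds   = kb/2 * [(kappa - kref)^2 - 2 (kappa - kref) kappa]
        dE_dtheta = params.k_bend * dkap
        dE_dds = 0.5 * params.k_bend * (dkap ** 2 - 2.0 * dkap * kappa)

        perp_prev = _perp(e_prev) / (ln_prev ** 2)[:, None]
        perp_next = _perp(e) / (ln ** 2)[:, None]
        # gradient of theta_i lives on nodes i-1, i, i+1
        gtheta = np.zeros((n, 2))
        w = dE_dtheta[:, None]
        gtheta += np.roll(w * perp_prev, -1, axis=0)          # at x_{i-1}
        gtheta += w * (-perp_prev - perp_next)                # at x_i
        gtheta += np.roll(w * perp_next, 1, axis=0)           # at x_{i+1}
        # gradient of ds_i = (|e_{i-1}| + |e_i|)/2
        gds = np.zeros((n, 2))
        ehat_prev = np.roll(ehat, 1, axis=0)
        v = dE_dds[:, None]
        gds += np.roll(-0.5 * v * ehat_prev, -1, axis=0)      # at x_{i-1}
        gds += 0.5 * v * (ehat_prev - ehat)                   # at x_i
        gds += np.roll(0.5 * v * ehat, 1, axis=0)             # at x_{i+1}
        F -= gtheta + gds

    return F


def repulsion_forces(states: Sequence[MembraneState], params: MembraneParams,
                     wall_gap=None) -> list[np.ndarray]:
    """Short-range repulsion between distinct membranes and against the walls.

    ``wall_gap`` is an optional callable mapping node positions (m, 2) to the
    signed gaps (m, 2) = (distance below upper wall, distance above lower
    wall).  Cell-cell terms are equal and opposite (no net momentum).
    """
    n_mem = len(states)
    forces = [np.zeros_like(s.positions) for s in states]
    cutoff = params.repulsion_cutoff
    if cutoff <= 0:
        return forces
    k = params.repulsion_strength
    for i in range(n_mem):
        for j in range(i + 1, n_mem):
            pi, pj = states[i].positions, states[j].positions
            d = pi[:, None, :] - pj[None, :, :]
            dist = np.linalg.norm(d, axis=2)
            mask = dist < cutoff
            if not mask.any():
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                mag = np.where(mask, 2.0 * k / cutoff * (1.0 - dist / cutoff), 0.0)
                dirn = d / np.where(dist > 0, dist, 1.0)[:, :, None]
            fij = mag[:, :, None] * dirn
            forces[i] += fij.sum(axis=1)
            forces[j] -= fij.sum(axis=0)
    if wall_gap is not None:
        for i, s in enumerate(states):
            gap_up, gap_lo = wall_gap(s.positions)
            for gap, sign in ((gap_up, -1.0), (gap_lo, 1.0)):
                mask = gap < cutoff
                mag = np.where(mask, 2.0 * k / cutoff * (1.0 - gap / cutoff), 0.0)
                forces[i][:, 1] += sign * mag
    return forces


def reparameterize(state: MembraneState, n_iter: int = 2) -> MembraneState:
    """Redistribute nodes at equal arc length, preserving the enclosed area.

    Periodic cubic resampling followed by an exact area restoration (uniform
    scaling about the centroid), so the area is conserved to round-off and
    the node spacing is uniform to within the spline interpolation error.
    """
    if not state.is_simple():
        raise ValueError("cannot reparameterize a self-intersecting membrane")
    pts = state.positions
    area0 = enclosed_area(pts)
    n = len(pts)
    for _ in range(n_iter):
        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        spl = CubicSpline(s, closed, bc_type="periodic")
        s_new = np.linspace(0.0, s[-1], n, endpoint=False)
        pts = spl(s_new)
    c = pts.mean(axis=0)
    area1 = enclosed_area(pts)
    if area1 <= 0:
        raise ValueError("reparameterization inverted the curve")
    pts = c + (pts - c) * np.sqrt(area0 / area1)
    new = state.copy()
    new.positions = pts
    return new
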