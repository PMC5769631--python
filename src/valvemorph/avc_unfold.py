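"""Tube unfolding and tissue-convergence quantification from 3D stacks.

The atrioventricular canal (AVC) region of a two-channel 3D stack is
parameterized by a centerline: every point is described by its arc-length
position ``s`` along the fitted axis and its azimuth ``theta`` around it.
The shell intensity is projected onto this parametric surface, yielding a
2D "unfolded" image whose rows are arc-length samples and whose columns are
azimuth samples.  The length ``L`` of the nonphotoconverted gap between the
two photoconverted (red) bands is measured per azimuth, and the shortening
factor ``(L2 - L1) / L1`` between two timepoints quantifies tissue
convergence (negative = the labeled regions moved closer).

Conventions: arrays are (z, y, x); physical positions are index * spacing
(0-based, no half-voxel offset); intervals are half-open.  Azimuth frames
are rotation-minimizing along the centerline with ``theta = 0`` anchored to
a configurable reference direction, so the anatomical quadrant labels
(superior / exterior / inferior / interior) can be mapped by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import make_interp_spline, make_smoothing_spline
from scipy.ndimage import map_coordinates, gaussian_filter1d
import tifffile

from .synthetic_data import rmf_frames

__all__ = [
    "CenterlineParam",
    "UnfoldedImage",
    "ShorteningResult",
    "fit_centerline",
    "unfold",
    "measure_L",
    "shortening",
    "read_stack",
]

log = logging.getLogger(__name__)

QUADRANT_NAMES = ("superior", "exterior", "inferior", "interior")


@dataclass
class CenterlineParam:
    """Smooth arc-length-parameterized centerline with transported frames."""

    samples: np.ndarray         # (n, 3) physical (z, y, x) points
    s: np.ndarray               # (n,) arc length, strictly increasing
    tangents: np.ndarray        # (n, 3)
    normal1: np.ndarray         # (n, 3) theta = 0 direction
    normal2: np.ndarray         # (n, 3) theta = 90deg direction

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def at(self, s_query):
        """Interpolate point and frame at arc positions s_query."""
        s_query = np.atleast_1d(np.asarray(s_query, dtype=float))
        out = []
        for arr in (self.samples, self.tangents, self.normal1, self.normal2):
            interp = make_interp_spline(self.s, arr, k=3)
            out.append(interp(s_query))
        pts, t, n1, n2 = out
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        n1 -= np.einsum("ij,ij->i", n1, t)[:, None] * t
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = np.cross(t, n1)
        return pts, t, n1, n2


@dataclass
class UnfoldedImage:
    """2D (arc length x azimuth) projection of the tube surface."""

    green: np.ndarray           # (n_s, n_theta)
    red: np.ndarray             # (n_s, n_theta)
    radius: np.ndarray          # (n_s, n_theta) fitted shell radius
    missing: np.ndarray         # (n_s, n_theta) bool: ray left the stack
    s: np.ndarray               # (n_s,) arc-length of each row
    theta: np.ndarray           # (n_theta,) azimuth of each column (radians)

    @property
    def row_spacing(self) -> float:
        return float(self.s[1] - self.s[0])

    @property
    def column_spacing_deg(self) -> float:
        return float(np.degrees(self.theta[1] - self.theta[0]))


@dataclass
class ShorteningResult:
    """Per-azimuth and per-quadrant shortening between two timepoints."""

    theta: np.ndarray
    L1: np.ndarray
    L2: np.ndarray
    shortening: np.ndarray            # (L2 - L1) / L1; NaN where missing
    quadrant_offset: float            # radians; center of the superior sector
    quadrant_means: dict = field(default_factory=dict)
    quadrant_stds: dict = field(default_factory=dict)
    quadrant_counts: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"theta_deg": np.degrees(self.theta),
                             "L1": self.L1, "L2": self.L2,
                             "shortening": self.shortening})


def read_stack(path, channel_axis=0):
    """Read a single- or two-channel TIFF/OME-TIFF as (channels, z, y, x)."""
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    elif arr.ndim != 4:
        raise ValueError(f"expected 3D or 4D stack, got shape {arr.shape}")
    if channel_axis != 0:
        arr = np.moveaxis(arr, channel_axis, 0)
    return arr


def _refine_point(volume, spacing, point, radius):
    """Intensity-weighted centroid of a ball around a point (physical)."""
    spacing = np.asarray(spacing, dtype=float)
    lo = np.maximum(((point - radius) / spacing).astype(int), 0)
    hi = np.minimum(((point + radius) / spacing).astype(int) + 2,
                    np.array(volume.shape))
    if np.any(lo >= hi):
        raise ValueError("seed point outside the image")
    sub = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    idx = np.indices(sub.shape).reshape(3, -1).T + lo
    pos = idx * spacing
    d = np.linalg.norm(pos - point, axis=1)
    w = np.where(d <= radius, sub.ravel(), 0.0)
    w = np.clip(w - np.percentile(sub, 20), 0.0, None) * (d <= radius)
    if w.sum() <= 0:
        return point
    return (w[:, None] * pos).sum(axis=0) / w.sum()


def fit_centerline(stack, seeds, spacing, refine_radius: float = 15.0,
                   n_refine: int = 2, n_samples: int = 200,
                   smoothing: Optional[float] = None,
                   reference_direction=(1.0, 0.0, 0.0)) -> CenterlineParam:
    """Fit a smooth centerline through user seed points.

    ``seeds`` are >= 3 ordered physical (z, y, x) points inside the lumen,
    atrium first.  Each is refined toward the local intensity centroid of
    the structural channel (a ball wide enough to cover the full shell ring
    averages to the axis), then a smoothing spline is fitted and
    reparameterized by arc length.  ``reference_direction`` anchors
    ``theta = 0`` of the transported frames (anatomical "superior").
    """
    volume = stack[0] if stack.ndim == 4 else stack
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if len(seeds) < 3:
        raise ValueError("need at least 3 seed points ordered along the tube")
    spacing = np.asarray(spacing, dtype=float)
    extent = np.array(volume.shape) * spacing
    if np.any(seeds < 0) or np.any(seeds >= extent):
        raise ValueError("seed points outside the image")

    pts = seeds.copy()
    for _ in range(n_refine):
        pts = np.array([_refine_point(volume, spacing, p, refine_radius)
                        for p in pts])

    # chord-length parameterization + smoothing spline per coordinate
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    u = chord / chord[-1]
    if smoothing is None:
        smoothing = 1e-3
    coords = []
    for dim in range(3):
        if len(pts) >= 5:
            spl = make_smoothing_spline(u, pts[:, dim], lam=smoothing)
        else:
            spl = make_interp_spline(u, pts[:, dim], k=min(3, len(pts) - 1))
        coords.append(spl)

    uu = np.linspace(0.0, 1.0, 4 * n_samples)
    dense = np.column_stack([c(uu) for c in coords])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])

    # adaptive quadrature of |dC/du| as an arc-length cross-check
    def speed(ui):
        return np.sqrt(sum(float(c.derivative()(ui)) ** 2 for c in coords))
    arc_quad, _ = quad(speed, 0.0, 1.0, limit=200)
    if abs(arc_quad - s_dense[-1]) > 1e-3 * max(arc_quad, 1e-9):
        log.warning("arc-length quadrature and polyline disagree by %.2g%%",
                    100 * abs(arc_quad - s_dense[-1]) / arc_quad)

    s_targets = np.linspace(0.0, s_dense[-1], n_samples)
    u_of_s = np.interp(s_targets, s_dense, uu)
    samples = np.column_stack([c(u_of_s) for c in coords])
    t, n1, n2 = rmf_frames(samples)

    # rotate frames so theta=0 aligns with the reference direction at mid-tube
    ref = np.asarray(reference_direction, dtype=float)
    mid = len(samples) // 2
    proj = ref - np.dot(ref, t[mid]) * t[mid]
    if np.linalg.norm(proj) > 1e-9:
        ang = np.arctan2(np.dot(proj, n2[mid]), np.dot(proj, n1[mid]))
        c_, s_ = np.cos(ang), np.sin(ang)
        n1, n2 = c_ * n1 + s_ * n2, -s_ * n1 + c_ * n2

    return CenterlineParam(samples=samples, s=s_targets, tangents=t,
                           normal1=n1, normal2=n2)


def unfold(stack, centerline: CenterlineParam, spacing, n_s: int = 120,
           n_theta: int = 36, r_max: Optional[float] = None,
           band_halfwidth: float = 3.0, n_r: int = 80) -> UnfoldedImage:
    """Project both channels onto the fitted tube surface.

    For each (s, theta) a ray is cast from the centerline along the frame
    direction; the shell radius is the structural-channel intensity peak
    along the ray (sub-sample parabolic refinement) and each channel's
    projected value is its maximum within ``band_halfwidth`` of that
    radius.  Rays that leave the stack before meeting the shell are flagged
    missing rather than zeroed.
    """
    if n_theta < 8:
        raise ValueError("need at least 8 azimuth samples")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 3:
        stack = stack[None]
    green = stack[0]
    red = stack[1] if stack.shape[0] > 1 else stack[0]
    spacing = np.asarray(spacing, dtype=float)
    extent = np.array(green.shape) * spacing

    if r_max is None:
        r_max = 0.45 * float(np.min(extent))
    s_rows = np.linspace(0.0, centerline.length, n_s)
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    pts, t, n1, n2 = centerline.at(s_rows)

    radii = np.linspace(0.0, r_max, n_r)
    dirs = (np.cos(theta)[None, :, None] * n1[:, None, :]
            + np.sin(theta)[None, :, None] * n2[:, None, :])   # (n_s, n_th, 3)
    coords = (pts[:, None, None, :] + radii[None, None, :, None]
              * dirs[:, :, None, :])                            # (n_s, n_th, n_r, 3)
    inside = np.all((coords >= 0) & (coords < extent - spacing), axis=-1)
    vox = (coords / spacing).reshape(-1, 3).T

    g_prof = map_coordinates(green, vox, order=1, mode="constant",
                             cval=0.0).reshape(n_s, n_theta, n_r)
    r_prof = map_coordinates(red, vox, order=1, mode="constant",
                             cval=0.0).reshape(n_s, n_theta, n_r)

    g_masked = np.where(inside, g_prof, -np.inf)
    ipk = np.argmax(g_masked, axis=-1)
    missing = (~np.take_along_axis(inside, ipk[..., None], axis=-1)[..., 0]) \
        | (ipk == 0) | (ipk == n_r - 1)

    # parabolic sub-sample peak refinement
    dr = radii[1] - radii[0]
    i0 = np.clip(ipk, 1, n_r - 2)
    ym = np.take_along_axis(g_prof, (i0 - 1)[..., None], -1)[..., 0]
    y0 = np.take_along_axis(g_prof, i0[..., None], -1)[..., 0]
    yp = np.take_along_axis(g_prof, (i0 + 1)[..., None], -1)[..., 0]
    denom = ym - 2 * y0 + yp
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (ym - yp) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    r_peak = radii[i0] + shift * dr

    band = np.abs(radii[None, None, :] - r_peak[..., None]) <= band_halfwidth
    band &= inside
    g_out = np.where(band, g_prof, -np.inf).max(axis=-1)
    r_out = np.where(band, r_prof, -np.inf).max(axis=-1)
    g_out[missing] = np.nan
    r_out[missing] = np.nan

    return UnfoldedImage(green=g_out, red=r_out, radius=r_peak,
                         missing=missing, s=s_rows, theta=theta)


def measure_L(unfolded: UnfoldedImage, smooth_sigma: float = 1.0,
              threshold_frac: float = 0.5) -> np.ndarray:
    """Arc length of the nonphotoconverted gap, per azimuth column.

    Each column's red profile is smoothed along s, binarized at
    ``threshold_frac`` of its band plateau, and the distance between the
    first band's far edge and the second band's near edge is returned with
    sub-sample (linear) edge interpolation.  Columns where two bands cannot
    be found yield NaN.  Full photoconversion (no gap) yields 0.

    The gap signal can alternatively be measured on the photoconverted
    label itself by inverting upstream; this function measures the
    unlabeled span, the definition used for the shortening factor.
    """
    n_s, n_theta = unfolded.red.shape
    L = np.full(n_theta, np.nan)
    ds = unfolded.row_spacing
    n_missing = 0
    for j in range(n_theta):
        prof = unfolded.red[:, j].astype(float)
        valid = ~np.isnan(prof)
        if valid.sum() < 5:
            n_missing += 1
            continue
        prof = np.where(valid, prof, np.nanmin(prof))
        prof = gaussian_filter1d(prof, smooth_sigma)
        lo, hi = np.nanmin(prof), np.nanmax(prof)
        if hi - lo <= 1e-12:
            n_missing += 1
            continue
        thr = lo + threshold_frac * (hi - lo)
        above = prof > thr
        # connected runs of "photoconverted"
        edges = np.flatnonzero(np.diff(above.astype(int)))
        runs = []
        start = 0 if above[0] else None
        for e in edges:
            if above[e]:        # falling edge after a run
                runs.append((start, e))
                start = None
            else:               # rising edge
                start = e + 1
        if start is not None and above[-1]:
            runs.append((start, n_s - 1))
        runs = [r for r in runs if r[1] > r[0]]
        if len(runs) < 2:
            if len(runs) == 1 and not (runs[0][0] == 0 or runs[0][1] == n_s - 1):
                # a single interior band: the photoconverted regions merged
                L[j] = 0.0
            elif len(runs) == 1 and runs[0][0] == 0 and runs[0][1] == n_s - 1:
                L[j] = 0.0      # column photoconverted end to end
            else:
                n_missing += 1  # a band is cut off at the field edge
            continue
        first, last = runs[0], runs[-1]
        # sub-sample threshold crossings: descending edge of the first band,
        # ascending edge of the last band
        i1 = first[1]
        if i1 < n_s - 1 and prof[i1 + 1] != prof[i1]:
            e1 = i1 + (thr - prof[i1]) / (prof[i1 + 1] - prof[i1])
        else:
            e1 = float(i1)
        i2 = last[0]
        if i2 > 0 and prof[i2] != prof[i2 - 1]:
            e2 = i2 - 1 + (thr - prof[i2 - 1]) / (prof[i2] - prof[i2 - 1])
        else:
            e2 = float(i2)
        L[j] = max((e2 - e1) * ds, 0.0)
    if n_missing:
        log.info("measure_L: %d of %d azimuth columns missing", n_missing, n_theta)
    return L


def shortening(L1: np.ndarray, L2: np.ndarray,
               quadrant_offset: float = 0.0,
               theta: Optional[np.ndarray] = None) -> ShorteningResult:
    """Per-azimuth shortening (L2 - L1)/L1 plus quadrant statistics.

    Quadrants are four contiguous 90-degree sectors centered at
    ``quadrant_offset + {0, 90, 180, 270} deg``, labelled superior (a),
    exterior (b), inferior (c), interior (d).  Missing azimuths are
    excluded from the means; a quadrant with no valid azimuths is flagged
    with NaN and count 0, never fabricated.
    """
    L1 = np.asarray(L1, dtype=float)
    L2 = np.asarray(L2, dtype=float)
    if L1.shape != L2.shape:
        raise ValueError("the two timepoints must share the azimuth grid")
    n = len(L1)
    if theta is None:
        theta = np.arange(n) * (2.0 * np.pi / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        sh = np.where(L1 > 0, (L2 - L1) / L1, np.nan)

    means, stds, counts = {}, {}, {}
    for qi, name in enumerate(QUADRANT_NAMES):
        center = quadrant_offset + qi * np.pi / 2.0
        d = np.angle(np.exp(1j * (theta - center)))
        # half-open sectors so each azimuth belongs to exactly one quadrant
        mask = (d >= -np.pi / 4.0 - 1e-12) & (d < np.pi / 4.0 - 1e-12) \
            & ~np.isnan(sh)
        counts[name] = int(mask.sum())
        if counts[name]:
            means[name] = float(np.mean(sh[mask]))
            stds[name] = float(np.std(sh[mask], ddof=1)) if counts[name] > 1 else 0.0
        else:
            means[name] = float("nan")
            stds[name] = float("nan")
    return ShorteningResult(theta=theta, L1=L1, L2=L2, shortening=sh,
                            quadrant_offset=quadrant_offset,
                            quadrant_means=means, quadrant_stds=stds,
                            quadrant_counts=counts)
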