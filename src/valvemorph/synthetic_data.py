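"""Synthetic inputs for every pipeline stage.

Two generators:

* a 3D two-channel image phantom of a curved tubular tissue ("green"
  structural shell everywhere, "red" photoconverted label in two rings
  flanking an unlabeled gap), with exact ground truth for the gap length at
  two timepoints -- emulating two-channel confocal stacks of a
  photoconverted embryonic heart tube;
* a wall-shear-stress-like time series with prescribed constant, harmonic
  and noise content for validating the spectral decomposition.

All randomness flows through explicit seeds; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
import tifffile

__all__ = [
    "PhantomSpec",
    "SignalSpec",
    "GroundTruth",
    "make_phantom",
    "make_signal",
    "write_phantom",
    "write_signal",
    "rmf_frames",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Curved-tube phantom with two photoconverted rings.

    All physical quantities in micrometres; arrays are indexed (z, y, x)
    and physical positions are index * spacing (0-based, no half-voxel
    offset).  The two red bands flank an unlabeled gap centered at
    ``gap_center`` (arc length from the start of the centerline); the gap
    length differs between timepoints 1 and 2.
    """

    control_points: tuple = (
        (16.0, 28.0, 14.0), (18.0, 30.0, 36.0), (20.0, 36.0, 58.0),
        (22.0, 46.0, 80.0),
    )
    semi_axes: tuple = (11.0, 8.0)         # cross-section (in-plane a, b)
    shell_thickness: float = 3.0
    voxel_spacing: tuple = (2.0, 1.0, 1.0)  # (z, y, x) um per voxel
    shape: tuple = (22, 64, 96)             # (z, y, x) voxels
    gap_center: float = 36.0                # arc length position
    band_length: float = 12.0
    gap_length_t1: float = 40.0
    gap_length_t2: float = 28.0
    foreground: float = 200.0
    background: float = 10.0
    noise_sigma: float = 0.0
    edge_offset_amplitude: float = 0.0      # per-azimuth sinusoidal band-edge offset
    edge_offset_phase: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.voxel_spacing) <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.shell_thickness >= min(self.semi_axes):
            raise ValueError("shell thickness must be below the smallest semi-axis")
        for gap in (self.gap_length_t1, self.gap_length_t2):
            if gap < 0:
                raise ValueError("gap lengths must be non-negative")

    def gap_length(self, timepoint: int) -> float:
        if timepoint == 1:
            return self.gap_length_t1
        if timepoint == 2:
            return self.gap_length_t2
        raise ValueError("timepoint must be 1 or 2")

    @property
    def true_shortening(self) -> float:
        return (self.gap_length_t2 - self.gap_length_t1) / self.gap_length_t1


@dataclass(frozen=True)
class GroundTruth:
    timepoint: int
    gap_length: float
    band1: tuple          # (s_start, s_end) of the atrial-side band
    band2: tuple          # (s_start, s_end) of the ventricular-side band
    arc_length_total: float


@dataclass(frozen=True)
class SignalSpec:
    """Constant + harmonics + noise time series."""

    constant: float = 0.0
    harmonics: tuple = ()        # (k, amplitude, phase) triplets
    f1: float = 1.0
    n_beats: int = 8
    samples_per_beat: int = 64
    noise_sigma: float = 0.0
    amplitude_jitter: float = 0.0   # per-beat fractional jitter of harmonics
    seed: int = 0

    def __post_init__(self):
        for k, amp, phase in self.harmonics:
            if int(k) != k or k <= 0:
                raise ValueError("harmonic indices must be positive integers")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")
        kmax = max((int(k) for k, _, _ in self.harmonics), default=1)
        if self.samples_per_beat < 4 * kmax:
            raise ValueError("samples per beat below 4x the highest harmonic "
                             "(Nyquist margin)")


def rmf_frames(points: np.ndarray):
    """Rotation-minimizing frames along a polyline (double-reflection).

    Returns (tangents, normal1, normal2), each (n, 3); the frame is
    continuous (no flips) and the normals stay orthonormal to the tangent.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    t = np.gradient(pts, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n1 = np.zeros_like(pts)
    # initial normal: least-aligned coordinate axis
    ref = np.eye(3)[np.argmin(np.abs(t[0]))]
    v = ref - np.dot(ref, t[0]) * t[0]
    n1[0] = v / np.linalg.norm(v)
    for i in range(n - 1):
        # double reflection (Wang et al.): reflect across chord, then tangent
        v1 = pts[i + 1] - pts[i]
        c1 = v1 @ v1
        if c1 == 0:
            n1[i + 1] = n1[i]
            continue
        rL = n1[i] - (2.0 / c1) * (v1 @ n1[i]) * v1
        tL = t[i] - (2.0 / c1) * (v1 @ t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = v2 @ v2
        n1[i + 1] = rL if c2 == 0 else rL - (2.0 / c2) * (v2 @ rL) * v2
        n1[i + 1] -= np.dot(n1[i + 1], t[i + 1]) * t[i + 1]
        n1[i + 1] /= np.linalg.norm(n1[i + 1])
    n2 = np.cross(t, n1)
    return t, n1, n2


def _dense_centerline(spec: PhantomSpec, n_dense: int = 1500):
    cp = np.asarray(spec.control_points, dtype=float)
    u = np.linspace(0.0, 1.0, len(cp))
    spl = make_interp_spline(u, cp, k=min(3, len(cp) - 1))
    uu = np.linspace(0.0, 1.0, n_dense)
    pts = spl(uu)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def make_phantom(spec: PhantomSpec, timepoint: int):
    """Voxelize the phantom at one timepoint.

    Returns ``(image, truth)`` where image has shape (2, nz, ny, nx)
    (channel 0 = green shell, channel 1 = red bands) and truth records the
    exact band edges and gap arc length.
    """
    gap = spec.gap_length(timepoint)
    pts, s = _dense_centerline(spec)
    total = s[-1]
    g0, g1 = spec.gap_center - gap / 2.0, spec.gap_center + gap / 2.0
    band1 = (g0 - spec.band_length, g0)
    band2 = (g1, g1 + spec.band_length)
    if band1[0] < 0 or band2[1] > total:
        raise ValueError("bands fall outside the centerline arc range")
    if band1[1] > band2[0]:
        raise ValueError("photoconverted bands overlap")

    t, n1, n2 = rmf_frames(pts)
    tree = cKDTree(pts)

    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_spacing
    zz, yy, xx = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                             np.arange(nx) * dx, indexing="ij")
    vox = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    dist, idx = tree.query(vox, workers=-1)

    a, b = spec.semi_axes
    # per-point axis-aligned extent of the shell cross-section (frame-aware,
    # so a tube running along an axis is not rejected at its open ends)
    reach = (np.abs(n1) * a + np.abs(n2) * b) + spec.shell_thickness / 2.0
    extent = np.array([nz * dz, ny * dy, nx * dx])
    if np.any(pts - reach < 0) or np.any(pts + reach > extent):
        raise ValueError("tube exits the voxel grid; enlarge shape or shrink tube")

    off = vox - pts[idx]
    p = np.einsum("ij,ij->i", off, n1[idx])
    q = np.einsum("ij,ij->i", off, n2[idx])
    theta = np.arctan2(q, p)
    rho = np.sqrt((p / a) ** 2 + (q / b) ** 2)
    # local ellipse radius along this direction; signed distance to the shell
    r_dir = 1.0 / np.sqrt((np.cos(theta) / a) ** 2 + (np.sin(theta) / b) ** 2)
    d_shell = (rho - 1.0) * r_dir
    in_shell = np.abs(d_shell) <= spec.shell_thickness / 2.0

    s_vox = s[idx]
    if spec.edge_offset_amplitude:
        wobble = spec.edge_offset_amplitude * np.sin(theta - spec.edge_offset_phase)
    else:
        wobble = 0.0
    in_b1 = (s_vox >= band1[0] + wobble) & (s_vox <= band1[1] + wobble)
    in_b2 = (s_vox >= band2[0] + wobble) & (s_vox <= band2[1] + wobble)

    green = np.where(in_shell, spec.foreground, 0.0).reshape(spec.shape)
    red = np.where(in_shell & (in_b1 | in_b2), spec.foreground, 0.0).reshape(spec.shape)

    sig_vox = 1.0  # hard-edged annulus smoothed by a 1-voxel Gaussian
    green = gaussian_filter(green, sig_vox) + spec.background
    red = gaussian_filter(red, sig_vox) + spec.background

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, timepoint]))
    if spec.noise_sigma > 0:
        green = green + rng.normal(0.0, spec.noise_sigma, green.shape)
        red = red + rng.normal(0.0, spec.noise_sigma, red.shape)
    image = np.stack([green, red]).astype(np.float32)
    image = np.clip(image, 0.0, None)

    truth = GroundTruth(timepoint=timepoint, gap_length=gap, band1=band1,
                        band2=band2, arc_length_total=total)
    return image, truth


def write_phantom(directory, spec: PhantomSpec, timepoints=(1, 2)) -> dict:
    """Write OME-TIFFs (two channels) plus a sidecar ground-truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {"tiffs": [], "truth_csv": str(directory / "ground_truth.csv")}
    rows = []
    for tp in timepoints:
        image, truth = make_phantom(spec, tp)
        path = directory / f"phantom_t{tp}.tif"
        dz, dy, dx = spec.voxel_spacing
        # plain (non-OME) TIFF: byte-identical across runs, which the run
        # manifest's checksum reproducibility relies on
        tifffile.imwrite(
            path, image, photometric="minisblack", ome=False,
            metadata={"axes": "CZYX", "spacing_zyx": [dz, dy, dx]},
        )
        out["tiffs"].append(str(path))
        rows.append({"timepoint": tp, "gap_length_um": truth.gap_length,
                     "band1_start": truth.band1[0], "band1_end": truth.band1[1],
                     "band2_start": truth.band2[0], "band2_end": truth.band2[1]})
    with open(out["truth_csv"], "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out


def make_signal(spec: SignalSpec):
    """Sampled series: constant + harmonic sines + jitter + noise.

    Returns (times, values); exactly ``n_beats * samples_per_beat`` samples,
    uniformly spaced with spacing ``1 / (f1 * samples_per_beat)``.
    """
    n = spec.n_beats * spec.samples_per_beat
    t = np.arange(n) / (spec.f1 * spec.samples_per_beat)
    rng = np.random.default_rng(spec.seed)
    v = np.full(n, float(spec.constant))
    beat_of = (np.arange(n) // spec.samples_per_beat)
    for k, amp, phase in spec.harmonics:
        if spec.amplitude_jitter > 0:
            jit = 1.0 + spec.amplitude_jitter * rng.standard_normal(spec.n_beats)
            amp_t = amp * jit[beat_of]
        else:
            amp_t = amp
        v = v + amp_t * np.sin(2.0 * np.pi * k * spec.f1 * t + phase)
    if spec.noise_sigma > 0:
        v = v + rng.normal(0.0, spec.noise_sigma, n)
    return t, v


def write_signal(path, spec: SignalSpec) -> None:
    t, v = make_signal(spec)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "station_id", "tau"])
        for ti, vi in zip(t, v):
            writer.writerow([f"{ti:.10g}", 0, f"{vi:.10g}"])
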