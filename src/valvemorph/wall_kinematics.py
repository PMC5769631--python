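"""Moving geometry of the valveless heart tube.

The embryonic heart at the onset of valve formation is idealized as a 2D
channel, periodic in the axial direction ``x``, whose upper and lower walls
oscillate harmonically about a rest profile.  The rest half-width ``h0(x)``
carries three labelled segments -- atrium, a narrowed atrioventricular canal
(AVC), and ventricle -- and the motion model assigns an amplitude ``a(x)``
and a phase ``phi(x)`` to every axial station:

    y_upper(x, t) = h0(x) - a(x) * (1 + sin(2 pi f1 t - phi(x))) / 2

so the wall swings between ``h0`` (fully open) and ``h0 - a`` (maximally
contracted).  A phase lag between the atrial and ventricular amplitude bumps
turns the tube into a valveless (impedance) pump.

Everything is nondimensional: lengths in units of the chamber rest
half-width, time in beat periods (``f1 = 1`` by default), viscosity ``mu = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import yaml

__all__ = [
    "TubeGeometry",
    "WallMotionModel",
    "two_chamber_preset",
    "wall_position",
    "wall_velocity",
    "enclosed_area",
    "enclosed_area_rate",
]


def _wrap(x, length):
    return np.mod(x, length)


def _smoothstep(t):
    """C2 quintic smootherstep clamped to [0, 1].

    Continuous curvature matters: wall-curvature jumps excite point-to-point
    oscillations in the boundary-integral traction.
    """
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _window(x, lo, hi, smooth, length):
    """Smooth periodic window: 1 on [lo, hi], 0 beyond a ``smooth`` margin."""
    x = _wrap(np.asarray(x, dtype=float), length)
    # signed distance into the interval, measured periodically
    up = _smoothstep((x - (lo - smooth)) / smooth)
    down = _smoothstep(((hi + smooth) - x) / smooth)
    w = up * down
    # wrap-around copies for intervals near the domain ends
    for shift in (-length, length):
        xs = x + shift
        w = np.maximum(w, _smoothstep((xs - (lo - smooth)) / smooth)
                       * _smoothstep(((hi + smooth) - xs) / smooth))
    return w


@dataclass(frozen=True)
class TubeGeometry:
    """Rest shape of the periodic heart tube.

    Segment extents are intervals on the periodic axis ``[0, length)``.
    ``chamber_half_width`` is the unit of length (default 1), and the AVC
    minimum half-width must be strictly smaller.
    """

    length: float = 10.0
    chamber_half_width: float = 1.0
    avc_half_width: float = 0.35
    atrium: Tuple[float, float] = (0.8, 4.0)
    avc: Tuple[float, float] = (4.6, 5.6)
    ventricle: Tuple[float, float] = (6.2, 9.4)
    smoothing: float = 0.8

    def __post_init__(self):
        if self.length <= 0 or self.chamber_half_width <= 0:
            raise ValueError("tube length and half-width must be positive")
        if not (0 < self.avc_half_width < self.chamber_half_width):
            raise ValueError("AVC half-width must lie in (0, chamber half-width)")
        if self.smoothing <= 0:
            raise ValueError("smoothing length must be positive")

    def rest_half_width(self, x):
        """Rest half-width profile h0(x), smooth and periodic."""
        w = _window(x, self.avc[0], self.avc[1], self.smoothing, self.length)
        return self.chamber_half_width - (self.chamber_half_width - self.avc_half_width) * w

    @property
    def avc_center(self) -> float:
        return 0.5 * (self.avc[0] + self.avc[1])

    def segment_of(self, x) -> str:
        """Label the segment containing station x (by nearest extent)."""
        x = float(_wrap(x, self.length))
        for name, (lo, hi) in (("atrium", self.atrium), ("avc", self.avc),
                               ("ventricle", self.ventricle)):
            if lo <= x <= hi:
                return name
        return "junction"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TubeGeometry":
        d = dict(d)
        for key in ("atrium", "avc", "ventricle"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class WallMotionModel:
    """Harmonic wall motion sampled on a dense periodic grid.

    The profile is stored as the complex field ``m(x) = a(x) exp(-i phi(x))``
    (real and imaginary parts on a uniform grid over ``[0, length)``),
    because amplitude and phase interpolate badly across phase branch cuts
    while the components of ``m`` are smooth and periodic.  The local wall
    displacement of the contraction term is ``(|m| + Im[m e^{i w t}]) / 2``
    with ``w = 2 pi f1``, which equals ``a (1 + sin(w t - phi)) / 2``.
    A serialized model reloads bit-exactly.
    """

    length: float
    x_grid: np.ndarray
    m_re_grid: np.ndarray
    m_im_grid: np.ndarray
    f1: float = 1.0
    symmetric: bool = True
    lower_amplitude_scale: float = 1.0

    @property
    def period(self) -> float:
        return 1.0 / self.f1

    def profile(self, x):
        """Complex motion profile m(x) = a exp(-i phi)."""
        return self._interp(x, self.m_re_grid) + 1j * self._interp(x, self.m_im_grid)

    def amplitude(self, x):
        return np.abs(self.profile(x))

    def phase(self, x):
        return np.mod(-np.angle(self.profile(x)), 2.0 * np.pi)

    def _interp(self, x, values):
        x = _wrap(np.asarray(x, dtype=float), self.length)
        xg = np.concatenate([self.x_grid, [self.length]])
        vg = np.concatenate([values, [values[0]]])
        return np.interp(x, xg, vg)

    def validate_against(self, geometry: TubeGeometry, n_check: int = 2048) -> None:
        """Raise at construction time if walls could cross the centerline."""
        x = np.linspace(0.0, self.length, n_check, endpoint=False)
        a = self.amplitude(x)
        scale = max(1.0, self.lower_amplitude_scale)
        if np.any(a * scale >= geometry.rest_half_width(x)):
            raise ValueError("wall amplitude reaches the rest half-width: "
                             "walls would cross the centerline")
        if abs(self.length - geometry.length) > 1e-12:
            raise ValueError("motion model and geometry disagree on tube length")

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "x_grid": self.x_grid.tolist(),
            "m_re_grid": self.m_re_grid.tolist(),
            "m_im_grid": self.m_im_grid.tolist(),
            "f1": self.f1,
            "symmetric": self.symmetric,
            "lower_amplitude_scale": self.lower_amplitude_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WallMotionModel":
        return cls(
            length=float(d["length"]),
            x_grid=np.asarray(d["x_grid"], dtype=float),
            m_re_grid=np.asarray(d["m_re_grid"], dtype=float),
            m_im_grid=np.asarray(d["m_im_grid"], dtype=float),
            f1=float(d.get("f1", 1.0)),
            symmetric=bool(d.get("symmetric", True)),
            lower_amplitude_scale=float(d.get("lower_amplitude_scale", 1.0)),
        )

    @classmethod
    def from_profile(cls, length, x_grid, m, f1=1.0, symmetric=True,
                     lower_amplitude_scale=1.0) -> "WallMotionModel":
        m = np.asarray(m, dtype=complex)
        return cls(length=length, x_grid=np.asarray(x_grid, dtype=float),
                   m_re_grid=m.real.copy(), m_im_grid=m.imag.copy(), f1=f1,
                   symmetric=symmetric, lower_amplitude_scale=lower_amplitude_scale)

    @classmethod
    def from_tables(cls, length, x, amplitude, phase, f1=1.0, symmetric=True,
                    lower_amplitude_scale=1.0, n_grid=1024) -> "WallMotionModel":
        """Build from tabulated (x, a, phi) triples by periodic interpolation."""
        x = np.asarray(x, dtype=float)
        order = np.argsort(x)
        x = x[order]
        m = np.asarray(amplitude, dtype=float)[order] * np.exp(
            -1j * np.asarray(phase, dtype=float)[order])
        xg = np.linspace(0.0, length, n_grid, endpoint=False)
        xp = np.concatenate([x, [x[0] + length]])
        mg = (np.interp(xg, xp, np.concatenate([m.real, [m.real[0]]]), period=length)
              + 1j * np.interp(xg, xp, np.concatenate([m.imag, [m.imag[0]]]),
                               period=length))
        return cls.from_profile(length, xg, mg, f1=f1, symmetric=symmetric,
                                lower_amplitude_scale=lower_amplitude_scale)


def two_chamber_preset(
    geometry: TubeGeometry | None = None,
    atrial_amplitude: float = 0.3,
    ventricular_amplitude: float = 0.3,
    avc_extra_amplitude: float = 0.2,
    avc_phase_offset: float = 1.4,
    winding: float = 0.8,
    f1: float = 1.0,
    symmetric: bool = True,
    lower_amplitude_scale: float = 1.0,
    volume_correction: bool = True,
    n_grid: int = 1024,
) -> tuple[TubeGeometry, WallMotionModel]:
    """Default two-chamber valveless pump: a peristaltic traveling wave.

    The whole tube between the inflow and outflow junction moves: the
    chambers carry the base amplitude (blending from ``atrial_amplitude``
    to ``ventricular_amplitude`` across the AVC), the AVC constriction adds
    ``avc_extra_amplitude`` so its relative occlusion is strongest, and the
    contraction phase advances linearly along the tube (winding by
    ``2 pi * winding`` across one period), so the contraction wave travels
    atrium -> AVC -> ventricle and the ventricular contraction lags the
    atrial one.  The AVC leads the local traveling phase by
    ``avc_phase_offset``; this relative timing of the constriction and the
    through-flux sets the sign pattern of the time-averaged wall shear
    stress around the AVC (a pure rectification effect: for single-phase
    standing motion the time average vanishes identically).

    In a periodic tube, incompressibility requires the instantaneous total
    enclosed area to be constant, i.e. the complex profile
    ``m(x) = a(x) exp(-i phi(x))`` must integrate to zero.  With
    ``volume_correction`` (default) the residual integral of the preset is
    subtracted, spread proportionally to the local amplitude, which perturbs
    the profiles only slightly but closes the volume budget exactly.
    """
    geometry = geometry or TubeGeometry()
    L = geometry.length
    xg = np.linspace(0.0, L, n_grid, endpoint=False)
    dx = L / n_grid
    sm = geometry.smoothing
    h0 = geometry.rest_half_width(xg)
    # smooth envelope over the moving span; the periodic outflow->inflow
    # junction stays motionless so the phase profile need not unwind there
    env = _window(xg, geometry.atrium[0] + sm, geometry.ventricle[1] - sm, sm, L)
    # chamber base amplitude blends across the AVC
    blend = _smoothstep((xg - geometry.avc[0]) / (geometry.avc[1] - geometry.avc[0]))
    base = atrial_amplitude + (ventricular_amplitude - atrial_amplitude) * blend
    narrowing = ((geometry.chamber_half_width - h0)
                 / (geometry.chamber_half_width - geometry.avc_half_width))
    amp = env * (base + avc_extra_amplitude * narrowing)
    sm_avc = min(sm, 0.25 * (geometry.avc[1] - geometry.avc[0]))
    w_avc = _window(xg, geometry.avc[0] + sm_avc, geometry.avc[1] - sm_avc, sm_avc, L)
    phase = 2.0 * np.pi * winding * xg / L + avc_phase_offset * w_avc

    m = np.minimum(amp, 0.9 * h0) * np.exp(-1j * phase)
    if volume_correction:
        for _ in range(2):      # correct, re-cap, correct the small residue
            a = np.abs(m)
            defect = np.sum(m) * dx
            m = m - defect * a / (np.sum(a) * dx)
            scale = np.minimum(np.abs(m), 0.92 * h0) / np.maximum(np.abs(m), 1e-30)
            m = m * scale

    model = WallMotionModel.from_profile(L, xg, m, f1=f1, symmetric=symmetric,
                                         lower_amplitude_scale=lower_amplitude_scale)
    model.validate_against(geometry)
    return geometry, model


def _lower_scale(model: WallMotionModel) -> float:
    return model.lower_amplitude_scale if not model.symmetric else 1.0


def wall_position(model: WallMotionModel, geometry: TubeGeometry, x, t, side: str):
    """Transverse wall coordinate at axial station(s) x and time t.

    The inward displacement is ``(|m| + Im[m e^{i w t}]) / 2``, i.e.
    ``a (1 + sin(w t - phi)) / 2``: the wall touches h0 when fully open.
    """
    h0 = geometry.rest_half_width(x)
    m = model.profile(x)
    phasor = np.exp(2j * np.pi * model.f1 * np.asarray(t, dtype=float))
    disp = 0.5 * (np.abs(m) + np.imag(m * phasor))
    if side == "upper":
        return h0 - disp
    if side == "lower":
        return -h0 + _lower_scale(model) * disp
    raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


def wall_velocity(model: WallMotionModel, geometry: TubeGeometry, x, t, side: str):
    """Exact time derivative of :func:`wall_position`."""
    omega = 2.0 * np.pi * model.f1
    m = model.profile(x)
    phasor = np.exp(2j * np.pi * model.f1 * np.asarray(t, dtype=float))
    rate = 0.5 * omega * np.real(m * phasor)
    if side == "upper":
        return -rate
    if side == "lower":
        return _lower_scale(model) * rate
    raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


def enclosed_area(model, geometry, t, x_lo=None, x_hi=None, n_quad=2048):
    """Fluid area between the walls over [x_lo, x_hi] (full tube by default)."""
    x_lo = 0.0 if x_lo is None else x_lo
    x_hi = geometry.length if x_hi is None else x_hi
    x = np.linspace(x_lo, x_hi, n_quad)
    gap = (wall_position(model, geometry, x, t, "upper")
           - wall_position(model, geometry, x, t, "lower"))
    return np.trapezoid(gap, x)


def enclosed_area_rate(model, geometry, t, x_lo=None, x_hi=None, n_quad=2048):
    """Exact d/dt of :func:`enclosed_area` via the wall velocities."""
    x_lo = 0.0 if x_lo is None else x_lo
    x_hi = geometry.length if x_hi is None else x_hi
    x = np.linspace(x_lo, x_hi, n_quad)
    rate = (wall_velocity(model, geometry, x, t, "upper")
            - wall_velocity(model, geometry, x, t, "lower"))
    return np.trapezoid(rate, x)


def save_config(path, geometry: TubeGeometry, model: WallMotionModel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"geometry": geometry.to_dict(), "motion": model.to_dict()}, fh)


def load_config(path) -> tuple[TubeGeometry, WallMotionModel]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    geometry = TubeGeometry.from_dict(d["geometry"])
    model = WallMotionModel.from_dict(d["motion"])
    model.validate_against(geometry)
    return geometry, model
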