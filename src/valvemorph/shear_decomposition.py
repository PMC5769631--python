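"""Decomposition of wall shear stress into periodic and nonperiodic parts.

The wall shear stress in a beating heart is modelled as the sum of three
components: a constant part tau_0 (the time average), harmonic oscillations
whose frequencies are integer multiples of the beat frequency f1 (amplitudes
tau_1, tau_2, ... obtained by Fourier analysis of the phase average), and a
nonperiodic residual tau' quantified as the root mean square of the
deviation of the signal from its periodic component.  The periodic part
(tau_0 plus harmonics) is the phase average itself; the residual is driven
by the chaotic dynamics of the red blood cells and vanishes without them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heart_simulator import WSSRecord

__all__ = [
    "DecompositionResult",
    "phase_average",
    "harmonic_amplitudes",
    "nonperiodic_rms",
    "spatial_profiles",
    "gradient_tau1",
    "estimate_period",
]

log = logging.getLogger(__name__)


@dataclass
class DecompositionResult:
    """Per-station decomposition of tau(t) along the wall."""

    station_x: np.ndarray          # (n_stations,)
    station_side: np.ndarray       # 0 = lower, 1 = upper
    tau0: np.ndarray               # (n_stations,)
    amplitudes: np.ndarray         # (n_stations, K) tau_1..tau_K
    phases: np.ndarray             # (n_stations, K)
    tau_prime: np.ndarray          # (n_stations,)
    phase_avg: np.ndarray          # (n_stations, bins) periodic component
    period: float
    n_harmonics: int
    normalization: float = 1.0     # spatial mean of tau_1 (for scaled copies)

    @property
    def tau1(self) -> np.ndarray:
        return self.amplitudes[:, 0]

    def normalized(self) -> "DecompositionResult":
        """Copy with stresses divided by the spatial mean of tau_1."""
        scale = float(np.mean(self.amplitudes[:, 0]))
        if scale == 0:
            raise ValueError("cannot normalize: spatial mean of tau_1 is zero")
        return DecompositionResult(
            station_x=self.station_x, station_side=self.station_side,
            tau0=self.tau0 / scale, amplitudes=self.amplitudes / scale,
            phases=self.phases, tau_prime=self.tau_prime / scale,
            phase_avg=self.phase_avg / scale, period=self.period,
            n_harmonics=self.n_harmonics, normalization=scale,
        )

    def side_mask(self, side: str) -> np.ndarray:
        return self.station_side == (1 if side == "upper" else 0)

    def to_frame(self) -> pd.DataFrame:
        d = {"x": self.station_x, "side": self.station_side,
             "tau0": self.tau0, "tau_prime": self.tau_prime}
        for k in range(self.n_harmonics):
            d[f"tau{k + 1}"] = self.amplitudes[:, k]
            d[f"phase{k + 1}"] = self.phases[:, k]
        return pd.DataFrame(d)


def phase_average(times, values, period: float, bins: int = 64) -> np.ndarray:
    """One-period curve: mean of samples at fixed phase over all beats.

    Samples are assigned to the two nearest phase-bin centers with linear
    weights, which reduces to plain binning when sample phases coincide with
    bin centers.  A trailing partial beat is discarded with a warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
        squeeze = True
    else:
        squeeze = False
    span = times[-1] - times[0] + (times[1] - times[0] if len(times) > 1 else 0)
    n_beats = int(np.floor(span / period + 1e-9))
    if n_beats < 2:
        raise ValueError("phase averaging needs at least 2 complete beats")
    frac = span / period - n_beats
    if frac > 1e-6:
        keep = times - times[0] < n_beats * period - 1e-12
        log.warning("discarding trailing partial beat (%d of %d samples)",
                    np.sum(~keep), len(times))
        times, values = times[keep], values[keep]
    # bin centers at phases b/bins, so sampling grids commensurate with the
    # bin grid are binned without smearing
    phase = np.mod(times - times[0], period) / period * bins
    lo = np.floor(phase).astype(int)
    w_hi = phase - lo
    w_lo = 1.0 - w_hi
    b_lo = np.mod(lo, bins)
    b_hi = np.mod(lo + 1, bins)
    acc = np.zeros((bins, values.shape[1]))
    wsum = np.zeros(bins)
    np.add.at(acc, b_lo, w_lo[:, None] * values)
    np.add.at(acc, b_hi, w_hi[:, None] * values)
    np.add.at(wsum, b_lo, w_lo)
    np.add.at(wsum, b_hi, w_hi)
    if np.any(wsum == 0):
        raise ValueError("need at least as many samples per beat as phase bins")
    curve = acc / wsum[:, None]
    return curve[:, 0] if squeeze else curve.T


def harmonic_amplitudes(curve: np.ndarray, n_harmonics: int):
    """Fourier analysis of a one-period curve sampled at bin centers.

    Returns (tau0, amplitudes, phases) scaled so that a pure input
    ``A sin(2 pi k t/T + phi)`` yields amplitude A and phase phi for
    harmonic k.  Phases follow the sine convention.
    """
    curve = np.atleast_2d(np.asarray(curve, dtype=float))
    nbins = curve.shape[-1]
    if n_harmonics >= nbins / 2:
        raise ValueError("number of harmonics must be < bins/2 (aliasing)")
    coef = np.fft.rfft(curve, axis=-1)
    tau0 = coef[:, 0].real / nbins
    ck = coef[:, 1:n_harmonics + 1] * 2.0 / nbins
    amplitudes = np.abs(ck)
    # c_k = (amp/2)(e^{i phi} / i) pairing: A sin(w t + phi) has rfft
    # coefficient (N/2) * A * (sin phi - i cos phi) -> phi = atan2(Re, -Im)
    phases = np.arctan2(ck.real, -ck.imag)
    if curve.shape[0] == 1:
        return float(tau0[0]), amplitudes[0], phases[0]
    return tau0, amplitudes, phases


def _periodic_interp(phase, curve, period, bins):
    """Evaluate a bin-center-sampled periodic curve at arbitrary phases."""
    pos = np.mod(phase, period) / period * bins
    lo = np.floor(pos).astype(int)
    w = pos - lo
    return (1 - w) * curve[np.mod(lo, bins)] + w * curve[np.mod(lo + 1, bins)]


def nonperiodic_rms(times, values, curve, period: float) -> float:
    """RMS deviation of the signal from its periodic component.

    ``curve`` must be the phase average of the same series over the same
    period; it is evaluated at each sample's phase by periodic linear
    interpolation.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    bins = len(curve)
    span = times[-1] - times[0] + (times[1] - times[0] if len(times) > 1 else 0)
    if span < period * (1 - 1e-9):
        raise ValueError("series shorter than the stated period")
    tilde = _periodic_interp(times - times[0], np.asarray(curve), period, bins)
    return float(np.sqrt(np.mean((values - tilde) ** 2)))


def spatial_profiles(record: WSSRecord, n_harmonics: int = 3,
                     bins: int = 64) -> DecompositionResult:
    """Decompose every wall station of a simulation record.

    The beat period is taken from the known wall-motion period carried by
    the record (f1 is an input in the simulation context), not estimated
    from the signal.
    """
    if record.tau.shape[1] < 2:
        raise ValueError("need at least 2 stations for spatial profiles")
    bins = min(bins, record.samples_per_beat)
    curves = phase_average(record.times, record.tau, record.period, bins)
    tau0, amps, phases = harmonic_amplitudes(curves, n_harmonics)
    tau_p = np.array([
        nonperiodic_rms(record.times, record.tau[:, i], curves[i], record.period)
        for i in range(record.tau.shape[1])
    ])
    return DecompositionResult(
        station_x=record.station_x, station_side=record.station_side,
        tau0=np.atleast_1d(tau0), amplitudes=np.atleast_2d(amps),
        phases=np.atleast_2d(phases), tau_prime=tau_p, phase_avg=curves,
        period=record.period, n_harmonics=n_harmonics,
    )


def gradient_tau1(result: DecompositionResult, side: str = "upper") -> np.ndarray:
    """Signed spatial derivative of tau_1 along one wall (+x positive).

    Central divided differences on the (possibly nonuniform) station grid,
    one-sided at the ends of the periodic station ordering.
    """
    mask = result.side_mask(side)
    x = result.station_x[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 stations for a gradient")
    order = np.argsort(x)
    t1 = result.amplitudes[mask, 0][order]
    return x[order], np.gradient(t1, x[order])


def estimate_period(times, values) -> float:
    """Beat-period estimate for measured signals: first autocorrelation peak."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float) - np.mean(values)
    ac = np.correlate(v, v, mode="full")[len(v) - 1:]
    # first local maximum after the zero-lag peak has decayed
    dip = np.argmax(ac < 0) or 1
    k = dip + int(np.argmax(ac[dip:]))
    dt = times[1] - times[0]
    return float(k * dt)
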