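import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valvemorph.shear_decomposition import (
    phase_average, harmonic_amplitudes, nonperiodic_rms, spatial_profiles,
    gradient_tau1, estimate_period, DecompositionResult,
)
from valvemorph.synthetic_data import SignalSpec, make_signal


def _sine_series(n_beats=3, spb=64, amp=1.0, k=1, phase=0.3):
    t = np.arange(n_beats * spb) / spb
    return t, amp * np.sin(2 * np.pi * k * t + phase)


def test_phase_average_reproduces_a_pure_sine():
    t, v = _sine_series()
    curve = phase_average(t, v, 1.0, bins=64)
    expect = np.sin(2 * np.pi * np.arange(64) / 64 + 0.3)
    np.testing.assert_allclose(curve, expect, atol=1e-12)


def test_phase_average_of_constant_is_constant():
    t = np.arange(200) / 50.0
    curve = phase_average(t, np.full(200, 3.7), 1.0, bins=25)
    np.testing.assert_allclose(curve, 3.7, atol=1e-12)


def test_phase_average_noise_shrinks_like_one_over_sqrt_beats():
    # Monte-Carlo over seeds: residual RMS of the phase average ~ sigma/sqrt(N)
    sigma, n_beats, spb = 0.3, 64, 32
    rms = []
    for seed in range(8):
        spec = SignalSpec(constant=0.0, harmonics=((1, 1.0, 0.0),),
                          n_beats=n_beats, samples_per_beat=spb,
                          noise_sigma=sigma, seed=seed)
        t, v = make_signal(spec)
        curve = phase_average(t, v, 1.0, bins=spb)
        clean = np.sin(2 * np.pi * np.arange(spb) / spb)
        rms.append(np.sqrt(np.mean((curve - clean) ** 2)))
    assert np.mean(rms) == pytest.approx(sigma / np.sqrt(n_beats), rel=0.25)


def test_phase_average_requires_two_beats():
    t = np.arange(40) / 40.0
    with pytest.raises(ValueError, match="beats"):
        phase_average(t, np.sin(t), 1.0, bins=8)


def test_harmonic_amplitudes_exact_on_two_harmonic_curve():
    tb = np.arange(64) / 64.0
    curve = 2.0 + 3.0 * np.sin(2 * np.pi * tb) + 0.5 * np.sin(4 * np.pi * tb)
    tau0, amps, phases = harmonic_amplitudes(curve, 3)
    assert tau0 == pytest.approx(2.0, abs=1e-13)
    assert amps[0] == pytest.approx(3.0, abs=1e-13)
    assert amps[1] == pytest.approx(0.5, abs=1e-13)
    assert amps[2] == pytest.approx(0.0, abs=1e-13)


def test_harmonic_phase_convention_is_sine():
    tb = np.arange(64) / 64.0
    for phi in (0.0, 0.7, -1.2):
        curve = np.sin(2 * np.pi * tb + phi)
        _, amps, phases = harmonic_amplitudes(curve, 1)
        assert phases[0] == pytest.approx(phi, abs=1e-12)


def test_constant_curve_has_no_harmonics():
    tau0, amps, _ = harmonic_amplitudes(np.full(32, 7.0), 5)
    assert tau0 == pytest.approx(7.0)
    assert np.abs(amps).max() < 1e-13


def test_reconstruction_from_all_harmonics_is_complete():
    rng = np.random.default_rng(2)
    curve = rng.standard_normal(64)
    K = 31
    tau0, amps, phases = harmonic_amplitudes(curve, K)
    tb = np.arange(64) / 64.0
    recon = tau0 + sum(a * np.sin(2 * np.pi * (k + 1) * tb + p)
                       for k, (a, p) in enumerate(zip(amps, phases)))
    # complete except the Nyquist bin, excluded by K < bins/2
    coef = np.fft.rfft(curve)
    nyq = (coef[32].real / 64) * np.cos(2 * np.pi * 32 * tb)
    np.testing.assert_allclose(recon + nyq, curve, atol=1e-10)


def test_too_many_harmonics_rejected():
    with pytest.raises(ValueError, match="alias"):
        harmonic_amplitudes(np.zeros(32), 16)


def test_nonperiodic_rms_vanishes_for_exactly_periodic_series():
    t, v = _sine_series(n_beats=4)
    curve = phase_average(t, v, 1.0, bins=64)
    assert nonperiodic_rms(t, v, curve, 1.0) < 1e-12


def test_nonperiodic_rms_recovers_noise_level():
    # variance decomposition: residual ~ sigma * sqrt(1 - 1/N)
    sigma, n_beats = 0.4, 64
    spec = SignalSpec(constant=1.0, harmonics=((1, 2.0, 0.1),),
                      n_beats=n_beats, samples_per_beat=32,
                      noise_sigma=sigma, seed=9)
    t, v = make_signal(spec)
    curve = phase_average(t, v, 1.0, bins=32)
    tp = nonperiodic_rms(t, v, curve, 1.0)
    assert tp == pytest.approx(sigma * np.sqrt(1 - 1 / n_beats), rel=0.1)


def test_variance_identity_partitions_total_power():
    # nonperiodic content from beat-to-beat amplitude jitter: band-limited,
    # so the Nyquist bin (excluded by K = bins/2 - 1) stays empty
    spec = SignalSpec(constant=1.5, harmonics=((1, 2.0, 0.4), (2, 0.7, -0.2)),
                      n_beats=16, samples_per_beat=64,
                      amplitude_jitter=0.08, seed=4)
    t, v = make_signal(spec)
    bins = 64
    curve = phase_average(t, v, 1.0, bins=bins)
    K = bins // 2 - 1
    tau0, amps, _ = harmonic_amplitudes(curve, K)
    tp = nonperiodic_rms(t, v, curve, 1.0)
    lhs = np.mean(v ** 2)
    rhs = tau0 ** 2 + 0.5 * np.sum(amps ** 2) + tp ** 2
    assert lhs == pytest.approx(rhs, rel=1e-6)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(a=st.floats(-3, 3).filter(lambda v: abs(v) > 1e-3),
       b=st.floats(-5, 5))
def test_decomposition_is_affine_equivariant(a, b):
    t, v = _sine_series(n_beats=4)
    v = v + 0.8
    curve0 = phase_average(t, v, 1.0, bins=64)
    tau0_0, amps0, _ = harmonic_amplitudes(curve0, 2)
    tp0 = nonperiodic_rms(t, v, curve0, 1.0)
    curve1 = phase_average(t, a * v + b, 1.0, bins=64)
    tau0_1, amps1, _ = harmonic_amplitudes(curve1, 2)
    tp1 = nonperiodic_rms(t, a * v + b, curve1, 1.0)
    assert tau0_1 == pytest.approx(a * tau0_0 + b, abs=1e-9)
    np.testing.assert_allclose(amps1, np.abs(a) * amps0, atol=1e-9)
    assert tp1 == pytest.approx(abs(a) * tp0, abs=1e-9)


def test_nonperiodic_rms_invariant_to_whole_beat_shifts():
    spec = SignalSpec(constant=0.0, harmonics=((1, 1.0, 0.0),), n_beats=8,
                      samples_per_beat=32, noise_sigma=0.3, seed=12)
    t, v = make_signal(spec)
    curve = phase_average(t, v, 1.0, bins=32)
    tp = nonperiodic_rms(t, v, curve, 1.0)
    v_shift = np.roll(v, 2 * 32)           # two whole beats
    curve_s = phase_average(t, v_shift, 1.0, bins=32)
    tp_s = nonperiodic_rms(t, v_shift, curve_s, 1.0)
    assert tp_s == pytest.approx(tp, rel=1e-9)


def test_gradient_of_flat_and_linear_profiles():
    x = np.linspace(0, 9, 10)
    res = DecompositionResult(
        station_x=x, station_side=np.ones(10, int), tau0=np.zeros(10),
        amplitudes=np.full((10, 1), 2.0), phases=np.zeros((10, 1)),
        tau_prime=np.zeros(10), phase_avg=np.zeros((10, 4)), period=1.0,
        n_harmonics=1)
    _, g = gradient_tau1(res)
    assert np.abs(g).max() < 1e-12
    res.amplitudes = (0.5 * x + 1.0)[:, None]
    _, g = gradient_tau1(res)
    np.testing.assert_allclose(g, 0.5, atol=1e-12)


def test_normalized_profiles_have_unit_mean_tau1(norbc_run):
    dec = norbc_run["dec"].normalized()
    assert np.mean(dec.amplitudes[:, 0]) == pytest.approx(1.0, abs=1e-12)


def test_period_estimate_recovers_the_beat():
    t, v = _sine_series(n_beats=6, spb=50)
    assert estimate_period(t, v) == pytest.approx(1.0, rel=0.05)
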