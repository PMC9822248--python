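"""Electrophysiology metric tests: identities, generator-oracle checks, invariants."""

import numpy as np
import pytest

from synapkit import (
    SweepTrace,
    detect_minis,
    paired_pulse_ratio,
    psc_amplitude,
    rise_time_20_80,
    sucrose_charge,
    train_amplitudes,
)
from synapkit.errors import InputError, UndefinedMetricError, WindowError
from synapkit.synthetic import (
    simulate_evoked_pair,
    simulate_minis,
    simulate_sucrose_step,
    simulate_trace,
    simulate_train,
)

FS = 5000.0


def _trace(samples, stims=(0.01,), polarity="inward"):
    return SweepTrace(samples=np.asarray(samples, float), sampling_rate=FS,
                      stimulus_times=stims, polarity=polarity)


# ----------------------------------------------------------- psc_amplitude
def test_flat_trace_amplitude_zero():
    assert psc_amplitude(_trace(np.zeros(500))) == 0.0


def test_step_response_amplitude():
    x = np.zeros(500)
    x[int(0.015 * FS):] = -100.0   # step 5 ms after the stimulus
    assert psc_amplitude(_trace(x)) == pytest.approx(100.0)


def test_amplitude_offset_invariance():
    x = np.zeros(500)
    x[int(0.015 * FS):] = -80.0
    a0 = psc_amplitude(_trace(x))
    a1 = psc_amplitude(_trace(x + 55.0))
    assert a0 == pytest.approx(a1)


def test_artifact_is_blanked():
    """A stimulus artifact inside the blanking window must not contaminate
    the amplitude; oracle = the artifact-free twin trace."""
    clean, _ = simulate_evoked_pair(a1=80.0, a2=80.0, artifact_pa=0.0, noise_sd=0.0)
    spiky, _ = simulate_evoked_pair(a1=80.0, a2=80.0, artifact_pa=500.0, noise_sd=0.0)
    assert psc_amplitude(spiky, 1) == pytest.approx(psc_amplitude(clean, 1), rel=1e-9)
    assert psc_amplitude(clean, 1) == pytest.approx(80.0, rel=1e-6)


def test_window_beyond_trace_raises():
    with pytest.raises(WindowError):
        psc_amplitude(_trace(np.zeros(100)))  # 20 ms trace, 52 ms search window


# ------------------------------------------------------------- rise time
def test_rise_time_linear_ramp():
    """A linear ramp reaching its peak in 10 ms has a 20-80% rise of 6 ms."""
    x = np.zeros(1000)
    ramp = np.linspace(0.0, -100.0, int(0.010 * FS) + 1)
    start = int(0.015 * FS)
    x[start:start + ramp.size] = ramp
    x[start + ramp.size:] = -100.0
    assert rise_time_20_80(_trace(x)) == pytest.approx(6.0, abs=1000.0 / FS)


def test_rise_time_instantaneous_step():
    x = np.zeros(1000)
    x[int(0.015 * FS):] = -50.0
    assert rise_time_20_80(_trace(x)) <= 1000.0 / FS  # within one sample period


def test_rise_time_exponential_closed_form():
    """A single-exponential rise with tau has 20-80% rise tau*ln(4)."""
    tau = 0.002
    t = np.arange(1000) / FS
    x = np.where(t >= 0.015, -100.0 * (1 - np.exp(-(t - 0.015) / tau)), 0.0)
    expected = tau * np.log(4.0) * 1000.0
    assert rise_time_20_80(_trace(x)) == pytest.approx(expected, abs=1000.0 / FS)


def test_rise_time_zero_amplitude_errors():
    with pytest.raises(UndefinedMetricError):
        rise_time_20_80(_trace(np.zeros(500)))


# ------------------------------------------------------------------- PPR
def test_ppr_identical_responses_is_one():
    tr, _ = simulate_evoked_pair(a1=90.0, a2=90.0, noise_sd=0.0)
    assert paired_pulse_ratio([tr]) == pytest.approx(1.0, rel=1e-6)


def test_ppr_noise_free_pair():
    tr, truth = simulate_evoked_pair(a1=100.0, a2=150.0, noise_sd=0.0)
    assert paired_pulse_ratio([tr]) == pytest.approx(1.5, abs=1e-3)
    assert truth.ppr == pytest.approx(1.5)


def test_ppr_scale_invariance():
    tr, _ = simulate_evoked_pair(a1=100.0, a2=150.0, noise_sd=0.0)
    scaled = SweepTrace(samples=3.7 * tr.samples, sampling_rate=tr.sampling_rate,
                        stimulus_times=tr.stimulus_times, polarity=tr.polarity)
    assert paired_pulse_ratio([scaled]) == pytest.approx(paired_pulse_ratio([tr]))


def test_ppr_from_noisy_sweeps_recovers_truth():
    sweeps = [simulate_evoked_pair(a1=100.0, a2=150.0, noise_sd=5.0, seed=s)[0]
              for s in range(4)]
    est = paired_pulse_ratio(sweeps)
    # averaging 4 sweeps at noise sd 5 pA: generous 3-sigma-ish envelope
    assert est == pytest.approx(1.5, abs=0.15)


def test_ppr_zero_first_pulse_errors():
    tr, _ = simulate_evoked_pair(a1=0.0, a2=50.0, noise_sd=0.0)
    with pytest.raises(UndefinedMetricError):
        paired_pulse_ratio([tr])


def test_ppr_mismatched_intervals_error():
    tr, _ = simulate_evoked_pair(interval_ms=50.0)
    with pytest.raises(InputError):
        paired_pulse_ratio([tr], interval_ms=20.0)


# ---------------------------------------------------------------- sucrose
def test_sucrose_flat_trace_zero_charge():
    tr = SweepTrace(samples=np.zeros(int(12 * FS)), sampling_rate=FS,
                    stimulus_times=(1.0,), polarity="inward")
    assert sucrose_charge(tr) == 0.0


def test_sucrose_plateau_charge():
    tr, _ = simulate_sucrose_step(plateau_pa=100.0, plateau_s=10.0, noise_sd=0.0)
    assert sucrose_charge(tr) == pytest.approx(1000.0, rel=1e-3)


def test_sucrose_only_first_window_counts():
    tr, _ = simulate_sucrose_step(plateau_pa=100.0, plateau_s=20.0, post_s=0.5,
                                  noise_sd=0.0)
    assert sucrose_charge(tr, window=10.0) == pytest.approx(1000.0, rel=1e-3)


def test_sucrose_linear_in_current():
    a, _ = simulate_sucrose_step(plateau_pa=50.0, plateau_s=10.0, noise_sd=0.0)
    b, _ = simulate_sucrose_step(plateau_pa=150.0, plateau_s=10.0, noise_sd=0.0)
    assert sucrose_charge(b) == pytest.approx(3.0 * sucrose_charge(a), rel=1e-6)


def test_sucrose_additive_over_subwindows():
    tr, _ = simulate_sucrose_step(plateau_pa=100.0, plateau_s=10.0, noise_sd=0.0)
    total = sucrose_charge(tr, window=10.0)
    first = sucrose_charge(tr, window=4.0)
    assert 0.0 < first < total
    assert first == pytest.approx(400.0, rel=1e-3)


def test_sucrose_short_trace_errors():
    tr = SweepTrace(samples=np.zeros(int(2 * FS)), sampling_rate=FS)
    with pytest.raises(WindowError):
        sucrose_charge(tr, window=10.0)


# ------------------------------------------------------------------ minis
def test_minis_empty_on_quiet_trace():
    tr, _ = simulate_minis(rate_hz=0.0, duration_s=100.0, noise_sd=2.0, seed=0)
    assert detect_minis(tr).events == ()


def test_minis_recover_inserted_events():
    times = tuple(np.linspace(5.0, 95.0, 10))
    tr, truth = simulate_minis(event_times=times, amplitude_pa=30.0,
                               noise_sd=30.0 / 8.0, seed=1)
    res = detect_minis(tr)
    detected = np.array([e.time for e in res.events])
    assert detected.size == 10
    assert np.all(np.abs(detected - np.array(times)) < 0.001)  # within 1 ms
    assert res.frequency == pytest.approx(0.1)
    amps = np.array([e.amplitude for e in res.events])
    assert np.all(np.abs(amps - 30.0) < 5.0)


def test_minis_threshold_monotonicity():
    times = tuple(np.linspace(5.0, 95.0, 10))
    tr, _ = simulate_minis(event_times=times, amplitude_pa=30.0,
                           noise_sd=3.0, seed=2)
    counts = [len(detect_minis(tr, threshold=th).events)
              for th in (2.0, 4.0, 8.0, 1e9)]
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 0


def test_minis_events_sorted_by_time():
    tr, _ = simulate_minis(rate_hz=1.0, duration_s=100.2, noise_sd=2.0,
                           amplitude_pa=40.0, seed=3)
    res = detect_minis(tr)
    times = [e.time for e in res.events]
    assert times == sorted(times)


# ------------------------------------------------------------------ train
def test_train_identical_responses():
    tr, _ = simulate_train(n_stimuli=10, rate=10.0, first_amplitude=100.0,
                           depression_ratio=1.0, noise_sd=0.0)
    amps = train_amplitudes(tr, n_stimuli=10)
    np.testing.assert_allclose(amps, amps[0], rtol=1e-6)
    assert amps[0] == pytest.approx(100.0, rel=1e-3)


def test_train_zero_trace_gives_zeros():
    stims = tuple(0.1 + 0.1 * i for i in range(10))
    tr = SweepTrace(samples=np.zeros(int(1.2 * FS)), sampling_rate=FS,
                    stimulus_times=stims)
    np.testing.assert_array_equal(train_amplitudes(tr, n_stimuli=10), 0.0)


def test_train_recovers_depression_ratio():
    tr, truth = simulate_train(n_stimuli=50, rate=10.0, first_amplitude=100.0,
                               depression_ratio=0.9, noise_sd=0.2, seed=4)
    amps = train_amplitudes(tr, n_stimuli=50)
    true_amps = np.array([a for _, a in truth.events])
    # ratios on the large early responses, where the noise-peak bias of the
    # max-over-window estimator is negligible relative to the amplitude
    ratios = amps[1:10] / amps[:9]
    assert np.all(np.abs(ratios - 0.9) < 0.05)
    np.testing.assert_allclose(amps, true_amps, atol=2.0)


def test_train_truncated_trace_errors():
    tr, _ = simulate_train(n_stimuli=10, rate=10.0, noise_sd=0.0)
    short = SweepTrace(samples=tr.samples[: int(0.55 * FS)], sampling_rate=FS,
                       stimulus_times=tuple(t for t in tr.stimulus_times if t < 0.55))
    with pytest.raises((InputError, WindowError)):
        train_amplitudes(short, n_stimuli=10)
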