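"""Unit tests for the species-specific cochlear filter-bank model."""

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq

from periphpitch import (
    FERRET,
    HUMAN,
    FilterbankConfig,
    Waveform,
    erb,
    excitation_profile,
    f0_power_profile,
    gammatone_channel,
    make_cf_grid,
    resolved_harmonic_count,
    simulate,
    transduce,
)
from periphpitch.stimuli import ToneComplexSpec, harmonic_complex, pure_tone

FS = 48000.0


def tone(freq, dur=0.25, amp=0.1):
    t = np.arange(int(dur * FS)) / FS
    return Waveform(amp * np.sin(2 * np.pi * freq * t), FS)


# ---------------------------------------------------------------------------
# ERB laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("species, f, expected", [
    (HUMAN, 1000.0, 78.7402),     # 1000 / 12.7
    (FERRET, 1000.0, 321.9149),   # 1000/8.9047 + 209.6149
    (HUMAN, 500.0, 48.4703),      # 500 / (12.7 * 0.5**0.3)
    (FERRET, 150.0, 226.4599),
])
def test_erb_printed_values(species, f, expected):
    assert erb(species, f) == pytest.approx(expected, abs=5e-4)


def test_erb_positive_increasing_and_ferret_wider():
    f = np.linspace(100.0, 10000.0, 1000)
    for sp in (HUMAN, FERRET):
        vals = erb(sp, f)
        assert np.all(vals > 0)
    grid = np.linspace(100.0, 20000.0, 1000)
    assert np.all(np.diff(erb(HUMAN, grid)) > 0)
    assert np.all(np.diff(erb(FERRET, grid)) > 0)
    assert np.all(erb(FERRET, f) > erb(HUMAN, f))


def test_erb_rejects_nonpositive_frequency():
    with pytest.raises(ValueError):
        erb(HUMAN, 0.0)
    with pytest.raises(ValueError):
        erb("ferret", -100.0)


# ---------------------------------------------------------------------------
# CF grid
# ---------------------------------------------------------------------------

def test_cf_grid_log_spacing():
    two = make_cf_grid(FilterbankConfig(n_channels=2, cf_min=100, cf_max=10000))
    assert two == pytest.approx([100.0, 10000.0])
    three = make_cf_grid(FilterbankConfig(n_channels=3, cf_min=100, cf_max=10000))
    assert three == pytest.approx([100.0, 1000.0, 10000.0])
    full = make_cf_grid(FilterbankConfig(n_channels=500, cf_min=100, cf_max=10000))
    ratios = full[1:] / full[:-1]
    assert len(full) == 500
    assert np.all(np.diff(full) > 0)
    assert ratios == pytest.approx(np.full(499, ratios[0]))


def test_cf_grid_erb_rate_spacing_needs_species():
    cfg = FilterbankConfig(n_channels=50, spacing="erb-rate")
    with pytest.raises(ValueError):
        make_cf_grid(cfg)
    grid = make_cf_grid(cfg, HUMAN)
    assert grid[0] == 100.0 and grid[-1] == 10000.0
    assert np.all(np.diff(grid) > 0)


def test_cf_grid_rejects_cf_above_nyquist():
    with pytest.raises(ValueError):
        FilterbankConfig(cf_max=30000.0, sample_rate=48000.0)


# ---------------------------------------------------------------------------
# Gammatone filtering
# ---------------------------------------------------------------------------

def test_gammatone_unit_gain_at_cf():
    w = tone(2000.0)
    out = gammatone_channel(w, 2000.0, 240.0)
    # skip the onset ring-out when measuring steady-state gain
    sl = slice(int(0.05 * FS), None)
    gain_db = 20 * np.log10(np.std(out[sl]) / np.std(w.samples[sl]))
    assert abs(gain_db) < 0.5


def test_gammatone_off_frequency_attenuation():
    # order-4 gammatone at 5 ERB off-centre: analytic attenuation ~56 dB
    cf, bw = 3000.0, 300.0
    probe = tone(cf + 5 * bw)
    out = gammatone_channel(probe, cf, bw)
    sl = slice(int(0.05 * FS), None)
    atten_db = 20 * np.log10(np.std(probe.samples[sl]) / np.std(out[sl]))
    assert atten_db >= 20.0


def test_gammatone_silence_and_invalid_bandwidth():
    silence = Waveform(np.zeros(4800), FS)
    assert np.allclose(gammatone_channel(silence, 1000.0, 100.0), 0.0)
    with pytest.raises(ValueError):
        gammatone_channel(silence, 1000.0, -5.0)
    with pytest.raises(ValueError):
        gammatone_channel(silence, 30000.0, 100.0)


# ---------------------------------------------------------------------------
# Transduction
# ---------------------------------------------------------------------------

def test_transduce_all_negative_input_is_silenced():
    x = -np.abs(np.sin(2 * np.pi * 800 * np.arange(9600) / FS)) - 0.1
    out = transduce(x, HUMAN, FS)
    assert np.max(np.abs(out)) < 1e-3 * np.max(np.abs(x) ** 0.3)


def test_transduce_passband_identity_on_nonnegative_input():
    # nonnegative, below 3 kHz: rectifier is identity, so output ~ x**0.3
    t = np.arange(int(0.3 * FS)) / FS
    x = 0.5 + 0.3 * np.sin(2 * np.pi * 200.0 * t)
    out = transduce(x, HUMAN, FS)
    sl = slice(int(0.05 * FS), int(0.25 * FS))
    assert out[sl] == pytest.approx(x[sl] ** 0.3, rel=1e-2)


def test_transduce_stopband_attenuation():
    # a 5 kHz component surviving rectification must be cut by >= 60 dB
    t = np.arange(int(0.3 * FS)) / FS
    x = 1.0 + 0.5 * np.sin(2 * np.pi * 5000.0 * t)  # nonnegative
    rect = x**0.3
    out = transduce(x, HUMAN, FS)
    sl = slice(int(0.05 * FS), int(0.25 * FS))
    probe = np.exp(-2j * np.pi * 5000.0 * t[sl])
    amp_in = np.abs(np.mean(rect[sl] * probe))
    amp_out = np.abs(np.mean(out[sl] * probe))
    assert 20 * np.log10(amp_in / amp_out) >= 60.0


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

SMALL = FilterbankConfig(n_channels=40, cf_min=300.0, cf_max=8000.0)


def test_simulate_pure_tone_peaks_at_matching_channel():
    r = simulate(tone(1000.0), HUMAN, SMALL)
    profile = excitation_profile(r)
    assert r.cfs[np.argmax(profile)] == pytest.approx(1000.0, rel=0.08)


def test_simulate_silence_and_determinism():
    silence = Waveform(np.zeros(int(0.2 * FS)), FS)
    r = simulate(silence, FERRET, SMALL)
    assert np.all(r.output == 0.0)
    w = tone(700.0)
    a = simulate(w, FERRET, SMALL).output
    b = simulate(w, FERRET, SMALL).output
    assert np.array_equal(a, b)


def test_simulate_rejects_sample_rate_mismatch():
    w = Waveform(np.zeros(1000), 44100.0)
    with pytest.raises(ValueError):
        simulate(w, HUMAN, SMALL)


def test_excitation_scales_with_compressed_gain():
    # gain g on the input scales the profile by g**(2 * 0.3)
    w1 = tone(1000.0, amp=0.05)
    w2 = tone(1000.0, amp=0.20)
    p1 = excitation_profile(simulate(w1, HUMAN, SMALL))
    p2 = excitation_profile(simulate(w2, HUMAN, SMALL))
    mid = slice(10, 30)
    assert p2[mid] / p1[mid] == pytest.approx(4.0**0.6, rel=1e-3)


@pytest.fixture(scope="module")
def complex_responses():
    spec = ToneComplexSpec(f0=500.0, band_lo=1000.0, band_hi=10000.0,
                           duration_s=0.3, level_db_spl=70.0)
    w = harmonic_complex(spec, FS)
    cfg = FilterbankConfig(n_channels=80, cf_min=500.0, cf_max=10000.0)
    return {sp.name: simulate(w, sp, cfg) for sp in (HUMAN, FERRET)}


def test_excitation_resolvability_deeper_troughs_in_human(complex_responses):
    """Low harmonics leave resolvable excitation peaks only with narrow filters."""
    def peak_trough(resp):
        profile = excitation_profile(resp)
        peak = profile[np.argmin(np.abs(resp.cfs - 1500.0))]
        trough = profile[np.argmin(np.abs(resp.cfs - 1250.0))]
        return peak / trough

    assert peak_trough(complex_responses["human"]) > peak_trough(
        complex_responses["ferret"])


def test_envelope_f0_modulation_deeper_in_ferret(complex_responses):
    """At a 5 kHz fibre the wider ferret filter admits more harmonics, whose
    beating modulates the response at F0 more deeply than in the human."""
    depth = {}
    for name, resp in complex_responses.items():
        ch = np.argmin(np.abs(resp.cfs - 5000.0))
        seg = resp.output[ch, int(0.05 * FS):int(0.25 * FS)]
        spec = np.abs(rfft(seg - seg.mean()))
        freqs = rfftfreq(len(seg), 1 / FS)
        f0_bin = np.argmin(np.abs(freqs - 500.0))
        depth[name] = spec[f0_bin] / seg.mean() / len(seg)
    assert depth["ferret"] > depth["human"]


# ---------------------------------------------------------------------------
# F0 power profile
# ---------------------------------------------------------------------------

def test_f0_fraction_matches_direct_dft_oracle(complex_responses):
    """The rfft-based fraction equals a straight-line DFT projection."""
    resp = complex_responses["ferret"]
    prof = f0_power_profile(resp, 500.0)
    fs = resp.sample_rate
    i0 = int(round(0.05 * fs))
    n_win = int(round(round(0.2 * 500.0) * fs / 500.0))
    t = np.arange(n_win)
    for ch in (5, 40, 75):
        x = resp.output[ch, i0:i0 + n_win]
        c = np.sum(x * np.exp(-2j * np.pi * 100 * t / n_win))  # bin 100 = 500 Hz
        oracle = 2 * abs(c) ** 2 / (n_win * np.sum((x - x.mean()) ** 2))
        assert prof.fraction[ch] == pytest.approx(oracle, rel=1e-9)
        assert prof.power[ch] == pytest.approx(2 * abs(c) ** 2 / n_win**2,
                                               rel=1e-9)


def test_f0_profile_dc_only_channel_is_zero():
    out = np.vstack([np.full(9600, 0.5), np.full(9600, 0.1)])
    from periphpitch.periphery import NerveResponse
    r = NerveResponse(out, np.array([500.0, 1000.0]), FS, "human")
    prof = f0_power_profile(r, 500.0, window=(0.0, 0.2))
    assert np.all(prof.fraction == 0.0)
    assert np.all(prof.normalized == 0.0)


def test_f0_profile_normalization_peaks_at_one(complex_responses):
    prof = f0_power_profile(complex_responses["human"], 500.0)
    assert prof.normalized.max() == 1.0
    assert np.all((prof.fraction >= 0) & (prof.fraction <= 1))
    assert np.all((prof.normalized >= 0) & (prof.normalized <= 1))


def test_f0_profile_window_validation(complex_responses):
    resp = complex_responses["human"]
    with pytest.raises(ValueError):
        f0_power_profile(resp, 500.0, window=(0.25, 0.2))  # past the end
    with pytest.raises(ValueError):
        f0_power_profile(resp, 500.0, window=(0.05, 0.0005))  # < 1 cycle


# ---------------------------------------------------------------------------
# Resolvability estimate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("species, f0, expected", [
    (FERRET, 1000.0, 3),   # 1000 / 321.9 = 3.11
    (FERRET, 150.0, 1),    # 150 / 226.5 = 0.66 rounds up
    (FERRET, 500.0, 2),
    (HUMAN, 1000.0, 13),   # 1000 / 78.74 = 12.7
])
def test_resolved_harmonic_counts(species, f0, expected):
    assert resolved_harmonic_count(species, f0) == expected


def test_resolved_harmonic_count_rejects_nonpositive_f0():
    with pytest.raises(ValueError):
        resolved_harmonic_count(FERRET, 0.0)
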