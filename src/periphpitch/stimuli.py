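"""Synthesis of the 2AFC pitch-task stimuli.

Three stimulus families are generated here:

* pure-tone references (the repeating tone that anchors each trial);
* band-limited harmonic complex tones — the standard targets and the four
  probe manipulations (resolved-only bands, unresolved-only bands, and
  random-phase variants that flatten the temporal envelope);
* the calibrated pink-noise masker that guards against cochlear
  distortion-product cues at the missing fundamental.

All components of a complex have equal amplitude; the overall waveform RMS
realizes the requested dB SPL level, and the per-component level (overall
minus 10*log10(n_components)) is recorded for masker calibration.  Every
stimulus gets 5 ms raised-cosine onset/offset ramps (can be disabled) to
avoid spectral splatter.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
import yaml

from .periphery import FERRET, SpeciesProfile, erb, gammatone_channel, get_species
from .waveform import DEFAULT_CALIBRATION, P_REF_PA, Waveform, rms_for_level

__all__ = [
    "ProbeCondition",
    "ToneComplexSpec",
    "MaskerSpec",
    "harmonics_in_band",
    "pure_tone",
    "harmonic_complex",
    "pink_noise",
    "calibrate_masker",
    "build_probe_set",
    "synthesize",
]

DEFAULT_RAMP_S = 0.005


class ProbeCondition(str, Enum):
    """Closed set of stimulus classes used in the behavioural task."""

    STANDARD = "standard"
    LOW_HARMONICS = "low_harmonics"
    HIGH_HARMONICS = "high_harmonics"
    ALL_RANDOM_PHASE = "all_random_phase"
    HIGH_RANDOM_PHASE = "high_random_phase"
    REFERENCE = "reference"
    MASKED_STANDARD = "masked_standard"


@dataclass(frozen=True)
class ToneComplexSpec:
    """Recipe for one band-limited harmonic complex tone."""

    f0: float
    band_lo: float
    band_hi: float
    phase_mode: str = "sine"
    duration_s: float = 0.2
    level_db_spl: float = 70.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.band_lo > self.band_hi:
            raise ValueError("band_lo must not exceed band_hi")
        if self.phase_mode not in ("sine", "random"):
            raise ValueError("phase_mode must be 'sine' or 'random'")
        if self.phase_mode == "random" and self.rng_seed is None:
            raise ValueError("random phase mode requires an rng_seed")
        if len(harmonics_in_band(self.f0, self.band_lo, self.band_hi)) == 0:
            raise ValueError("no harmonic of f0 lies inside the band")

    @property
    def harmonics(self) -> np.ndarray:
        return harmonics_in_band(self.f0, self.band_lo, self.band_hi)

    @property
    def component_level_db_spl(self) -> float:
        """Level of each pure-tone component (equal-amplitude synthesis)."""
        return self.level_db_spl - 10.0 * math.log10(len(self.harmonics))


@dataclass(frozen=True)
class MaskerSpec:
    """Band and relative attenuation of the pink-noise masker."""

    band_lo: float = 100.0
    band_hi: float = 10000.0
    rel_atten_db: float = 5.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.rel_atten_db <= 0:
            raise ValueError("rel_atten_db must be positive")
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("invalid masker band")


def harmonics_in_band(f0: float, lo: float, hi: float) -> np.ndarray:
    """Frequencies n*f0 inside [lo, hi] (inclusive, with float tolerance)."""
    n_lo = max(1, int(math.ceil(lo / f0 - 1e-9)))
    n_hi = int(math.floor(hi / f0 + 1e-9))
    if n_hi < n_lo:
        return np.empty(0)
    return f0 * np.arange(n_lo, n_hi + 1, dtype=np.float64)


def _ramp_envelope(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= ramp
        env[-n_ramp:] *= ramp[::-1]
    return env


def pure_tone(freq: float, duration_s: float, level_db_spl: float,
              sample_rate: float, calibration: float = DEFAULT_CALIBRATION,
              ramp_s: float = DEFAULT_RAMP_S) -> Waveform:
    """Calibrated sinusoid with raised-cosine on/off ramps."""
    if freq >= sample_rate / 2:
        raise ValueError("tone frequency must be below the Nyquist frequency")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    amp = math.sqrt(2.0) * rms_for_level(level_db_spl, calibration)
    x = amp * np.sin(2 * np.pi * freq * t)
    x *= _ramp_envelope(n, int(round(ramp_s * sample_rate)))
    return Waveform(x, sample_rate, level_db_spl=level_db_spl,
                    calibration=calibration, meta={"freq_hz": freq})


def harmonic_complex(spec: ToneComplexSpec, sample_rate: float,
                     calibration: float = DEFAULT_CALIBRATION,
                     ramp_s: float = DEFAULT_RAMP_S) -> Waveform:
    """Equal-amplitude harmonic complex per the spec.

    Sine phase mode starts every component in sine phase (the convention that
    maximizes envelope modulation at F0); random mode draws each phase
    i.i.d. uniform on [0, 2*pi) from ``spec.rng_seed``.  The pre-ramp RMS
    realizes ``spec.level_db_spl``.
    """
    freqs = spec.harmonics
    if freqs.max() >= sample_rate / 2:
        raise ValueError("highest harmonic exceeds the Nyquist frequency")
    n = int(round(spec.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    if spec.phase_mode == "sine":
        phases = np.zeros(len(freqs))
    else:
        phases = np.random.default_rng(spec.rng_seed).uniform(0.0, 2 * np.pi,
                                                              len(freqs))
    x = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    rms = float(np.sqrt(np.mean(x**2)))
    x *= rms_for_level(spec.level_db_spl, calibration) / rms
    x *= _ramp_envelope(n, int(round(ramp_s * sample_rate)))
    return Waveform(
        x, sample_rate, level_db_spl=spec.level_db_spl, calibration=calibration,
        meta={
            "f0_hz": spec.f0,
            "component_freqs_hz": freqs.tolist(),
            "component_level_db_spl": spec.component_level_db_spl,
            "phase_mode": spec.phase_mode,
            "phases_rad": phases.tolist(),
            "rng_seed": spec.rng_seed,
        },
    )


def pink_noise(m: MaskerSpec, duration_s: float, sample_rate: float,
               calibration: float = DEFAULT_CALIBRATION) -> Waveform:
    """Seeded band-limited pink noise (power spectral density ~ 1/f in band).

    Synthesized in the frequency domain: i.i.d. complex Gaussian bins shaped
    by 1/sqrt(f) inside [band_lo, band_hi], zero outside, then normalized to
    unit full-scale RMS.  Scale with :func:`calibrate_masker` before mixing.
    """
    if m.band_hi > sample_rate / 2:
        raise ValueError("masker band must lie below the Nyquist frequency")
    rng = np.random.default_rng(m.rng_seed)
    n = int(round(duration_s * sample_rate))
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    shape = np.zeros(len(freqs))
    in_band = (freqs >= m.band_lo) & (freqs <= m.band_hi)
    shape[in_band] = 1.0 / np.sqrt(freqs[in_band])
    spectrum = (rng.standard_normal(len(freqs))
                + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(spectrum, n)
    x /= np.sqrt(np.mean(x**2))
    return Waveform(x, sample_rate, calibration=calibration,
                    meta={"band_hz": [m.band_lo, m.band_hi], "rng_seed": m.rng_seed})


def calibrate_masker(noise: Waveform, target: ToneComplexSpec,
                     species: SpeciesProfile | str = FERRET,
                     masker: MaskerSpec | None = None) -> float:
    """Gain that puts the masker ``rel_atten_db`` below the target components.

    The noise is passed through an order-4 gammatone centred at the target F0
    with the species ERB (ferret by default, matching the auditory-nerve
    bandwidth data used to set the masker level); the returned scalar gain
    makes the level of that filtered noise equal to the component level of the
    target minus ``rel_atten_db``.
    """
    species = get_species(species)
    masker = masker or MaskerSpec()
    filtered = gammatone_channel(noise, target.f0, erb(species, target.f0))
    rms = float(np.sqrt(np.mean(filtered**2)))
    if rms == 0.0:
        raise ValueError("masker noise is silent")
    measured_db = 20.0 * math.log10(rms * noise.calibration / P_REF_PA)
    target_db = target.component_level_db_spl - masker.rel_atten_db
    return 10.0 ** ((target_db - measured_db) / 20.0)


# ---------------------------------------------------------------------------
# Probe-set construction
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _band_table() -> dict:
    text = (importlib.resources.files("periphpitch") / "data" /
            "probe_bands.yaml").read_text()
    return yaml.safe_load(text)


_REFERENCE_KEYS = {260: ("ferret", "260"), 707: ("ferret", "707"),
                   "human": ("human", "200")}

#: Reference pure-tone frequency per reference condition (log midpoint of the
#: two target F0s).
REFERENCE_HZ = {260: 260.0, 707: 707.0, "human": math.sqrt(180.0 * 220.0)}

REFERENCE_LEVEL_DB_SPL = 60.0


def build_probe_set(reference, species: SpeciesProfile | str | None = None,
                    rng_seed: int = 0, duration_s: float = 0.2,
                    ) -> dict[float, dict[ProbeCondition, ToneComplexSpec]]:
    """Specs for every stimulus class of one reference condition.

    Parameters
    ----------
    reference : {260, 707, "human"}
        Which task variant: the two ferret reference pure tones or the human
        180/220 Hz task.
    species : optional
        Cross-checked against the reference (ferret references imply ferret).
    rng_seed : int
        Base seed from which the random-phase probes derive their phases.

    Returns
    -------
    dict
        ``{f0: {ProbeCondition: ToneComplexSpec}}`` with the five target
        classes plus the reference tone (expressed as a single-component
        spec) and the masked standard (identical band to the standard; the
        masker itself is a separate :class:`MaskerSpec`).
    """
    try:
        sp_name, key = _REFERENCE_KEYS[reference]
    except KeyError:
        raise ValueError(f"unknown reference condition {reference!r}")
    if species is not None and get_species(species).name != sp_name:
        raise ValueError(f"reference {reference!r} belongs to the {sp_name} task")
    table = _band_table()[sp_name][key]
    level = float(table["level_db_spl"])
    ref_hz = REFERENCE_HZ[reference]

    out: dict[float, dict[ProbeCondition, ToneComplexSpec]] = {}
    for i, f0 in enumerate(table["f0s"]):
        f0 = float(f0)
        std_lo, std_hi = (float(v) for v in table["standard"][int(f0)])
        low_lo, low_hi = (float(v) for v in table["low_harmonics"][int(f0)])
        high_lo, high_hi = (float(v) for v in table["high_harmonics"][int(f0)])

        def spec(lo, hi, mode, seed_tag):
            seed = None if mode == "sine" else (rng_seed * 1000003 + seed_tag) % (2**31)
            return ToneComplexSpec(f0=f0, band_lo=lo, band_hi=hi,
                                   phase_mode=mode, duration_s=duration_s,
                                   level_db_spl=level, rng_seed=seed)

        out[f0] = {
            ProbeCondition.STANDARD: spec(std_lo, std_hi, "sine", 0),
            ProbeCondition.MASKED_STANDARD: spec(std_lo, std_hi, "sine", 0),
            ProbeCondition.LOW_HARMONICS: spec(low_lo, low_hi, "sine", 0),
            ProbeCondition.HIGH_HARMONICS: spec(high_lo, high_hi, "sine", 0),
            ProbeCondition.ALL_RANDOM_PHASE: spec(std_lo, std_hi, "random", 2 * i + 1),
            ProbeCondition.HIGH_RANDOM_PHASE: spec(high_lo, high_hi, "random", 2 * i + 2),
            ProbeCondition.REFERENCE: ToneComplexSpec(
                f0=ref_hz, band_lo=ref_hz, band_hi=ref_hz, phase_mode="sine",
                duration_s=duration_s, level_db_spl=REFERENCE_LEVEL_DB_SPL),
        }
    return out


def synthesize(spec: ToneComplexSpec, sample_rate: float,
               calibration: float = DEFAULT_CALIBRATION) -> Waveform:
    """Render a spec (single-component specs become pure tones)."""
    if len(spec.harmonics) == 1 and spec.band_lo == spec.band_hi:
        return pure_tone(spec.f0, spec.duration_s, spec.level_db_spl,
                         sample_rate, calibration)
    return harmonic_complex(spec, sample_rate, calibration)
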