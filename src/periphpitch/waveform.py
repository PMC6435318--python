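"""Calibrated audio waveforms.

All synthesis and analysis in this package works on :class:`Waveform` objects:
a mono sample array in full-scale units plus a sample rate and a single
calibration constant mapping full-scale units to Pascals.  Sound levels are
expressed in dB SPL re 20 uPa under that calibration, so levels are exact
*relative* levels; the absolute mapping to real-world SPL is a free constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

#: dB SPL reference pressure, 20 micropascal.
P_REF_PA = 20e-6

#: Default full-scale-to-Pascal calibration constant (1 full-scale unit = 1 Pa).
DEFAULT_CALIBRATION = 1.0


@dataclass
class Waveform:
    """A mono pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Pressure samples in full-scale units.
    sample_rate : float
        Sampling rate in Hz.
    level_db_spl : float, optional
        Nominal calibrated level of the signal in dB SPL, if known.
    calibration : float
        Pascals per full-scale unit.
    meta : dict
        Free-form synthesis metadata (component table, seed, ...).
    """

    samples: np.ndarray
    sample_rate: float
    level_db_spl: float | None = None
    calibration: float = DEFAULT_CALIBRATION
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def measured_level_db_spl(self) -> float:
        """Level of the waveform as stored, in dB SPL under its calibration."""
        r = self.rms()
        if r == 0.0:
            raise ValueError("cannot express silence in dB SPL")
        return 20.0 * np.log10(r * self.calibration / P_REF_PA)


def rms_for_level(level_db_spl: float, calibration: float = DEFAULT_CALIBRATION) -> float:
    """Full-scale RMS that realizes ``level_db_spl`` under ``calibration``."""
    return P_REF_PA * 10.0 ** (level_db_spl / 20.0) / calibration


def write_wav(path, w: Waveform) -> None:
    """Write a waveform as 32-bit float mono WAV."""
    wavfile.write(path, int(round(w.sample_rate)), w.samples.astype(np.float32))


def read_wav(path, calibration: float = DEFAULT_CALIBRATION) -> Waveform:
    """Read a mono WAV file into a :class:`Waveform`."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype.kind == "i":  # integer PCM -> full scale [-1, 1)
        data = data / float(np.iinfo(data.dtype).max + 1)
    return Waveform(samples=data.astype(np.float64), sample_rate=float(fs),
                    calibration=calibration)
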