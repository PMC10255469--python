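"""Signal conditioning: high-pass filter, common average reference, FFT band
extraction.

The canonical processing order is high-pass -> CAR -> band extraction:
removing slow drift before re-referencing keeps channel offsets from leaking
into the common average.  Band extraction is a hard FFT mask — the forward
transform of each channel, zeroing of every bin outside the band, inverse
transform — applied per segment, so the bin granularity is ``fs/n_samples``.

Band edges follow clinical convention (theta 4-8, alpha 8-13, beta 13-30,
gamma 30-45 Hz) and are configurable.  Bins are retained on the half-open
interval ``[f_lo, f_hi)`` so that adjacent bands partition the spectrum
without sharing their boundary bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import PreconditionError, RangeError
from .io import Recording

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "band_by_name",
    "common_average_reference",
    "highpass",
    "band_extract",
    "car_array",
    "highpass_array",
    "bandpass_fft",
]


@dataclass(frozen=True)
class Band:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 < self.f_lo < self.f_hi):
            raise RangeError(f"invalid band edges [{self.f_lo}, {self.f_hi})")

    def validate_for(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise RangeError(
                f"band {self.name} [{self.f_lo}, {self.f_hi}) exceeds Nyquist {fs / 2}"
            )


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 45.0),
)


def band_by_name(name: str, bands: tuple[Band, ...] = DEFAULT_BANDS) -> Band:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(name)


# -- array-level kernels (fragments are bare arrays) ------------------------

def car_array(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if data.shape[0] < 2:
        raise PreconditionError("common average reference needs >= 2 channels")
    return data - data.mean(axis=0, keepdims=True)


def highpass_array(data: np.ndarray, fs: float, cutoff: float = 1.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass (applied forward-backward)."""
    if not (0 < cutoff < fs / 2):
        raise RangeError(f"cutoff {cutoff} Hz outside (0, {fs / 2}) Hz")
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def bandpass_fft(data: np.ndarray, fs: float, band: Band) -> np.ndarray:
    """FFT mask band-pass: zero every rFFT bin with frequency outside
    ``[f_lo, f_hi)``, inverse-transform, take the real part."""
    band.validate_for(fs)
    n = data.shape[-1]
    if n == 0:
        raise RangeError("empty segment")
    spec = np.fft.rfft(data, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = (freqs >= band.f_lo) & (freqs < band.f_hi)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


# -- Recording-level operations ---------------------------------------------

def common_average_reference(rec: Recording) -> Recording:
    return rec.with_data(car_array(rec.data))


def highpass(rec: Recording, cutoff: float = 1.0, order: int = 4) -> Recording:
    return rec.with_data(highpass_array(rec.data, rec.fs, cutoff, order))


def band_extract(rec: Recording, band: Band) -> Recording:
    return rec.with_data(bandpass_fft(rec.data, rec.fs, band))
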