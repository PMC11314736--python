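"""Band-pass filter bank splitting epochs into motor-imagery sub-bands.

The default bank covers the rhythms modulated by motor imagery over
sensorimotor cortex: mu (8-13 Hz), low beta (13-22 Hz), high beta
(22-30 Hz), and the full 8-30 Hz band.  Filters are Butterworth band-pass,
applied forward-backward (zero phase) so epochs stay cue-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import EpochedEEG


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band edges must satisfy 0 < lo < hi, got ({self.lo}, {self.hi})")


def default_bands() -> list[BandSpec]:
    """The four standard motor-imagery sub-bands."""
    return [
        BandSpec("mu", 8.0, 13.0),
        BandSpec("low_beta", 13.0, 22.0),
        BandSpec("high_beta", 22.0, 30.0),
        BandSpec("full", 8.0, 30.0),
    ]


@dataclass
class FilterBank:
    """A set of band-pass filters sharing one design.

    Parameters
    ----------
    bands : list of BandSpec
        Pass bands; defaults to :func:`default_bands`.
    order : int
        Butterworth order (of the analog prototype; the band-pass filter has
        twice as many poles).
    zero_phase : bool
        Forward-backward filtering (no group delay) when True.
    """

    bands: list[BandSpec] = field(default_factory=default_bands)
    order: int = 4
    design: str = "butterworth"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("filter bank needs at least one band")
        if self.design != "butterworth":
            raise ValueError("only butterworth design is supported")

    def _sos(self, band: BandSpec, fs: float):
        nyq = fs / 2.0
        if band.hi >= nyq:
            raise ValueError(f"band edge {band.hi} Hz >= Nyquist ({nyq} Hz)")
        return butter(self.order, [band.lo / nyq, band.hi / nyq], btype="bandpass", output="sos")

    def filter_array(self, x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
        """Filter along the last axis of ``x``."""
        sos = self._sos(band, fs)
        if self.zero_phase:
            padlen = 3 * (2 * sos.shape[0] + 1)
            if x.shape[-1] <= padlen:
                raise ValueError(f"trial too short for zero-phase filtering (need > {padlen} samples)")
            return sosfiltfilt(sos, x, axis=-1)
        from scipy.signal import sosfilt

        return sosfilt(sos, x, axis=-1)


def apply_filterbank(epochs: EpochedEEG, bank: FilterBank | None = None) -> list[EpochedEEG]:
    """Decompose each trial into one narrowband copy per band.

    Filtering is applied per channel per trial; labels, sampling rate and
    tensor shape are preserved in every band's output.
    """
    if bank is None:
        bank = FilterBank()
    out = []
    for band in bank.bands:
        filtered = bank.filter_array(epochs.data, band, epochs.fs)
        out.append(EpochedEEG(filtered, epochs.labels.copy(), epochs.fs, list(epochs.channel_names)))
    return out
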