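"""Synthetic two-class EEG with a planted spatial-covariance difference.

The generator emulates the structure motor-imagery CSP assumes: two latent
oscillatory sources band-limited to the rhythm band of interest, whose
variances are modulated oppositely by the two classes (event-related
desynchronization in disguise), mixed into the channel array by a random
orthogonal matrix and buried in broadband sensor noise.  Because the class
difference is exactly a band-limited covariance rotation, CSP, the feature
selectors, and the classifiers all have recoverable ground truth.

``make_planted_feature_table`` plants class-shifted Gaussian columns among
exchangeable noise columns for testing the selectors in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filterbank import BandSpec, FilterBank
from .io import EpochedEEG, FeatureTable


@dataclass
class SynthConfig:
    """Study conditions for the synthetic motor-imagery generator.

    Attributes
    ----------
    n_trials_per_class : int
        Trials per class (exact balance).
    n_channels : int
        Sensor count; the two informative sources are mixed into all of them.
    fs : float
        Sampling rate in Hz (100 Hz matches typical downsampled MI datasets).
    duration : float
        Trial length in seconds (2.5 s of post-cue imagery).
    effect_band : (float, float)
        Band the class effect lives in, Hz.
    effect_strength : float
        Class-wise variance ratio of the two latent sources (>= 1; 1 = null).
    noise_sd : float
        Standard deviation of i.i.d. broadband sensor noise, in units of the
        (unit-variance) latent sources.
    seed : int
        Generator seed; output is bit-reproducible given the config.
    """

    n_trials_per_class: int = 60
    n_channels: int = 8
    fs: float = 100.0
    duration: float = 2.5
    effect_band: tuple[float, float] = (8.0, 30.0)
    effect_strength: float = 8.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1 or self.n_channels < 2:
            raise ValueError("need n_trials_per_class >= 1 and n_channels >= 2")
        lo, hi = self.effect_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("effect_band must lie within (0, fs/2)")
        if self.effect_strength < 1:
            raise ValueError("effect_strength must be >= 1")
        if self.duration * self.fs < 32:
            raise ValueError("trials too short")


def make_synthetic_mi(config: SynthConfig) -> tuple[EpochedEEG, dict]:
    """Generate two-class epochs with a planted band-limited covariance effect.

    Class 1 scales latent source A's variance by ``effect_strength``; class 2
    scales source B's.  Sources are white noise band-limited by the same
    Butterworth design the analysis filter bank uses, then mixed by a random
    orthogonal matrix (QR of a seeded Gaussian), plus i.i.d. Gaussian noise.

    Returns
    -------
    epochs : EpochedEEG
        Interleaved class-1/class-2 trials.
    truth : dict
        ``mixing`` (n_channels x 2 informative columns), ``source_indices``,
        and the full orthogonal matrix ``Q``.
    """
    rng = np.random.default_rng(config.seed)
    n_samp = int(round(config.duration * config.fs))
    n_trials = 2 * config.n_trials_per_class
    band = BandSpec("effect", *config.effect_band)
    bank = FilterBank(bands=[band])

    gauss = rng.normal(size=(config.n_channels, config.n_channels))
    Q, R = np.linalg.qr(gauss)
    Q = Q * np.sign(np.diag(R))  # unique orthogonal factor
    mixing = Q[:, :2]  # columns for sources A and B

    labels = np.empty(n_trials, dtype=int)
    labels[0::2] = 1
    labels[1::2] = 2
    gain = np.sqrt(config.effect_strength)

    # band-limit with padding so filtfilt edge effects stay out of the trial
    pad = max(int(config.fs), 32)
    raw = rng.normal(size=(n_trials, 2, n_samp + 2 * pad))
    sources = bank.filter_array(raw, band, config.fs)[..., pad:-pad]
    sources /= sources.std(axis=-1, keepdims=True)  # unit variance per trial

    data = np.empty((n_trials, config.n_channels, n_samp))
    for i in range(n_trials):
        s = sources[i].copy()
        if labels[i] == 1:
            s[0] *= gain
        else:
            s[1] *= gain
        data[i] = mixing @ s
    data += config.noise_sd * rng.normal(size=data.shape)

    epochs = EpochedEEG(data, labels, config.fs, [f"ch{i}" for i in range(config.n_channels)])
    truth = {"mixing": mixing, "source_indices": [0, 1], "Q": Q}
    return epochs, truth


def make_planted_feature_table(
    n_trials: int,
    n_informative: int,
    n_noise: int,
    delta: float,
    seed: int = 0,
) -> tuple[FeatureTable, np.ndarray]:
    """Feature table with class-shifted informative columns among pure noise.

    Informative columns are unit-variance Gaussians with class means at
    ±delta/2; noise columns are class-independent standard Gaussians.  Labels
    are exactly balanced (n_trials rounded down to even).

    Returns the table and a boolean mask marking the informative columns
    (always the first ``n_informative``; selectors are equivariant to column
    order, which the tests verify separately).
    """
    if n_informative < 1:
        raise ValueError("need n_informative >= 1")
    if n_noise < 0 or n_trials < 4:
        raise ValueError("need n_noise >= 0 and n_trials >= 4")
    rng = np.random.default_rng(seed)
    n_trials = 2 * (n_trials // 2)
    labels = np.empty(n_trials, dtype=int)
    labels[0::2] = 1
    labels[1::2] = 2
    p = n_informative + n_noise
    values = rng.normal(size=(n_trials, p))
    shift = np.where(labels == 2, delta / 2.0, -delta / 2.0)
    values[:, :n_informative] += shift[:, None]
    mask = np.zeros(p, dtype=bool)
    mask[:n_informative] = True
    meta = [
        {"band": "planted" if mask[j] else "noise", "filter": int(j)} for j in range(p)
    ]
    return FeatureTable(values, labels, meta), mask
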