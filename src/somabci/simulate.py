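"""Synthetic motor-imagery EEG generator.

Emulates the statistical structure the downstream analysis relies on: each
trial is a 2 s, 100 Hz epoch whose cortical sources carry 1/f background
activity everywhere plus band-limited (mu, 8-13 Hz) oscillations planted in
chosen somatomotor ROIs with class-dependent amplitude.  Source activity is
projected to the scalp through the spherical lead field and white sensor
noise is added at a configurable signal-to-noise ratio.

The default planted configuration expresses a hand-vs-foot contrast in the
left-hemisphere hand areas (S1H_L, M1H_L, stronger for hand imagery) and
foot areas (S1F_L, M1F_L, stronger for foot imagery), mirroring the
homuncular regions that dominate real motor-imagery recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._rng import substream
from .containers import FOOT, HAND, TrialSet
from .headmodel import LeadField, SourceSpace, project_sources

__all__ = ["PlantedEffect", "GeneratorConfig", "generate_background",
           "plant_class_signal", "generate_trialset"]


@dataclass(frozen=True)
class PlantedEffect:
    """Class-dependent band-limited oscillation in one ROI.

    ``amplitude_hand`` / ``amplitude_foot`` are RMS amplitudes (same units as
    the unit-RMS background) applied to every member source of ``roi_id``
    when the trial label is hand / foot.  The two classes are distinguished
    only through this amplitude contrast; its sign convention is irrelevant
    to variance-based features.
    """

    roi_id: str
    band: tuple[float, float] = (8.0, 13.0)
    amplitude_hand: float = 1.0
    amplitude_foot: float = 1.0


def _default_effects() -> list[PlantedEffect]:
    return [
        PlantedEffect("S1H_L", (8.0, 13.0), amplitude_hand=1.7, amplitude_foot=1.0),
        PlantedEffect("M1H_L", (8.0, 13.0), amplitude_hand=1.7, amplitude_foot=1.0),
        PlantedEffect("S1F_L", (8.0, 13.0), amplitude_hand=1.0, amplitude_foot=1.7),
        PlantedEffect("M1F_L", (8.0, 13.0), amplitude_hand=1.0, amplitude_foot=1.7),
    ]


@dataclass
class GeneratorConfig:
    n_train: int = 200
    n_test: int = 100
    class_balance: float = 0.5       # fraction of hand (positive) trials
    fs: float = 100.0
    epoch_s: float = 2.0
    planted_effects: list[PlantedEffect] = field(default_factory=_default_effects)
    background_exponent: float = 1.0  # PSD ~ 1/f^exponent
    sensor_snr: float = 1.5           # signal RMS over sensor-noise RMS
    seed: int = 0

    def validate(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("trial counts must be positive")
        if not (0 < self.class_balance < 1):
            raise ValueError("class_balance must lie strictly between 0 and 1")
        if self.sensor_snr <= 0:
            raise ValueError("sensor_snr must be positive")
        if self.background_exponent < 0:
            raise ValueError("background_exponent must be non-negative")
        for eff in self.planted_effects:
            if self.fs <= 2 * eff.band[1]:
                raise ValueError(
                    f"fs={self.fs} must exceed twice the upper band edge {eff.band[1]}")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_background(n_sources: int, n_samples: int, exponent: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian 1/f^exponent processes, unit RMS, independent per source.

    Realized by shaping white Gaussian noise in the frequency domain with
    amplitude f^(-exponent/2) (DC excluded), so the PSD falls as 1/f^exponent.
    """
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    white = rng.standard_normal((n_sources, n_samples))
    if exponent == 0:
        return white
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)  # shape only; absolute scale is irrelevant
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-300)


def _bandlimited_noise(band: tuple[float, float], n: int, n_samples: int, fs: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (hard spectral mask)."""
    white = rng.standard_normal((n, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no FFT bins at fs={fs}, n={n_samples}")
    x = np.fft.irfft(spec * mask, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-300)


def plant_class_signal(source_space: SourceSpace, effect: PlantedEffect, label: str,
                       n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Source-space increment for one planted effect on one trial.

    Returns an (n_sources, n_samples) array that is zero outside the effect's
    ROI and band-limited Gaussian noise with the class's RMS amplitude inside.
    """
    members = source_space.roi_members(effect.roi_id)
    amp = effect.amplitude_hand if label == HAND else effect.amplitude_foot
    out = np.zeros((source_space.n_sources, n_samples))
    out[members] = amp * _bandlimited_noise(effect.band, len(members), n_samples, fs, rng)
    return out


def _simulate_split(split: str, n_trials: int, config: GeneratorConfig,
                    leadfield: LeadField, source_space: SourceSpace) -> TrialSet:
    n_samples = int(round(config.epoch_s * config.fs))
    n_hand = int(round(config.class_balance * n_trials))
    labels = np.array([HAND] * n_hand + [FOOT] * (n_trials - n_hand), dtype=object)
    substream(config.seed, "labels", split).shuffle(labels)
    n_elec = leadfield.matrix.shape[0]
    data = np.empty((n_trials, n_elec, n_samples))
    for t in range(n_trials):
        rng = substream(config.seed, "trial", split, t)
        src = generate_background(source_space.n_sources, n_samples,
                                  config.background_exponent, rng)
        for eff in config.planted_effects:
            src += plant_class_signal(source_space, eff, labels[t], n_samples,
                                      config.fs, rng)
        sensor = project_sources(leadfield, src)
        if np.isfinite(config.sensor_snr):
            signal_rms = np.sqrt(np.mean(sensor ** 2))
            noise = substream(config.seed, "noise", split, t).standard_normal(sensor.shape)
            sensor = sensor + (signal_rms / config.sensor_snr) * noise
            sensor -= sensor.mean(axis=0, keepdims=True)  # restore average reference
        data[t] = sensor
    names = list(leadfield.electrode_ref.labels)
    return TrialSet(data, labels, config.fs, "sensor", names)


def generate_trialset(config: GeneratorConfig, leadfield: LeadField,
                      source_space: SourceSpace) -> tuple[TrialSet, TrialSet]:
    """Draw deterministic train/test sensor TrialSets from disjoint substreams."""
    config.validate()
    if leadfield.matrix.shape[1] != source_space.n_sources:
        raise ValueError("lead field and source space disagree on n_sources")
    for eff in config.planted_effects:
        source_space.roi_members(eff.roi_id)  # raises on unknown/empty ROI
    train = _simulate_split("train", config.n_train, config, leadfield, source_space)
    test = _simulate_split("test", config.n_test, config, leadfield, source_space)
    return train, test
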