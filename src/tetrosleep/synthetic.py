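"""Seeded synthetic EEG-like epoch generator for six sleep stages.

Each stage is emulated as a sum of band-limited sinusoids with random
phases on top of 1/f (pink) background noise, with dominant frequencies
loosely following sleep physiology: wake alpha (~10 Hz), S1 theta
(~6 Hz), S2 sigma spindles (~13 Hz), S3/S4 delta (2.5/1 Hz, high
amplitude) and REM a mixed theta+beta profile.  Amplitudes are set so
that no single summary statistic separates the classes but the full
multilevel textural pipeline does.

Every epoch is deterministic given ``(seed, class, index)``, so fixtures
regenerate identically anywhere.  This generator emulates balanced
stage-labeled epoch datasets only: there are no artifacts, no
inter-subject variability and no stage transitions within an epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["STAGES", "DEFAULT_PROFILES", "SynthConfig", "gen_epoch", "gen_dataset"]

STAGES = ("W", "S1", "S2", "S3", "S4", "REM")

#: per-stage list of (center frequency Hz, amplitude) sinusoid components
DEFAULT_PROFILES = {
    "W": [(10.0, 1.0), (20.0, 0.25)],
    "S1": [(6.0, 0.8), (10.0, 0.2)],
    "S2": [(13.0, 0.9), (3.0, 0.4)],
    "S3": [(2.5, 1.2), (13.0, 0.2)],
    "S4": [(1.0, 1.6), (2.5, 0.3)],
    "REM": [(5.0, 0.7), (20.0, 0.5)],
}


@dataclass
class SynthConfig:
    """Stated world of the synthetic fixtures.

    Defaults give 30-s epochs at 128 Hz (3,840 samples) in six balanced
    classes with unit-variance pink background noise.
    """

    sampling_rate: float = 128.0
    epoch_seconds: float = 30.0
    n_per_class: int = 50
    classes: tuple = STAGES
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    noise_amplitude: float = 1.0
    seed: int = 0

    @property
    def epoch_length(self) -> int:
        return int(round(self.sampling_rate * self.epoch_seconds))

    def validate(self) -> None:
        if self.epoch_length < 512:
            raise InvalidInputError(
                f"epoch length {self.epoch_length} < 512 samples; the 5-level "
                "extractor needs longer epochs"
            )
        if len(self.classes) != 6:
            raise InvalidInputError("six stage classes are required")
        missing = [c for c in self.classes if c not in self.profiles]
        if missing:
            raise InvalidInputError(f"no spectral profile for classes {missing}")
        if self.n_per_class < 1:
            raise InvalidInputError("n_per_class must be >= 1")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def gen_epoch(config: SynthConfig, class_id: str, index: int) -> np.ndarray:
    """One deterministic epoch of the given stage class."""
    config.validate()
    if class_id not in config.classes:
        raise InvalidInputError(f"unknown class {class_id!r}; expected one of {config.classes}")
    rng = np.random.default_rng(
        [config.seed, config.classes.index(class_id), int(index)]
    )
    n = config.epoch_length
    t = np.arange(n) / config.sampling_rate
    signal = np.zeros(n)
    for freq, amp in config.profiles[class_id]:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        signal += amp * np.sin(2.0 * np.pi * freq * t + phase)
    if config.noise_amplitude > 0:
        signal = signal + config.noise_amplitude * _pink_noise(rng, n)
    return signal


def gen_dataset(config: SynthConfig):
    """Balanced, label-shuffled dataset of ``6 * n_per_class`` epochs.

    Returns ``(epochs, labels)``: a 2-D float array (epochs x samples) and
    an array of stage labels in the shuffled order.
    """
    config.validate()
    epochs = []
    labels = []
    for class_id in config.classes:
        for index in range(config.n_per_class):
            epochs.append(gen_epoch(config, class_id, index))
            labels.append(class_id)
    order = np.random.default_rng([config.seed, len(config.classes)]).permutation(len(labels))
    return np.asarray(epochs)[order], np.asarray(labels)[order]
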