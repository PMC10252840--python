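"""Seeded generator of EEG-like multichannel recordings in the STEW text dialect.

Each channel is a sum of five band-limited oscillators (one per conventional
EEG band) whose amplitudes depend on the condition, plus pink (1/f) and white
noise.  The class contrast follows the standard stress signature: alpha
suppression and beta elevation under stress.  Everything is deterministic
given (seed, subject, condition).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_io import CHANNEL_NAMES, Recording, condition_to_suffix, recording_filename

__all__ = ["SimConfig", "generate_recording", "generate_dataset", "DEFAULT_BAND_AMPLITUDES"]

CONDITIONS = ("relax", "stress")

# Oscillator centre frequencies are drawn uniformly inside these ranges (Hz);
# dyadic band edges at fs=128 with a margin so the tone stays inside its band.
BAND_FREQ_RANGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.5),
    "theta": (4.5, 7.5),
    "alpha": (8.5, 15.5),
    "beta": (16.5, 31.0),
    "gamma": (33.0, 45.0),
}

DEFAULT_BAND_AMPLITUDES: dict[str, dict[str, float]] = {
    "relax": {"delta": 0.5, "theta": 0.5, "alpha": 2.0, "beta": 0.5, "gamma": 0.5},
    "stress": {"delta": 0.5, "theta": 0.5, "alpha": 0.8, "beta": 1.8, "gamma": 0.5},
}

# ratings are drawn from the low/high burden bands of the 1-9 scale
_RATING_CHOICES = {"relax": (1, 2, 3), "stress": (7, 8, 9)}


@dataclass
class SimConfig:
    n_subjects: int = 48
    duration: float = 150.0
    fs: float = 128.0
    n_channels: int = 14
    band_amplitudes: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_BAND_AMPLITUDES)
    )
    pink_noise_scale: float = 0.3
    white_noise_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        for cond in CONDITIONS:
            if cond not in self.band_amplitudes:
                raise ValueError(f"band_amplitudes missing condition {cond!r}")
            for band, amp in self.band_amplitudes[cond].items():
                if amp < 0:
                    raise ValueError(f"negative amplitude for {cond}/{band}: {amp}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _recording_rng(config: SimConfig, subject: int, condition: str) -> np.random.Generator:
    cond_code = CONDITIONS.index(condition)
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject, cond_code]))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n)
    std = pink.std()
    return pink / std if std > 0 else pink


def generate_recording(config: SimConfig, subject: int, condition: str) -> Recording:
    """Simulate one subject/condition recording.

    Deterministic given (config.seed, subject, condition): every channel draws
    its oscillator frequencies, phases and noise from a sub-generator keyed on
    that triple.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if not 1 <= subject <= config.n_subjects:
        raise ValueError(f"subject {subject} outside [1, {config.n_subjects}]")

    rng = _recording_rng(config, subject, condition)
    n = config.n_samples
    t = np.arange(n) / config.fs
    amplitudes = config.band_amplitudes[condition]
    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        sig = np.zeros(n)
        for band, (f_lo, f_hi) in BAND_FREQ_RANGES.items():
            amp = amplitudes.get(band, 0.0)
            freq = rng.uniform(f_lo, f_hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            if amp > 0:
                sig += amp * np.sin(2.0 * np.pi * freq * t + phase)
        if config.pink_noise_scale > 0:
            sig = sig + config.pink_noise_scale * _pink_noise(rng, n)
        else:
            rng.standard_normal(n)  # keep the stream position condition-independent
        if config.white_noise_scale > 0:
            sig = sig + config.white_noise_scale * rng.standard_normal(n)
        else:
            rng.standard_normal(n)
        data[ch] = sig

    rating = int(rng.choice(_RATING_CHOICES[condition]))
    names = (
        list(CHANNEL_NAMES)
        if config.n_channels == len(CHANNEL_NAMES)
        else [f"ch{i + 1}" for i in range(config.n_channels)]
    )
    return Recording(
        subject_id=subject,
        condition=condition_to_suffix(condition),
        rating=rating,
        fs=config.fs,
        channel_names=names,
        data=data,
    )


def generate_dataset(config: SimConfig, out_dir: str | Path) -> list[dict]:
    """Write n_subjects x 2 STEW-dialect recordings plus a ratings file.

    Returns a manifest of dicts with keys path/subject/condition/rating.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    rating_lines: list[str] = []
    for subject in range(1, config.n_subjects + 1):
        for condition in CONDITIONS:
            rec = generate_recording(config, subject, condition)
            fname = recording_filename(subject, condition)
            path = out_dir / fname
            np.savetxt(path, rec.data.T, fmt="%.6f", delimiter=" ")
            manifest.append(
                {
                    "path": str(path),
                    "subject": subject,
                    "condition": condition_to_suffix(condition),
                    "rating": rec.rating,
                }
            )
            rating_lines.append(f"{subject},{condition_to_suffix(condition)},{rec.rating}")
    (out_dir / "ratings.txt").write_text("\n".join(rating_lines) + "\n")
    return manifest
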