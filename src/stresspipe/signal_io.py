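"""Reading and validating STEW-dialect EEG text files.

The dialect: whitespace-delimited plain text, no header, one row per time
sample, one numeric column per electrode (14 by default, ordered as
``CHANNEL_NAMES``); filenames ``sub{NN}_{lo|hi}.txt`` encode subject and
condition; a companion ``ratings.txt`` holds ``subject,condition,rating``
lines with 1-9 workload ratings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "CHANNEL_NAMES",
    "read_recording",
    "read_ratings",
    "rating_to_burden",
    "to_binary_label",
    "recording_filename",
    "condition_to_suffix",
    "ChannelCountError",
    "MalformedNumberError",
    "EmptyRecordingError",
    "MissingFieldError",
]

# Emulated electrode column order (10-20 system names); a documented
# convention of this package, not a claim about the upstream dataset.
CHANNEL_NAMES = [
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
]

_FILENAME_RE = re.compile(r"^sub(?P<subject>\d+)_(?P<condition>lo|hi)\.txt$")

_CONDITION_SUFFIX = {"relax": "lo", "stress": "hi", "lo": "lo", "hi": "hi"}


class ChannelCountError(ValueError):
    """File has a different number of columns than expected."""


class MalformedNumberError(ValueError):
    """File contains a token that does not parse as a number."""


class EmptyRecordingError(ValueError):
    """File contains no data rows."""


class MissingFieldError(ValueError):
    """A labelling policy needs a field the recording does not carry."""


@dataclass
class Recording:
    """One subject/condition multichannel EEG segment.

    ``data`` is (channels, samples); ``condition`` is "lo" (rest) or "hi"
    (task) when known; ``rating`` is the 1-9 workload rating when known.
    """

    data: np.ndarray
    fs: float = 128.0
    channel_names: list[str] | None = None
    subject_id: int | None = None
    condition: str | None = None
    rating: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got {self.data.shape}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.rating is not None and not 1 <= self.rating <= 9:
            raise ValueError(f"rating must be in 1..9, got {self.rating}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def condition_to_suffix(condition: str) -> str:
    try:
        return _CONDITION_SUFFIX[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None


def recording_filename(subject: int, condition: str) -> str:
    return f"sub{subject:02d}_{condition_to_suffix(condition)}.txt"


def parse_recording_filename(name: str) -> tuple[int | None, str | None]:
    m = _FILENAME_RE.match(Path(name).name)
    if not m:
        return None, None
    return int(m.group("subject")), m.group("condition")


def read_recording(
    path: str | Path,
    fs: float = 128.0,
    expected_channels: int = 14,
    rating: int | None = None,
) -> Recording:
    """Parse one STEW-dialect file into a Recording.

    Subject and condition are taken from the filename when it matches the
    dialect grammar, else left absent.  Blank lines and trailing whitespace
    are tolerated; scientific notation is accepted.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != expected_channels:
                raise ChannelCountError(
                    f"{path.name}:{lineno}: expected {expected_channels} columns, "
                    f"got {len(tokens)}"
                )
            try:
                rows.append([float(tok) for tok in tokens])
            except ValueError as exc:
                raise MalformedNumberError(f"{path.name}:{lineno}: {exc}") from None
    if not rows:
        raise EmptyRecordingError(f"{path.name}: no data rows")
    subject, condition = parse_recording_filename(path.name)
    names = (
        list(CHANNEL_NAMES)
        if expected_channels == len(CHANNEL_NAMES)
        else [f"ch{i + 1}" for i in range(expected_channels)]
    )
    return Recording(
        data=np.asarray(rows).T,
        fs=fs,
        channel_names=names,
        subject_id=subject,
        condition=condition,
        rating=rating,
    )


def read_ratings(path: str | Path) -> dict[tuple[int, str], int]:
    """Parse ratings.txt lines ``subject,condition,rating`` into a lookup."""
    out: dict[tuple[int, str], int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"ratings:{lineno}: expected 'subject,condition,rating'")
        out[(int(parts[0]), parts[1].strip())] = int(parts[2])
    return out


def rating_to_burden(rating: int) -> str:
    """Map a 1-9 workload rating to its burden band: low / moderate / high."""
    if not isinstance(rating, (int, np.integer)) or isinstance(rating, bool):
        raise TypeError(f"rating must be an integer, got {rating!r}")
    if not 1 <= rating <= 9:
        raise ValueError(f"rating must be in 1..9, got {rating}")
    if rating <= 3:
        return "low"
    if rating <= 6:
        return "moderate"
    return "high"


def to_binary_label(
    recording: Recording, policy: str = "by_condition", threshold: int = 7
) -> int:
    """Binary stress label: 0 = relaxed, 1 = stressed.

    ``by_condition``: rest ("lo") -> 0, task ("hi") -> 1.
    ``by_rating``: rating >= threshold -> 1, else 0.
    """
    if policy == "by_condition":
        if recording.condition is None:
            raise MissingFieldError("by_condition policy needs a condition")
        return {"lo": 0, "hi": 1}[recording.condition]
    if policy == "by_rating":
        if recording.rating is None:
            raise MissingFieldError("by_rating policy needs a rating")
        return int(recording.rating >= threshold)
    raise ValueError(f"unknown labelling policy {policy!r}")
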