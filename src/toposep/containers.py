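"""In-memory containers for continuous recordings, epochs, and evoked data.

All voltages are in microvolts, all times in milliseconds relative to
stimulus onset, and channel order always follows the attached montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .montage import Montage

__all__ = ["ContinuousRecording", "EpochSet", "EvokedMapSeries"]


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG with stimulus events.

    ``data`` is channels x samples in microvolts; ``events`` is a list of
    ``(sample_index, event_code)`` with 0-based sample indices.
    """

    data: np.ndarray
    sampling_rate: float
    events: list[tuple[int, str]]
    montage: Montage
    reference_label: Optional[str] = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{len(self.montage)}"
            )
        n = self.data.shape[1]
        for s, _ in self.events:
            if not (0 <= s < n):
                raise ValueError(f"event sample {s} outside recording (0..{n - 1})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _check_time_axis(time: np.ndarray) -> None:
    if np.any(np.diff(time) <= 0):
        raise ValueError("time axis must be strictly increasing")
    if not (time[0] <= 0.0 <= time[-1]):
        raise ValueError("time axis must contain stimulus onset (0 ms)")


@dataclass
class EpochSet:
    """Stack of stimulus-locked segments for one subject x condition.

    ``data`` is trials x channels x samples (microvolts).  ``kept_mask``
    flags trials that survived artifact rejection; rejected trials stay in
    the array so rejection is reversible.
    """

    data: np.ndarray
    time: np.ndarray  # ms relative to stimulus onset
    montage: Montage
    subject_id: str = ""
    condition: tuple[str, str] = ("", "")  # (frequency_label, location_label)
    kept_mask: Optional[np.ndarray] = None
    baseline_corrected: bool = False
    reference: str = "recording"  # {"recording", "average"}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        self.time = np.asarray(self.time, dtype=float)
        _check_time_axis(self.time)
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel count does not match montage")
        if self.data.shape[2] != self.time.size:
            raise ValueError("sample count does not match time axis")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.size != self.data.shape[0]:
                raise ValueError("kept_mask length must equal trial count")
        self.condition = tuple(self.condition)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.time)))

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept_mask]

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)


@dataclass
class EvokedMapSeries:
    """Trial-averaged channels x time series (an ERP) with provenance flags."""

    data: np.ndarray
    time: np.ndarray
    montage: Montage
    n_trials: int = 1
    reference: str = "recording"
    baseline_corrected: bool = False
    subject_id: str = ""
    condition: tuple[str, str] = ("", "")

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        _check_time_axis(self.time)
        if self.data.shape[0] != len(self.montage):
            raise ValueError("channel count does not match montage")
        if self.data.shape[1] != self.time.size:
            raise ValueError("sample count does not match time axis")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.reference == "average":
            col_means = self.data.mean(axis=0)
            if np.max(np.abs(col_means)) > 1e-6:
                raise ValueError(
                    "reference='average' but channel means are not zero"
                )
        self.condition = tuple(self.condition)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.time - t_ms)))

    def window_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        return (self.time >= start_ms) & (self.time <= end_ms)

    def copy_with(self, **kw) -> "EvokedMapSeries":
        return replace(self, **kw)
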