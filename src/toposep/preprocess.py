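"""Preprocessing of continuous and epoched EEG.

Covers the standard evoked-potential chain: zero-phase Butterworth
band-pass plus mains notch, average-reference transform, spline-derived
virtual channels, bipolar difference traces, stimulus-locked segmentation,
amplitude-threshold artifact rejection with manual override, baseline
correction, and (split-half) trial averaging.

All filter operations are linear and zero-phase, so they commute with
trial averaging; the pipeline relies on that property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochSet, EvokedMapSeries
from .montage import to_cartesian
from .spline import SplineInterpolator

__all__ = [
    "FilterSpec",
    "bandpass_notch",
    "to_average_reference",
    "add_virtual_channels",
    "difference_channel",
    "segment",
    "reject_artifacts",
    "baseline_correct",
    "average",
    "split_half_averages",
    "DEFAULT_VIRTUAL_CHANNELS",
]

logger = logging.getLogger(__name__)

#: Virtual midline channels between Cz/CPz and Fz/FCz, in this package's
#: spherical convention (phi = +90 anterior, -90 posterior).
DEFAULT_VIRTUAL_CHANNELS = (("CzCPz", 11.0, -90.0), ("FzFCz", 34.0, 90.0))


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + optional notch specification.

    ``slope_db_per_oct`` maps to the analog Butterworth order at 6 dB per
    octave per pole (24 dB/oct -> order 4); the zero-phase forward-backward
    pass doubles the effective attenuation.
    """

    band: tuple[float, float] = (0.5, 70.0)
    slope_db_per_oct: float = 24.0
    notch_hz: Optional[float] = 50.0
    zero_phase: bool = True

    @property
    def order(self) -> int:
        order = int(round(self.slope_db_per_oct / 6.0))
        if order < 1:
            raise ValueError("slope must be at least 6 dB/oct")
        return order

    def validate(self, sampling_rate: float) -> None:
        lo, hi = self.band
        nyq = sampling_rate / 2.0
        if not (0 < lo < hi < nyq):
            raise ValueError(
                f"band {self.band} invalid for sampling rate {sampling_rate} "
                f"(need 0 < low < high < {nyq})"
            )
        if self.notch_hz is not None and not (0 < self.notch_hz < nyq):
            raise ValueError(f"notch frequency {self.notch_hz} exceeds Nyquist")


def _filtfilt(sos: np.ndarray, x: np.ndarray, fs: float, low_hz: float) -> np.ndarray:
    # reflect padding, long enough to settle the slow high-pass edge
    padlen = min(x.shape[-1] - 1, int(3 * fs / low_hz))
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def bandpass_notch(rec: ContinuousRecording, spec: FilterSpec = FilterSpec()) -> ContinuousRecording:
    """Apply the zero-phase Butterworth band-pass (and notch) per channel."""
    spec.validate(rec.sampling_rate)
    lo, hi = spec.band
    sos = signal.butter(spec.order, [lo, hi], btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    data = _filtfilt(sos, rec.data, rec.sampling_rate, lo)
    if spec.notch_hz is not None:
        # narrow 2nd-order band-stop, +-2 Hz about the mains frequency
        sos_n = signal.butter(2, [spec.notch_hz - 2.0, spec.notch_hz + 2.0],
                              btype="bandstop", fs=rec.sampling_rate, output="sos")
        data = _filtfilt(sos_n, data, rec.sampling_rate, lo)
    return ContinuousRecording(
        data=data, sampling_rate=rec.sampling_rate, events=list(rec.events),
        montage=rec.montage, reference_label=rec.reference_label,
    )


def to_average_reference(x: Union[EpochSet, EvokedMapSeries]):
    """Subtract the per-sample channel mean; sets ``reference='average'``."""
    if len(x.montage) < 2:
        raise ValueError("average reference undefined for a single channel")
    data = x.data - x.data.mean(axis=-2, keepdims=True)
    return x.copy_with(data=data, reference="average")


def add_virtual_channels(x: Union[EpochSet, EvokedMapSeries],
                         defs: Sequence[tuple[str, float, float]] = DEFAULT_VIRTUAL_CHANNELS,
                         order_m: int = 4, degree_n: int = 10,
                         lambda_reg: float = 0.0):
    """Append spline-interpolated channels at ``(label, theta, phi)`` sites.

    The new montage carries the added positions; existing channel data is
    untouched.  Note an average-referenced input generally loses the exact
    zero-mean property once channels are appended, so the reference flag is
    preserved only for non-average references.
    """
    targets = to_cartesian([d[1] for d in defs], [d[2] for d in defs])
    interp = SplineInterpolator(x.montage.cartesian, targets,
                                order_m=order_m, degree_n=degree_n,
                                lambda_reg=lambda_reg)
    new_montage = x.montage.extended(defs)
    moved = np.moveaxis(x.data, -2, -1)  # ... x samples x channels
    flat = moved.reshape(-1, moved.shape[-1])
    virt = interp(flat).reshape(moved.shape[:-1] + (len(defs),))
    virt = np.moveaxis(virt, -1, -2)
    data = np.concatenate([x.data, virt], axis=-2)
    ref = "recording" if x.reference == "average" else x.reference
    return x.copy_with(data=data, montage=new_montage, reference=ref)


def difference_channel(x: Union[EpochSet, EvokedMapSeries], a_label: str,
                       b_label: str) -> np.ndarray:
    """Bipolar derivation ``a - b`` per sample (e.g. Cz-Fz)."""
    ia, ib = x.montage.index(a_label), x.montage.index(b_label)
    return np.take(x.data, ia, axis=-2) - np.take(x.data, ib, axis=-2)


def reference_trace(x: EvokedMapSeries, label: str) -> np.ndarray:
    """Single-channel trace against the series' current reference.

    With an average-referenced series this is the Cz-AvgRef style trace.
    """
    return np.take(x.data, x.montage.index(label), axis=-2)


def segment(rec: ContinuousRecording, event_codes: Optional[Iterable[str]] = None,
            t_min_ms: float = -100.0, t_max_ms: float = 600.0,
            subject_id: str = "", condition: tuple[str, str] = ("", "")) -> EpochSet:
    """Cut stimulus-locked epochs around matching events.

    Events whose window would leave the recording are dropped (logged).
    """
    if not rec.events:
        raise ValueError("recording has no events to segment on")
    fs = rec.sampling_rate
    i_min = int(round(t_min_ms * fs / 1000.0))
    i_max = int(round(t_max_ms * fs / 1000.0))
    codes = None if event_codes is None else set(event_codes)
    epochs, dropped = [], 0
    for s, code in rec.events:
        if codes is not None and code not in codes:
            continue
        lo, hi = s + i_min, s + i_max
        if lo < 0 or hi >= rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, lo:hi + 1])
    if dropped:
        logger.info("segment: dropped %d event(s) with out-of-bounds windows", dropped)
    time = np.arange(i_min, i_max + 1) / fs * 1000.0
    data = (np.stack(epochs) if epochs
            else np.empty((0, rec.n_channels, time.size)))
    return EpochSet(data=data, time=time, montage=rec.montage,
                    subject_id=subject_id, condition=condition)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0,
                     keep: Iterable[int] = (), reject: Iterable[int] = ()) -> EpochSet:
    """Flag trials whose absolute amplitude exceeds the threshold anywhere.

    ``keep``/``reject`` are explicit trial-index overrides applied after the
    automatic threshold (the manual half of semiautomatic rejection).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    mask = ~(np.abs(epochs.data) > threshold_uv).any(axis=(1, 2))
    for i in keep:
        mask[i] = True
    for i in reject:
        mask[i] = False
    n_rej = int((~mask).sum())
    if n_rej:
        logger.info("reject_artifacts: %d of %d trials rejected", n_rej, epochs.n_trials)
    return epochs.copy_with(kept_mask=mask)


def baseline_correct(x: Union[EpochSet, EvokedMapSeries],
                     window_ms: tuple[float, float] = (-53.0, -3.0)):
    """Subtract the per-channel mean over the pre-stimulus window."""
    lo, hi = window_ms
    sel = (x.time >= lo) & (x.time <= hi)
    if not sel.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    base = x.data[..., sel].mean(axis=-1, keepdims=True)
    return x.copy_with(data=x.data - base, baseline_corrected=True)


def average(epochs: EpochSet) -> EvokedMapSeries:
    """Arithmetic mean over kept trials."""
    kept = epochs.kept_data()
    if kept.shape[0] < 1:
        raise ValueError("no kept trials to average")
    return EvokedMapSeries(
        data=kept.mean(axis=0), time=epochs.time, montage=epochs.montage,
        n_trials=kept.shape[0], reference=epochs.reference,
        baseline_corrected=epochs.baseline_corrected,
        subject_id=epochs.subject_id, condition=epochs.condition,
    )


def split_half_averages(epochs: EpochSet) -> tuple[EvokedMapSeries, EvokedMapSeries]:
    """Averages of odd- and even-numbered kept trials (acquisition order).

    Ordinals are 1-based over kept trials, so the first kept trial belongs
    to the odd average.
    """
    kept = epochs.kept_data()
    if kept.shape[0] < 2:
        raise ValueError("need at least 2 kept trials for split-half averages")
    common = dict(time=epochs.time, montage=epochs.montage,
                  reference=epochs.reference,
                  baseline_corrected=epochs.baseline_corrected,
                  subject_id=epochs.subject_id, condition=epochs.condition)
    odd = kept[0::2]
    even = kept[1::2]
    return (
        EvokedMapSeries(data=odd.mean(axis=0), n_trials=odd.shape[0], **common),
        EvokedMapSeries(data=even.mean(axis=0), n_trials=even.shape[0], **common),
    )
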