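"""Automated SEP component marking and component time windows.

Marks P1/N1/P2 on a single derivation (e.g. Cz-Fz or Cz against average
reference) as the windowed extremum of each component, gates markers by
split-half waveform stability, and derives component time windows three
ways: group mean latency +- 2 SD, global-field-power minima bracketing each
GFP peak, and the narrower span between GFP inflection points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MarkerSet",
    "ComponentWindows",
    "DEFAULT_SEARCH_WINDOWS",
    "detect_markers",
    "stability",
    "responder_rate",
    "windows_mean2sd",
    "windows_from_gfp",
    "WindowDetectionError",
]

logger = logging.getLogger(__name__)

#: Default component search windows in ms (P1 positive, N1 negative,
#: P2 positive), covering the canonical component time frames.
DEFAULT_SEARCH_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (40.0, 90.0),
    "N1": (80.0, 170.0),
    "P2": (185.0, 380.0),
}

#: Extremum polarity per component name (+1 maximum, -1 minimum).
_POLARITY = {"P1": +1, "N1": -1, "P2": +1, "P40": +1, "N50": -1,
             "P65": +1, "N85": -1}


class WindowDetectionError(RuntimeError):
    """GFP-based window extraction could not find the expected peaks."""


@dataclass
class MarkerSet:
    """Per-recording component markers on one channel pair."""

    channel_pair: str
    latency_ms: dict[str, float] = field(default_factory=dict)
    amplitude_uv: dict[str, float] = field(default_factory=dict)
    stable: bool = True
    stability_r: float = np.nan

    @property
    def peak_to_peak(self) -> dict[str, float]:
        out = {}
        a = self.amplitude_uv
        if "P1" in a and "N1" in a:
            out["P1N1"] = a["P1"] - a["N1"]
        if "P2" in a and "N1" in a:
            out["P2N1"] = a["P2"] - a["N1"]
        return out

    @property
    def complete(self) -> bool:
        return all(np.isfinite(v) for v in self.latency_ms.values()) and bool(self.latency_ms)


@dataclass
class ComponentWindows:
    """(start, end) window in ms per component, plus the method used."""

    windows: dict[str, tuple[float, float]]
    method: str  # {"mean2sd", "gfp_minima", "gfp_inflection", "fixed"}

    def __post_init__(self):
        for name, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ValueError(f"window for {name} inverted: ({lo}, {hi})")


def detect_markers(trace: np.ndarray, time_ms: np.ndarray,
                   search_windows: Mapping[str, tuple[float, float]] = DEFAULT_SEARCH_WINDOWS,
                   channel_pair: str = "") -> MarkerSet:
    """Mark each component at its windowed extremum.

    Positive components take the maximum, negative the minimum, inside the
    component's search window; plateau ties resolve to the earliest sample.
    The polarity is read off the component name (leading P/N).
    """
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    ms = MarkerSet(channel_pair=channel_pair)
    for name, (lo, hi) in search_windows.items():
        sel = np.flatnonzero((time_ms >= lo) & (time_ms <= hi))
        if sel.size == 0:
            raise ValueError(f"search window {name}=({lo}, {hi}) outside trace")
        pol = _POLARITY.get(name, +1 if name.upper().startswith("P") else -1)
        seg = trace[sel]
        i = int(np.argmax(seg) if pol > 0 else np.argmin(seg))
        ms.latency_ms[name] = float(time_ms[sel[i]])
        ms.amplitude_uv[name] = float(seg[i])
    return ms


def stability(odd: np.ndarray, even: np.ndarray,
              time_ms: Optional[np.ndarray] = None,
              window_ms: Optional[tuple[float, float]] = None,
              r_min: float = 0.5) -> tuple[float, bool]:
    """Split-half waveform stability: Pearson r of odd vs even averages.

    The recording counts as stable when r >= ``r_min`` over the window.
    This is the numeric stand-in for the visual "overlapping waveform"
    criterion; the threshold is a package default, not an established norm.
    """
    odd = np.asarray(odd, dtype=float)
    even = np.asarray(even, dtype=float)
    if odd.shape != even.shape:
        raise ValueError("odd/even traces must share the time axis")
    if window_ms is not None:
        if time_ms is None:
            raise ValueError("window_ms requires the time axis")
        sel = (np.asarray(time_ms) >= window_ms[0]) & (np.asarray(time_ms) <= window_ms[1])
        odd, even = odd[sel], even[sel]
    if odd.size < 3:
        raise ValueError("too few samples for a stability correlation")
    r = float(np.corrcoef(odd, even)[0, 1])
    return r, bool(r >= r_min)


def responder_rate(marker_sets: Sequence[MarkerSet]) -> float:
    """Percentage of recordings with a stable SEP and all components marked."""
    if len(marker_sets) == 0:
        raise ValueError("responder rate undefined for an empty collection")
    good = sum(1 for m in marker_sets if m.stable and m.complete)
    return 100.0 * good / len(marker_sets)


def windows_mean2sd(latencies_ms: Sequence[float],
                    sample_interval_ms: float = 1.0) -> tuple[float, float]:
    """Group window: mean latency +- 2 sample SDs, snapped outward to the grid.

    A degenerate (zero-SD) window is widened to one sample on either side,
    with a warning.
    """
    lat = np.asarray(latencies_ms, dtype=float)
    lat = lat[np.isfinite(lat)]
    if lat.size < 2:
        raise ValueError("need at least 2 latencies")
    mean = lat.mean()
    sd = lat.std(ddof=1)
    lo = np.floor((mean - 2 * sd) / sample_interval_ms) * sample_interval_ms
    hi = np.ceil((mean + 2 * sd) / sample_interval_ms) * sample_interval_ms
    if hi <= lo:
        logger.warning("degenerate +-2SD window at %.1f ms; widening by one sample", mean)
        lo, hi = lo - sample_interval_ms, hi + sample_interval_ms
    return float(lo), float(hi)


def _smooth(curve: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return np.asarray(curve, dtype=float)
    from scipy.ndimage import uniform_filter1d

    width_samples |= 1  # force odd so the average is centered
    return uniform_filter1d(np.asarray(curve, dtype=float), width_samples,
                            mode="reflect")


def windows_from_gfp(gfp: np.ndarray, time_ms: np.ndarray, mode: str = "minima",
                     smooth_ms: float = 5.0, search_start_ms: float = 50.0,
                     n_components: int = 2,
                     component_names: Sequence[str] = ("N1", "P2")) -> ComponentWindows:
    """Component windows from the GFP curve.

    ``minima`` mode brackets each post-stimulus GFP peak by the nearest
    local minima; ``inflection`` mode uses the zero crossings of the second
    derivative flanking each peak (always nested inside the minima window
    for a unimodal bump).  Peaks are taken in temporal order from
    ``search_start_ms``; with the defaults the first is N1 and the second
    P2 (no separate GFP peak is assumed for P1).
    """
    from scipy.signal import find_peaks

    gfp = np.asarray(gfp, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    dt = float(np.median(np.diff(time_ms)))
    width = max(1, int(round(smooth_ms / dt)))
    sm = _smooth(gfp, width)

    searchable = np.flatnonzero(time_ms >= search_start_ms)
    peaks, props = find_peaks(sm[searchable], prominence=0.05 * sm.max())
    peaks = searchable[peaks]
    if peaks.size < n_components:
        found = ", ".join(f"{time_ms[p]:.0f} ms" for p in peaks) or "none"
        raise WindowDetectionError(
            f"expected {n_components} GFP peaks after {search_start_ms} ms, "
            f"found {peaks.size} ({found})"
        )
    peaks = peaks[:n_components]

    windows: dict[str, tuple[float, float]] = {}
    if mode == "minima":
        for name, p in zip(component_names, peaks):
            i = p
            while i > 0 and sm[i - 1] < sm[i]:
                i -= 1
            j = p
            while j < sm.size - 1 and sm[j + 1] < sm[j]:
                j += 1
            windows[name] = (float(time_ms[i]), float(time_ms[j]))
    elif mode == "inflection":
        d2 = np.gradient(np.gradient(sm, time_ms), time_ms)
        for name, p in zip(component_names, peaks):
            lo = _zero_crossing(d2, time_ms, p, direction=-1)
            hi = _zero_crossing(d2, time_ms, p, direction=+1)
            windows[name] = (lo, hi)
    else:
        raise ValueError(f"unknown mode {mode!r} (use 'minima' or 'inflection')")
    return ComponentWindows(windows=windows, method=f"gfp_{mode}")


def _zero_crossing(d2: np.ndarray, time_ms: np.ndarray, peak: int,
                   direction: int) -> float:
    """Nearest sign change of the second derivative on one side of a peak,
    linearly interpolated between samples."""
    i = peak
    while 0 < i < d2.size - 1:
        j = i + direction
        if d2[i] <= 0.0 <= d2[j] or d2[j] <= 0.0 <= d2[i]:
            if d2[j] != d2[i]:
                frac = abs(d2[i]) / abs(d2[j] - d2[i])
            else:
                frac = 0.5
            return float(time_ms[i] + frac * (time_ms[j] - time_ms[i]))
        i = j
    return float(time_ms[i])  # fall back to the curve boundary
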