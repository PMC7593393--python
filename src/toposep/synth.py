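"""Synthetic stimulus-locked SEP generator with known ground truth.

Emulates the statistical structure of multichannel sensory evoked
potentials from repeated lower-urinary-tract stimulation: a weak central
P1, a centro-parietal N1 negativity with frontal counter-positivity, a
central P2 positivity with surrounding negativity, and a slow pre-stimulus
CNV drift that is strongest for the slowest stimulation frequency.
Component map strength decreases with stimulation frequency, subjects vary
in amplitude (lognormal) and latency (Gaussian jitter), and trial noise is
spatially and temporally smoothed Gaussian noise.

Spatial patterns are built from von-Mises-like lobes on the unit sphere,
``exp(kappa (cos(gamma) - 1))``, centered on montage labels and
mean-centered across channels so generated maps are average-reference
compatible.  Temporal pulses are Gaussian.  Everything is deterministic
given the seed, and the programmed truth is returned (and serialized)
next to the data so downstream tests never have to re-infer it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .containers import EpochSet
from .montage import Montage, standard_montage

__all__ = [
    "ComponentSpec",
    "GeneratorConfig",
    "make_component_defaults",
    "component_pattern",
    "simulate",
    "null_dataset",
    "smoothed_noise",
    "make_microstate_dataset",
    "reduced_montage",
]

#: Condition labels for the three stimulation frequencies (Hz).
FREQ_LABELS = ("0.5Hz", "1.1Hz", "1.6Hz")


def _kappa_from_fwhm(fwhm_deg: float) -> float:
    """Concentration of exp(kappa(cos g - 1)) with the given angular FWHM."""
    half = np.deg2rad(fwhm_deg / 2.0)
    return float(np.log(2.0) / (1.0 - np.cos(half)))


@dataclass(frozen=True)
class ComponentSpec:
    """One SEP component: spatial lobes, temporal pulse, variability."""

    name: str
    lobes: tuple[tuple[str, float, float], ...]  # (center label, FWHM deg, gain)
    latency_ms: float
    width_ms: float                # FWHM of the Gaussian pulse
    amplitude_uv: float            # peak channel amplitude of the pattern
    freq_multipliers: dict = field(default_factory=lambda: dict(
        zip(FREQ_LABELS, (1.0, 0.8, 0.6))))
    amp_sigma: float = 0.3         # lognormal sigma of subject amplitude
    latency_jitter_ms: float = 5.0


def make_component_defaults() -> list[ComponentSpec]:
    """Default P1 / N1 / P2 / CNV components.

    N1: centro-parietal negativity with a frontal positivity, 115 ms.
    P2: central positivity inside a circular negative surround, 255 ms.
    P1: weak central positivity, 60 ms.  CNV: slow central negativity
    ramping up before the stimulus, largest at the slowest frequency.
    Frequency multipliers decrease strictly from 0.5 to 1.6 Hz.
    """
    return [
        ComponentSpec(
            name="P1",
            lobes=(("Cz", 45.0, 1.0),),
            latency_ms=60.0, width_ms=22.0, amplitude_uv=1.2,
            latency_jitter_ms=3.0,
        ),
        ComponentSpec(
            name="N1",
            lobes=(("CPz", 45.0, -1.0), ("Fz", 55.0, 0.55)),
            latency_ms=115.0, width_ms=30.0, amplitude_uv=5.0,
            latency_jitter_ms=5.0,
        ),
        ComponentSpec(
            name="P2",
            lobes=(("Cz", 50.0, 1.0), ("Cz", 70.0, -0.35)),
            latency_ms=255.0, width_ms=55.0, amplitude_uv=4.0,
            latency_jitter_ms=8.0,
        ),
        ComponentSpec(
            name="CNV",
            lobes=(("Cz", 70.0, -1.0),),
            latency_ms=0.0, width_ms=0.0, amplitude_uv=2.0,
            freq_multipliers=dict(zip(FREQ_LABELS, (1.0, 0.4, 0.15))),
            amp_sigma=0.3, latency_jitter_ms=0.0,
        ),
    ]


def component_pattern(comp: ComponentSpec, montage: Montage) -> np.ndarray:
    """Per-channel spatial weights: summed lobes, mean-centered, peak |.| = 1."""
    pat = np.zeros(len(montage))
    for center, fwhm, gain in comp.lobes:
        c = montage.cartesian[montage.index(center)]
        cosg = montage.cartesian @ c
        pat += gain * np.exp(_kappa_from_fwhm(fwhm) * (cosg - 1.0))
    pat -= pat.mean()
    peak = np.max(np.abs(pat))
    if peak <= 0:
        raise ValueError(f"component {comp.name} has a flat pattern")
    return pat / peak


@dataclass(frozen=True)
class GeneratorConfig:
    """Study layout and noise model for the generator.

    ``n_subjects_per_group`` subjects are simulated for each stimulation
    location (a between-subject factor); every subject contributes all
    frequency conditions (within-subject).  ``noise_sd_uv`` is the
    per-trial, per-channel noise SD after smoothing.
    """

    montage: Optional[Montage] = None            # default: standard 64-channel
    n_subjects_per_group: int = 20
    freq_labels: tuple[str, ...] = FREQ_LABELS
    locations: tuple[str, ...] = ("BD",)
    n_trials: int = 100
    noise_sd_uv: float = 1.0
    spatial_smooth_fwhm_deg: Optional[float] = 60.0   # None = white across channels
    temporal_smooth_sigma_ms: float = 20.0
    sampling_rate: float = 1000.0
    window_ms: tuple[float, float] = (-100.0, 600.0)
    seed: int = 0

    def resolve_montage(self) -> Montage:
        return self.montage if self.montage is not None else standard_montage()

    def time_axis(self) -> np.ndarray:
        fs = self.sampling_rate
        i0 = int(round(self.window_ms[0] * fs / 1000.0))
        i1 = int(round(self.window_ms[1] * fs / 1000.0))
        return np.arange(i0, i1 + 1) / fs * 1000.0


def reduced_montage(n_channels: int = 20) -> Montage:
    """Evenly thinned subset of the standard 64-channel montage.

    Always keeps the midline anchors used by the default components
    (Cz, CPz, Fz, Pz, Oz); other channels are picked evenly across the cap.
    """
    full = standard_montage()
    keep = [l for l in ("Cz", "CPz", "Fz", "Pz", "Oz") if l in full.labels]
    others = [l for l in full.labels if l not in keep]
    need = n_channels - len(keep)
    if need < 0 or need > len(others):
        raise ValueError(f"n_channels must be in {len(keep)}..{len(full)}")
    idx = np.unique(np.linspace(0, len(others) - 1, need).round().astype(int))
    chosen = set(keep) | {others[i] for i in idx}
    labels = [l for l in full.labels if l in chosen]
    return full.subset(labels)


def _resolve_lobe_centers(comp: ComponentSpec, montage: Montage) -> ComponentSpec:
    """Map lobe centers to the nearest montage channel when absent."""
    full = standard_montage()
    new_lobes = []
    for center, fwhm, gain in comp.lobes:
        if center in montage.labels:
            new_lobes.append((center, fwhm, gain))
        else:
            if center not in full.labels:
                raise KeyError(
                    f"lobe center {center!r} is in neither the montage nor "
                    "the standard 64-channel layout")
            target = full.cartesian[full.index(center)]
            i = int(np.argmax(montage.cartesian @ target))
            new_lobes.append((montage.labels[i], fwhm, gain))
    return replace(comp, lobes=tuple(new_lobes))


def smoothed_noise(rng: np.random.Generator, shape: tuple,
                   dt_ms: float, sigma_ms: float = 20.0,
                   spatial_weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Gaussian noise smoothed over time (and optionally channels).

    The last axis is time.  Both smoothing kernels are L2-normalized so the
    per-sample SD of the output stays 1 for unit white input.
    """
    from scipy.ndimage import convolve1d

    x = rng.standard_normal(shape)
    if spatial_weights is not None:
        x = np.moveaxis(np.tensordot(spatial_weights, np.moveaxis(x, -2, 0),
                                     axes=(1, 0)), 0, -2)
    if sigma_ms > 0:
        half = max(1, int(round(4 * sigma_ms / dt_ms)))
        t = np.arange(-half, half + 1) * dt_ms
        k = np.exp(-0.5 * (t / sigma_ms) ** 2)
        k /= np.linalg.norm(k)
        x = convolve1d(x, k, axis=-1, mode="reflect")
    return x


def _spatial_kernel(montage: Montage, fwhm_deg: float) -> np.ndarray:
    """Row-L2-normalized channel-smoothing matrix (variance-preserving)."""
    kappa = _kappa_from_fwhm(fwhm_deg)
    W = np.exp(kappa * (montage.cartesian @ montage.cartesian.T - 1.0))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    return W


def _cnv_time_course(time_ms: np.ndarray, decay_tau_ms: float = 200.0) -> np.ndarray:
    """Linear ramp over the pre-stimulus span, exponential decay after."""
    t0 = time_ms[0]
    tc = np.where(time_ms < 0,
                  (time_ms - t0) / (0.0 - t0) if t0 < 0 else 1.0,
                  np.exp(-np.maximum(time_ms, 0.0) / decay_tau_ms))
    return tc


def noise_free_evoked(config: GeneratorConfig,
                      components: Optional[Sequence[ComponentSpec]] = None,
                      freq_label: Optional[str] = None,
                      subject_amp: Optional[dict] = None,
                      subject_lat: Optional[dict] = None) -> np.ndarray:
    """Programmed (noise-free) evoked signal, channels x time, one condition."""
    montage = config.resolve_montage()
    time = config.time_axis()
    comps = components if components is not None else make_component_defaults()
    freq = freq_label if freq_label is not None else config.freq_labels[0]
    out = np.zeros((len(montage), time.size))
    for comp in comps:
        comp = _resolve_lobe_centers(comp, montage)
        pat = component_pattern(comp, montage)
        mult = comp.freq_multipliers.get(freq, 1.0)
        amp = comp.amplitude_uv * mult * (subject_amp or {}).get(comp.name, 1.0)
        if comp.name == "CNV":
            tc = _cnv_time_course(time)
        else:
            lat = comp.latency_ms + (subject_lat or {}).get(comp.name, 0.0)
            sigma = comp.width_ms / 2.355
            tc = np.exp(-0.5 * ((time - lat) / sigma) ** 2)
        out += amp * pat[:, None] * tc[None, :]
    return out


def simulate(config: GeneratorConfig,
             components: Optional[Sequence[ComponentSpec]] = None
             ) -> tuple[dict, dict]:
    """Simulate stimulus-locked epochs for the whole study layout.

    Returns ``(epoch_sets, truth)``: ``epoch_sets`` maps
    ``(subject_id, freq_label, location)`` to an EpochSet; ``truth``
    records per-subject amplitude factors and latency offsets plus the
    programmed component table.
    """
    montage = config.resolve_montage()
    time = config.time_axis()
    dt = 1000.0 / config.sampling_rate
    comps = list(components) if components is not None else make_component_defaults()
    comps = [_resolve_lobe_centers(c, montage) for c in comps]
    rng = np.random.default_rng(config.seed)
    W = (None if config.spatial_smooth_fwhm_deg is None
         else _spatial_kernel(montage, config.spatial_smooth_fwhm_deg))

    truth: dict = {
        "components": [
            {"name": c.name, "latency_ms": c.latency_ms,
             "amplitude_uv": c.amplitude_uv,
             "freq_multipliers": dict(c.freq_multipliers)} for c in comps
        ],
        "subjects": {},
        "seed": config.seed,
    }
    epoch_sets: dict = {}
    for loc in config.locations:
        for si in range(config.n_subjects_per_group):
            subject = f"{loc}-S{si:02d}"
            amp = {c.name: float(np.exp(rng.normal(0.0, c.amp_sigma)))
                   for c in comps}
            lat = {c.name: float(rng.normal(0.0, c.latency_jitter_ms))
                   for c in comps}
            truth["subjects"][subject] = {
                "location": loc, "amplitude_factor": amp, "latency_offset_ms": lat,
            }
            for freq in config.freq_labels:
                signal = noise_free_evoked(config, comps, freq, amp, lat)
                noise = config.noise_sd_uv * smoothed_noise(
                    rng, (config.n_trials, len(montage), time.size), dt,
                    config.temporal_smooth_sigma_ms, W)
                epoch_sets[(subject, freq, loc)] = EpochSet(
                    data=signal[None, :, :] + noise, time=time,
                    montage=montage, subject_id=subject,
                    condition=(freq, loc),
                )
    return epoch_sets, truth


def null_dataset(config: GeneratorConfig,
                 components: Optional[Sequence[ComponentSpec]] = None,
                 pure_noise: bool = False) -> tuple[dict, dict]:
    """Dataset in which condition labels carry no signal.

    Components are given identical multipliers across all frequency labels
    (the default calibration input for the factorial randomization tests);
    with ``pure_noise=True`` no signal at all is generated, which is the
    appropriate null for the topographic consistency test.
    """
    comps = components if components is not None else make_component_defaults()
    if pure_noise:
        comps = []
    else:
        comps = [replace(c, freq_multipliers={f: 1.0 for f in config.freq_labels})
                 for c in comps]
    return simulate(config, comps)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)


# ------------------------------------------------- microstate ground truth

def make_microstate_dataset(n_subjects: int = 20, n_states: int = 4,
                            samples_per_state: int = 24,
                            montage: Optional[Montage] = None,
                            noise_sd: float = 1.0, seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject map series with a known microstate sequence.

    Templates are orthonormalized smooth random maps (unit GFP); every
    subject shows the same state sequence (each state for
    ``samples_per_state`` samples) plus white channel noise of SD
    ``noise_sd`` relative to unit template GFP.

    Returns ``(subject_maps (S, T, K), templates (n_states, K),
    state_sequence (T,))``.
    """
    mon = montage if montage is not None else reduced_montage(20)
    K = len(mon)
    if n_states >= K:
        raise ValueError("need more channels than states")
    rng = np.random.default_rng(seed)
    W = _spatial_kernel(mon, 60.0)
    raw = (W @ rng.standard_normal((K, n_states))).T      # smooth random maps
    raw -= raw.mean(axis=1, keepdims=True)
    # Gram-Schmidt for well-separated templates
    q, _ = np.linalg.qr(raw.T)
    templates = q.T[:n_states]
    templates -= templates.mean(axis=1, keepdims=True)
    templates /= templates.std(axis=1, keepdims=True)
    seq = np.repeat(np.arange(n_states), samples_per_state)
    clean = templates[seq]                                 # (T, K)
    noise = rng.standard_normal((n_subjects,) + clean.shape) * noise_sd
    noise -= noise.mean(axis=2, keepdims=True)
    return clean[None, :, :] + noise, templates, seq
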