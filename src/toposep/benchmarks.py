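"""Simulation benchmarks that exercise the pipeline against generator truth.

Each function runs a self-contained simulation study on the synthetic SEP
generator and returns summary numbers: permutation-test calibration under
the null, power and specificity for the frequency effect on map strength,
marker and time-window recovery, microstate class-count recovery, and
spherical-spline accuracy.  They are used by the validation test suite and
by ``scripts/acceptance.py``; problem sizes are scaled for a single CPU
(reduced montages, coarse sampling, tens of trials) and stated in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import markers as tmark
from . import microstates as tms
from . import preprocess as prep
from . import synth
from . import topostats as ts
from .montage import standard_montage
from .spline import spline_interpolate

__all__ = [
    "calibration_rates",
    "frequency_effect_rates",
    "marker_recovery",
    "window_recovery",
    "microstate_recovery",
    "spline_errors",
    "gfp_identity_error",
]

N1_WINDOW_MS = (87.0, 147.0)  # group +-2SD N1 window on the Cz-Fz channel


def _evoked_maps(epoch_sets, freq_labels, location="BD", baseline=False):
    """Average-referenced evoked arrays (S, C, K, T) from an epoch dict."""
    subs = sorted({k[0] for k in epoch_sets})
    out = []
    for s in subs:
        per = []
        for f in freq_labels:
            ep = epoch_sets[(s, f, location)]
            if baseline:
                ep = prep.baseline_correct(ep)
            per.append(prep.to_average_reference(prep.average(ep)).data)
        out.append(np.stack(per))
    return np.stack(out)


def calibration_rates(n_sims: int = 500, n_perm: int = 999, n_subjects: int = 12,
                      n_channels: int = 20, seed: int = 0) -> dict:
    """Type-I error of TANOVA, GFP test and TCT at alpha = 0.05.

    TANOVA / GFP test run on ``null_dataset`` evokeds (identical signal
    under both condition labels, smoothed noise; the exchangeable unit is
    the within-subject condition label).  TCT runs on signal-free,
    channel-exchangeable white-noise maps, matching its channel-shuffle
    null.  Rejections are pooled over simulations and time points
    (50 samples per epoch).
    """
    mon = synth.reduced_montage(n_channels)
    root = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    rej = {"tanova": 0, "gfp_test": 0, "tct": 0}
    n_tests = 0
    for i in range(n_sims):
        cfg = synth.GeneratorConfig(
            montage=mon, n_subjects_per_group=n_subjects,
            freq_labels=("0.5Hz", "1.1Hz"), n_trials=1, noise_sd_uv=1.0,
            sampling_rate=70.0, seed=int((root[0] + i) % (2 ** 31)))
        eps, _ = synth.null_dataset(cfg)
        X = _evoked_maps(eps, cfg.freq_labels)
        d = ts.DesignSpec(within_levels=cfg.freq_labels, n_perm=n_perm,
                          seed=int((root[1] + i) % (2 ** 31)))
        rej["tanova"] += int((ts.tanova(X, d)["within"].p < 0.05).sum())
        rej["gfp_test"] += int((ts.gfp_test(X, d)["within"].p < 0.05).sum())

        cfg2 = replace(cfg, freq_labels=("0.5Hz",), spatial_smooth_fwhm_deg=None,
                       temporal_smooth_sigma_ms=0.0,
                       seed=int((root[2] + i) % (2 ** 31)))
        eps2, _ = synth.null_dataset(cfg2, pure_noise=True)
        X2 = _evoked_maps(eps2, cfg2.freq_labels)[:, 0]
        rej["tct"] += int((ts.tct(X2, n_perm=n_perm,
                                  seed=int((root[2] + i) % (2 ** 31))).p < 0.05).sum())
        n_tests += X.shape[-1]
    return {k: v / n_tests for k, v in rej.items()} | {"n_tests": n_tests}


def frequency_effect_rates(n_runs: int = 50, n_subjects: int = 20,
                           n_trials: int = 100, n_perm: int = 999,
                           seed: int = 0) -> dict:
    """Strength/topography dissociation for a pure amplitude scaling.

    All components get map-strength multipliers 1.0 / 0.8 / 0.6 across the
    three stimulation frequencies (global scaling, identical topography).
    The GFP test on the N1-window mean maps should detect the frequency
    effect; TANOVA on the same maps should reject only at chance.

    ``n_trials`` matters for TANOVA's specificity: with very few trials the
    residual evoked noise is normalized up in the weaker conditions, which
    leaks a small map-strength signature into the normalized topographies.
    The default of 100 trials per average keeps the evoked noise in the
    regime of real recordings (which average several hundred trials).
    """
    mon = synth.reduced_montage(20)
    mult = dict(zip(synth.FREQ_LABELS, (1.0, 0.8, 0.6)))
    comps = [replace(c, freq_multipliers=dict(mult))
             for c in synth.make_component_defaults()]
    root = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    det = fp = 0
    for run in range(n_runs):
        cfg = synth.GeneratorConfig(
            montage=mon, n_subjects_per_group=n_subjects, n_trials=n_trials,
            noise_sd_uv=1.0, sampling_rate=125.0,
            seed=int((root + run) % (2 ** 31)))
        eps, _ = synth.simulate(cfg, comps)
        t = cfg.time_axis()
        sel = (t >= N1_WINDOW_MS[0]) & (t <= N1_WINDOW_MS[1])
        X = _evoked_maps(eps, cfg.freq_labels, baseline=True)[..., sel].mean(axis=-1)
        d = ts.DesignSpec(within_levels=cfg.freq_labels, within_name="frequency",
                          n_perm=n_perm, seed=int((root + run) % (2 ** 31)))
        det += int(ts.gfp_test(X, d)["frequency"].p < 0.05)
        fp += int(ts.tanova(X, d)["frequency"].p < 0.05)
    return {"gfp_detection_rate": det / n_runs, "tanova_fp_rate": fp / n_runs,
            "n_runs": n_runs}


def _marker_trace(sampling_rate: float = 125.0):
    """Noise-free Cz-Fz trace of the default components, plus truth."""
    cfg = synth.GeneratorConfig(n_subjects_per_group=1, n_trials=1,
                                noise_sd_uv=0.0, sampling_rate=sampling_rate,
                                seed=0)
    sig = synth.noise_free_evoked(cfg)
    mon = cfg.resolve_montage()
    trace = sig[mon.index("Cz")] - sig[mon.index("Fz")]
    return trace, cfg.time_axis(), sig, mon


def marker_recovery(n_runs: int = 200, snr: float = 5.0, seed: int = 0) -> dict:
    """Latency recovery of the programmed N1 (115 ms) and P2 (255 ms).

    Noise is temporally smoothed (20 ms kernel) and scaled so the weaker
    component still has peak/noise SNR of ``snr`` on the Cz-Fz trace.  A
    detection counts as recovered when it lands within one sample interval
    of the programmed latency after grid quantization (|error| <=
    1.5 * dt: the programmed latencies do not fall on the 8 ms grid, so
    quantization alone contributes up to half a sample).
    """
    trace0, t, _, _ = _marker_trace()
    dt = float(np.median(np.diff(t)))
    truth = {"N1": 115.0, "P2": 255.0}
    sel = {c: (t >= w[0]) & (t <= w[1])
           for c, w in tmark.DEFAULT_SEARCH_WINDOWS.items()}
    amp = {"N1": -trace0[sel["N1"]].min(), "P2": trace0[sel["P2"]].max()}
    noise_sd = min(amp.values()) / snr
    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in truth}
    for _ in range(n_runs):
        noisy = trace0 + noise_sd * synth.smoothed_noise(rng, trace0.shape, dt, 20.0)
        ms = tmark.detect_markers(noisy, t)
        for c, true_lat in truth.items():
            if abs(ms.latency_ms[c] - true_lat) <= 1.5 * dt + 1e-9:
                hits[c] += 1
    return {f"{c.lower()}_recovery_rate": h / n_runs for c, h in hits.items()} | {
        "noise_sd_uv": float(noise_sd), "n_runs": n_runs, "dt_ms": dt}


def window_recovery() -> dict:
    """GFP-derived windows versus the programmed component latencies.

    Checks that minima-mode windows bracket N1 (115 ms) and P2 (255 ms)
    and that inflection-mode windows nest inside the minima windows.
    """
    _, t, sig, _ = _marker_trace()
    curve = ts.gfp(sig - sig.mean(axis=0), axis=0)
    minima = tmark.windows_from_gfp(curve, t, mode="minima")
    inflect = tmark.windows_from_gfp(curve, t, mode="inflection")
    truth = {"N1": 115.0, "P2": 255.0}
    out = {}
    for c, lat in truth.items():
        lo, hi = minima.windows[c]
        li, hi2 = inflect.windows[c]
        out[f"{c.lower()}_bracketed"] = bool(lo <= lat <= hi)
        out[f"{c.lower()}_nested"] = bool(lo <= li and hi2 <= hi)
        out[f"{c.lower()}_minima"] = [lo, hi]
        out[f"{c.lower()}_inflection"] = [li, hi2]
    return out


def microstate_recovery(n_seeds: int = 25, n_subjects: int = 20,
                        n_states: int = 4, n_repeats: int = 50,
                        k_grid=range(3, 21), noise_sd: float = 1.0,
                        seed: int = 0) -> dict:
    """Cross-validated class-count and prototype recovery.

    Each seed builds a dataset with ``n_states`` programmed template maps
    (unit GFP, orthogonal) and per-subject white map noise; reports the
    fraction of seeds whose CV picks the true k, the worst prototype-truth
    correlation of the full-data AAHC fit at the true k, and label purity
    on the noise-free sequence.
    """
    root = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    k_hits = 0
    min_proto_corr = 1.0
    for i in range(n_seeds):
        s = int((root + i) % (2 ** 31))
        maps, templates, _ = synth.make_microstate_dataset(
            n_subjects=n_subjects, n_states=n_states, noise_sd=noise_sd, seed=s)
        cv = tms.cross_validate_k(maps, k_grid, n_repeats=n_repeats, seed=s)
        k_hits += int(cv.chosen_k == n_states)
        model = tms.aahc(maps.mean(axis=0), n_states)
        corr = np.abs(tms._corr_to_prototypes(templates, model.prototypes))
        min_proto_corr = min(min_proto_corr, float(corr.max(axis=1).min()))

    # noise-free purity at the same layout
    clean, templates, seq = synth.make_microstate_dataset(
        n_subjects=1, n_states=n_states, noise_sd=0.0, seed=root)
    model = tms.aahc(clean[0], n_states)
    relabel = {}
    purity_ok = True
    for lab, true in zip(model.labels, seq):
        relabel.setdefault(int(lab), int(true))
        purity_ok &= relabel[int(lab)] == int(true)
    purity_ok &= len(relabel) == n_states
    return {"k_recovery_rate": k_hits / n_seeds,
            "min_prototype_truth_correlation": min_proto_corr,
            "noise_free_label_purity": 1.0 if purity_ok else 0.0,
            "n_seeds": n_seeds}


def spline_errors(seed: int = 0) -> dict:
    """Spherical-spline accuracy on the 64-channel montage.

    Constant-field reproduction, electrode-site interpolation at lambda=0,
    and recovery of a random degree-<=3 spherical-harmonic field at
    between-electrode targets (relative RMS).
    """
    from scipy.special import sph_harm_y

    mon = standard_montage()
    rng = np.random.default_rng(seed)
    th, ph = np.deg2rad(mon.theta), np.deg2rad(mon.phi)

    const_err = float(np.max(np.abs(
        spline_interpolate(mon, np.full(len(mon), 3.25),
                           [[0.0, 0.0, 1.0], [0.6, 0.0, 0.8]]) - 3.25)))

    v = rng.normal(size=len(mon))
    at_sites = spline_interpolate(mon, v, mon.cartesian)
    site_err = float(np.max(np.abs(at_sites - v)))

    def harm(n, m, theta, phi):
        y = sph_harm_y(n, abs(m), theta, phi)
        return np.real(y) if m >= 0 else np.imag(y)

    terms = [(n, m, rng.normal()) for n in range(1, 4) for m in range(-n, n + 1)]
    field = sum(w * harm(n, m, th, ph) for n, m, w in terms)
    pairs = rng.integers(0, len(mon), size=(300, 2))
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    mid = mon.cartesian[pairs[:, 0]] + mon.cartesian[pairs[:, 1]]
    mid /= np.linalg.norm(mid, axis=1, keepdims=True)
    mid = mid[mid[:, 2] > np.cos(np.deg2rad(mon.theta.max()))]
    tt, tp = np.arccos(np.clip(mid[:, 2], -1, 1)), np.arctan2(mid[:, 1], mid[:, 0])
    truth = sum(w * harm(n, m, tt, tp) for n, m, w in terms)
    est = spline_interpolate(mon, field, mid)
    harm_rel_rms = float(np.sqrt(np.mean((est - truth) ** 2))
                         / np.sqrt(np.mean(truth ** 2)))
    return {"constant_abs_error": const_err, "site_abs_error": site_err,
            "harmonic_rel_rms": harm_rel_rms, "n_targets": int(len(mid))}


def gfp_identity_error(n_maps: int = 1000, n_channels: int = 32,
                       seed: int = 0) -> float:
    """Max |gfp - population SD| over random maps (independent computation)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_maps, n_channels))
    ref = np.sqrt(np.mean((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1))
    return float(np.max(np.abs(ts.gfp(X, axis=1) - ref)))
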