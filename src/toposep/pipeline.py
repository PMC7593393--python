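"""Config-driven end-to-end analysis runs and topographic map figures.

A run executes the full workflow — input (simulate / fixtures /
BrainVision), preprocessing, component markers, data-driven time windows,
randomization statistics, microstate segmentation — and writes TSV tables,
JSON summaries, and a reproducibility manifest to an output directory.
Given the same config and seed, all tables and summaries are byte
identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import markers as tmark
from . import microstates as tms
from . import preprocess as prep
from . import synth
from . import topostats as ts
from .containers import EpochSet, EvokedMapSeries
from .montage import to_cartesian
from .spline import SplineInterpolator

__all__ = ["load_config", "validate_config", "run", "plot_map_series"]

logger = logging.getLogger(__name__)

_INPUT_KEYS = ("simulate", "fixtures", "brainvision")

DEFAULT_CONFIG = {
    "preprocess": {
        "filter": {"band": [0.5, 70.0], "notch": 50.0},
        "epoch_window_ms": [-100.0, 600.0],
        "event_codes": None,
        "reject_threshold_uv": 100.0,
        "baseline_window_ms": [-53.0, -3.0],
        "virtual_channels": "default",
    },
    "markers": {
        "enable": True,
        "channel_pair": "Cz-AvgRef",
        "search_windows": {"P1": [40, 90], "N1": [80, 170], "P2": [185, 380]},
        "stability_r_min": 0.5,
    },
    "windows": {"enable": True, "smooth_ms": 5.0},
    "topostats": {"enable": True, "n_perm": 499},
    "microstates": {
        "enable": True,
        "k_grid": [3, 8],
        "n_repeats": 10,
        "window_ms": [20.0, 600.0],
        "n_perm": 499,
    },
    "plots": {"enable": False, "start_ms": -85.0, "end_ms": 380.0, "step_ms": 15.0},
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    """Validate and normalize a run config; raises before any computation."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    if "input" not in config:
        raise ValueError("config needs an 'input' block")
    sources = [k for k in _INPUT_KEYS if k in config["input"]]
    if len(sources) != 1:
        raise ValueError(
            f"config must name exactly one input source of {_INPUT_KEYS}, got {sources}"
        )
    if "seed" not in config:
        raise ValueError("config needs an explicit 'seed' (randomization is used)")
    merged = _merge(DEFAULT_CONFIG, {k: v for k, v in config.items()
                                     if k not in ("input", "seed")})
    merged["input"] = config["input"]
    merged["seed"] = int(config["seed"])
    return merged


# ------------------------------------------------------------- input stage

def _load_epoch_sets(config: dict) -> dict:
    inp = config["input"]
    if "simulate" in inp:
        sim = dict(inp["simulate"])
        n_channels = sim.pop("n_channels", None)
        if n_channels is not None and "montage" not in sim:
            sim["montage"] = synth.reduced_montage(int(n_channels))
        for key in ("freq_labels", "locations", "window_ms"):
            if key in sim:
                sim[key] = tuple(sim[key])
        gen = synth.GeneratorConfig(seed=config["seed"], **sim)
        epoch_sets, _truth = synth.simulate(gen)
        return epoch_sets
    if "fixtures" in inp:
        out = {}
        for path in inp["fixtures"]:
            ep = tio.read_epochs(path)
            out[(ep.subject_id, ep.condition[0], ep.condition[1])] = ep
        return out
    bv = inp["brainvision"]
    rec = tio.load_brainvision(bv["header"])
    pcfg = config["preprocess"]
    fspec = prep.FilterSpec(band=tuple(pcfg["filter"]["band"]),
                            notch_hz=pcfg["filter"]["notch"])
    rec = prep.bandpass_notch(rec, fspec)
    ep = prep.segment(rec, pcfg.get("event_codes"),
                      *pcfg["epoch_window_ms"],
                      subject_id=bv.get("subject", "S00"),
                      condition=tuple(bv.get("condition", ("", ""))))
    return {(ep.subject_id, ep.condition[0], ep.condition[1]): ep}


def _trace(evoked: EvokedMapSeries, pair: str) -> np.ndarray:
    """Resolve 'A-B' or 'A-AvgRef' channel-pair syntax to a trace."""
    a, b = pair.split("-", 1)
    if b == "AvgRef":
        avg = evoked if evoked.reference == "average" else prep.to_average_reference(evoked)
        return prep.reference_trace(avg, a)
    return prep.difference_channel(evoked, a, b)


# --------------------------------------------------------------- main run

def run(config: dict, out_dir, make_plots: Optional[bool] = None) -> dict:
    """Execute the configured workflow; returns a summary dict.

    All outputs land in ``out_dir``: ``markers.tsv``, ``responder.json``,
    ``windows.json``, ``stats_timewise.tsv``, ``microstates.json``,
    ``microstate_parameters.tsv``, ``microstate_tests.tsv``,
    ``manifest.json`` and (optionally) topographic map figures.
    """
    cfg = validate_config(config)
    os.makedirs(out_dir, exist_ok=True)
    seed = cfg["seed"]
    manifest: dict = {
        "config": cfg_serializable(cfg),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_serializable(cfg), sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "versions": _versions(),
        "stages": {},
        "status": "incomplete",
    }
    summary: dict = {}
    try:
        epoch_sets = _load_epoch_sets(cfg)
        pcfg = cfg["preprocess"]

        vdefs = pcfg["virtual_channels"]
        if vdefs == "default":
            vdefs = prep.DEFAULT_VIRTUAL_CHANNELS
        elif vdefs:
            vdefs = tuple((d[0], float(d[1]), float(d[2])) for d in vdefs)

        evokeds, odd_even, kept_counts = {}, {}, {}
        for key, ep in sorted(epoch_sets.items()):
            ep = prep.reject_artifacts(ep, pcfg["reject_threshold_uv"])
            ep = prep.baseline_correct(ep, tuple(pcfg["baseline_window_ms"]))
            kept_counts[key] = ep.n_kept
            ev = prep.average(ep)
            if vdefs:
                ev = prep.add_virtual_channels(ev, vdefs, lambda_reg=1e-8)
            evokeds[key] = ev
            if ep.n_kept >= 2:
                odd, even = prep.split_half_averages(ep)
                odd_even[key] = (odd, even)
        manifest["stages"]["preprocess"] = {
            "n_datasets": len(evokeds),
            "kept_trials": {"|".join(k): v for k, v in kept_counts.items()},
        }

        subjects = sorted({k[0] for k in evokeds})
        freqs = sorted({k[1] for k in evokeds})
        locs = sorted({k[2] for k in evokeds})
        any_ev = next(iter(evokeds.values()))
        time = any_ev.time
        dt = float(np.median(np.diff(time)))
        subject_loc = {s: next(k[2] for k in evokeds if k[0] == s) for s in subjects}

        # ------------------------------------------------------- markers
        mcfg = cfg["markers"]
        marker_rows, marker_sets = [], []
        if mcfg["enable"]:
            pair = mcfg["channel_pair"]
            wins = {k: tuple(v) for k, v in mcfg["search_windows"].items()}
            for key, ev in sorted(evokeds.items()):
                trace = _trace(ev, pair)
                mset = tmark.detect_markers(trace, time, wins, channel_pair=pair)
                if key in odd_even:
                    o, e = odd_even[key]
                    if vdefs:
                        o = prep.add_virtual_channels(o, vdefs, lambda_reg=1e-8)
                        e = prep.add_virtual_channels(e, vdefs, lambda_reg=1e-8)
                    r, stable = tmark.stability(_trace(o, pair), _trace(e, pair),
                                                r_min=mcfg["stability_r_min"])
                    mset.stability_r, mset.stable = r, stable
                marker_sets.append(mset)
                for comp in wins:
                    marker_rows.append({
                        "subject": key[0], "frequency": key[1], "location": key[2],
                        "channel_pair": pair, "component": comp,
                        "latency_ms": mset.latency_ms[comp],
                        "amplitude_uv": mset.amplitude_uv[comp],
                        "stability_r": mset.stability_r, "stable": mset.stable,
                    })
            _write_tsv(pd.DataFrame(marker_rows), os.path.join(out_dir, "markers.tsv"))
            rate = tmark.responder_rate(marker_sets)
            summary["responder_rate"] = rate
            _write_json({"responder_rate_percent": rate,
                         "n_recordings": len(marker_sets)},
                        os.path.join(out_dir, "responder.json"))
            manifest["stages"]["markers"] = {"n_recordings": len(marker_sets)}

        # ------------------------------------------------------- windows
        grand = np.mean([ev.data for ev in evokeds.values()], axis=0)
        grand_avgref = grand - grand.mean(axis=0, keepdims=True)
        gfp_curve = ts.gfp(grand_avgref, axis=0)
        if cfg["windows"]["enable"]:
            wout: dict = {}
            for mode in ("minima", "inflection"):
                try:
                    cw = tmark.windows_from_gfp(
                        gfp_curve, time, mode=mode,
                        smooth_ms=cfg["windows"]["smooth_ms"])
                    wout[f"gfp_{mode}"] = {k: list(v) for k, v in cw.windows.items()}
                except tmark.WindowDetectionError as exc:
                    wout[f"gfp_{mode}"] = {"error": str(exc)}
            if marker_rows:
                df = pd.DataFrame(marker_rows)
                m2 = {}
                for comp, sub in df.groupby("component"):
                    try:
                        m2[comp] = list(tmark.windows_mean2sd(
                            sub["latency_ms"].to_numpy(), dt))
                    except ValueError:
                        pass
                wout["mean2sd"] = m2
            summary["windows"] = wout
            _write_json(wout, os.path.join(out_dir, "windows.json"))
            manifest["stages"]["windows"] = {"modes": sorted(wout)}

        # ----------------------------------------------------- topostats
        if cfg["topostats"]["enable"] and len(subjects) >= 2 and len(freqs) >= 1:
            n_perm = int(cfg["topostats"]["n_perm"])
            X = np.stack([
                np.stack([_avgref_data(evokeds[(s, f, subject_loc[s])]) for f in freqs])
                for s in subjects
            ])  # (S, C, K, T)
            groups = tuple(subject_loc[s] for s in subjects)
            design = ts.DesignSpec(
                within_levels=tuple(freqs) if len(freqs) > 1 else None,
                groups=groups if len(set(groups)) > 1 else None,
                within_name="frequency", between_name="location",
                n_perm=n_perm, seed=seed,
            )
            rows = []
            if design.within_levels or design.groups:
                for name, res in {**ts.tanova(X, design, time_ms=time)}.items():
                    rows += _result_rows("tanova", name, res, time)
                for name, res in {**ts.gfp_test(X, design, time_ms=time)}.items():
                    rows += _result_rows("gfp_test", name, res, time)
            tct_res = ts.tct(X.mean(axis=1), n_perm=n_perm, seed=seed, time_ms=time)
            rows += _result_rows("tct", "consistency", tct_res, time)
            stats_df = pd.DataFrame(rows)
            _write_tsv(stats_df, os.path.join(out_dir, "stats_timewise.tsv"))
            intervals = {}
            for (test, factor), sub in stats_df.groupby(["test", "factor"]):
                p = sub["p"].to_numpy()
                tms_ = sub["time_ms"].to_numpy()
                res = ts.RandTestResult(factor, sub["effect"].to_numpy(), p,
                                        n_perm, seed, tms_)
                intervals[f"{test}:{factor}"] = res.significant_intervals(0.05)
            summary["stats"] = intervals
            _write_json(intervals, os.path.join(out_dir, "significant_intervals.json"))
            manifest["stages"]["topostats"] = {"n_perm": n_perm,
                                               "factors": sorted(intervals)}

        # --------------------------------------------------- microstates
        uscfg = cfg["microstates"]
        if uscfg["enable"] and len(subjects) >= 4:
            k_lo, k_hi = uscfg["k_grid"]
            window = (float(uscfg["window_ms"][0]),
                      min(float(uscfg["window_ms"][1]), float(time[-1])))
            wsel = (time >= window[0]) & (time <= window[1])
            subj_series = np.stack([
                np.concatenate([
                    _avgref_data(evokeds[(s, f, subject_loc[s])])[:, wsel].T
                    for f in freqs])
                for s in subjects
            ])  # (S, C*Tw, K)
            k_grid = range(k_lo, min(k_hi, subj_series.shape[1]) + 1)
            cv = tms.cross_validate_k(subj_series, k_grid,
                                      n_repeats=int(uscfg["n_repeats"]), seed=seed)
            model = tms.aahc(subj_series.mean(axis=0), cv.chosen_k)
            model.to_json(os.path.join(out_dir, "microstates.json"))
            cond_series = np.stack([
                np.stack([_avgref_data(evokeds[(s, f, subject_loc[s])]).T
                          for f in freqs]) for s in subjects
            ])  # (S, C, T, K)
            cmp = tms.assign_and_compare(model, cond_series, time,
                                         window_ms=window,
                                         condition_labels=freqs,
                                         n_perm=int(uscfg["n_perm"]), seed=seed)
            prow = [
                {"class": j, "condition": c, **vals}
                for (j, c), vals in sorted(cmp["parameters"].items())
            ]
            _write_tsv(pd.DataFrame(prow),
                       os.path.join(out_dir, "microstate_parameters.tsv"))
            trow = [
                {"class": j, "parameter": pname,
                 "effect": float(res.effect), "p": float(res.p)}
                for (j, pname), res in sorted(cmp["tests"].items())
            ]
            _write_tsv(pd.DataFrame(trow),
                       os.path.join(out_dir, "microstate_tests.tsv"))
            summary["microstates"] = {
                "chosen_k": cv.chosen_k,
                "gev": model.gev,
                "cv_mean_correlation": dict(zip(map(str, cv.k_grid),
                                                cv.mean_correlation.tolist())),
            }
            _write_json(summary["microstates"],
                        os.path.join(out_dir, "microstates_summary.json"))
            manifest["stages"]["microstates"] = {"chosen_k": cv.chosen_k}

        # --------------------------------------------------------- plots
        do_plots = cfg["plots"]["enable"] if make_plots is None else make_plots
        if do_plots:
            gm = EvokedMapSeries(data=grand_avgref, time=time,
                                 montage=any_ev.montage, n_trials=1,
                                 reference="average")
            files = plot_map_series(
                gm, max(cfg["plots"]["start_ms"], time[0]),
                min(cfg["plots"]["end_ms"], time[-1]),
                cfg["plots"]["step_ms"], out_dir)
            manifest["stages"]["plots"] = {"n_maps": len(files)}

        manifest["status"] = "complete"
    finally:
        _write_json(manifest, os.path.join(out_dir, "manifest.json"))
    return summary


def _avgref_data(ev: EvokedMapSeries) -> np.ndarray:
    return ev.data - ev.data.mean(axis=0, keepdims=True)


def _result_rows(test: str, factor: str, res, time) -> list[dict]:
    return [
        {"test": test, "factor": factor, "time_ms": float(t),
         "effect": float(e), "p": float(p)}
        for t, e, p in zip(time, np.atleast_1d(res.effect), np.atleast_1d(res.p))
    ]


def cfg_serializable(cfg: dict):
    def conv(v):
        if isinstance(v, dict):
            return {str(k): conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if hasattr(v, "labels"):  # Montage in a simulate block
            return {"labels": list(v.labels)}
        return v
    return conv(cfg)


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"toposep": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


# ------------------------------------------------------------------ plots

def plot_map_series(evoked: EvokedMapSeries, start_ms: float, end_ms: float,
                    step_ms: float = 15.0, out_dir=".",
                    prefix: str = "map", grid_n: int = 60,
                    cmap: str = "RdBu_r") -> list[str]:
    """Topographic map time-course figures, one PNG per step.

    Maps are spline-interpolated onto an azimuthal-equidistant head
    projection (nose up, right is right) with a symmetric color scale
    shared across the whole series.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if start_ms < evoked.time[0] - 1e-9 or end_ms > evoked.time[-1] + 1e-9:
        raise ValueError("plot range outside the time axis")
    times = [start_ms]
    while times[-1] + step_ms <= end_ms + 1e-9:
        times.append(times[-1] + step_ms)

    theta_max = np.deg2rad(evoked.montage.theta.max()) + 0.15
    ax1d = np.linspace(-theta_max, theta_max, grid_n)
    gx, gy = np.meshgrid(ax1d, ax1d)
    r = np.hypot(gx, gy)
    inside = r <= theta_max
    with np.errstate(invalid="ignore"):
        st = np.sin(r) / np.where(r > 0, r, 1.0)
    targets = np.stack([gx * st, gy * st, np.cos(r)], axis=-1)[inside]
    interp = SplineInterpolator(evoked.montage.cartesian, targets,
                                lambda_reg=1e-8)

    data = np.stack([evoked.data[:, evoked.time_index(t)] for t in times])
    fields = interp(data)
    vmax = np.max(np.abs(fields)) or 1.0

    # electrode positions in the same projection
    eth = np.deg2rad(evoked.montage.theta)
    eph = np.deg2rad(evoked.montage.phi)
    ex, ey = eth * np.cos(eph), eth * np.sin(eph)

    files = []
    for ti, t in enumerate(times):
        img = np.full(r.shape, np.nan)
        img[inside] = fields[ti]
        fig, ax = plt.subplots(figsize=(2.2, 2.2))
        ax.imshow(img, origin="lower", cmap=cmap, vmin=-vmax, vmax=vmax,
                  extent=[-theta_max, theta_max, -theta_max, theta_max])
        ax.scatter(ex, ey, s=2, c="k")
        ax.add_patch(plt.Circle((0, 0), theta_max, fill=False, lw=1))
        ax.plot([0, 0.06, -0.06, 0], [theta_max, theta_max * 0.96,
                                      theta_max * 0.96, theta_max], "k-", lw=1)
        ax.set_title(f"{t:.0f} ms", fontsize=8)
        ax.set_axis_off()
        path = os.path.join(out_dir, f"{prefix}_{ti:03d}_{int(round(t)):+d}ms.png")
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        files.append(path)
    return files
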