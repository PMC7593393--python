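"""Microstate segmentation by atomize-and-agglomerate clustering (AAHC).

A microstate is a brief period of quasi-stable scalp topography.  AAHC
starts from every map as its own cluster and repeatedly *atomizes* the
cluster contributing least to the global explained variance (GEV),
reassigning its member maps to the remaining cluster with the highest
spatial correlation.  Because the procedure is hierarchical, one descent
yields the segmentation for every intermediate class count.

Polarity handling: in ``sensitive`` mode (the default for evoked data,
where a negativity and a positivity are distinct functional states) the
signed spatial correlation is used and prototypes are normalized member
means; in ``ignorant`` mode the absolute correlation is used and the
prototype is the first principal direction of the member maps.

The optimal class count is chosen by repeated split-half cross-validation
over subjects: prototypes fitted on the training half's grand average are
assigned to the test half's grand average, and the class count with the
highest mean assignment correlation wins (ties break toward fewer
classes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .topostats import DesignSpec, RandTestResult, gfp, tanova, gfp_test

__all__ = [
    "MicrostateModel",
    "CVResult",
    "aahc",
    "cross_validate_k",
    "assign_states",
    "assign_and_compare",
]

logger = logging.getLogger(__name__)

_EPS_GFP = 1e-12


@dataclass
class MicrostateModel:
    """Fitted microstate segmentation."""

    k: int
    prototypes: np.ndarray          # (k, channels), unit GFP, average-referenced
    labels: np.ndarray              # (time,) class index; -1 = unassigned
    gev: float                      # global explained variance in [0, 1]
    polarity_mode: str = "sensitive"

    def to_json(self, path) -> None:
        payload = {
            "k": int(self.k),
            "polarity_mode": self.polarity_mode,
            "gev": float(self.gev),
            "prototypes": self.prototypes.tolist(),
            "labels": self.labels.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, path) -> "MicrostateModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(k=d["k"], prototypes=np.array(d["prototypes"]),
                   labels=np.array(d["labels"], dtype=int), gev=d["gev"],
                   polarity_mode=d["polarity_mode"])


@dataclass
class CVResult:
    """Cross-validation curve over candidate class counts."""

    k_grid: tuple[int, ...]
    mean_correlation: np.ndarray    # per k, averaged over repeats
    chosen_k: int
    n_repeats: int
    split_sizes: tuple[int, int]
    seed: Optional[int] = None
    per_repeat: Optional[np.ndarray] = None  # (repeats, k)


def _corr_to_prototypes(maps: np.ndarray, protos: np.ndarray) -> np.ndarray:
    """Spatial correlation of each map (rows) with each prototype (rows)."""
    M = maps - maps.mean(axis=1, keepdims=True)
    P = protos - protos.mean(axis=1, keepdims=True)
    Mn = np.linalg.norm(M, axis=1, keepdims=True)
    Pn = np.linalg.norm(P, axis=1, keepdims=True)
    Mn = np.where(Mn > 0, Mn, 1.0)
    Pn = np.where(Pn > 0, Pn, 1.0)
    return (M / Mn) @ (P / Pn).T


def _prototype(members: np.ndarray, polarity_mode: str) -> np.ndarray:
    """Cluster prototype, unit GFP."""
    if polarity_mode == "sensitive":
        proto = members.mean(axis=0)
    else:
        # first principal direction; deterministic sign
        _, _, vt = np.linalg.svd(members - members.mean(axis=1, keepdims=True),
                                 full_matrices=False)
        proto = vt[0]
        nz = np.flatnonzero(np.abs(proto) > 1e-12)
        if nz.size and proto[nz[0]] < 0:
            proto = -proto
    g = proto.std()
    if g <= _EPS_GFP:
        return np.zeros_like(proto)
    return (proto - proto.mean()) / g


def aahc(maps: np.ndarray, k_target: Union[int, Sequence[int]],
         polarity_mode: str = "sensitive") -> Union[MicrostateModel, dict[int, MicrostateModel]]:
    """Atomize-and-agglomerate hierarchical clustering of a map sequence.

    Parameters
    ----------
    maps : (time, channels) average-referenced maps (e.g. a grand-average
        series or concatenated condition series).
    k_target : final class count, or a sequence of counts; with a sequence
        a dict {k: model} is returned, all from a single descent.
    polarity_mode : "sensitive" (signed correlation) or "ignorant".

    GEV accounting: each map contributes ``(gfp * corr)**2`` with its
    cluster's prototype, normalized by the total squared GFP; the cluster
    with the smallest summed contribution is atomized at each step.
    """
    X = np.asarray(maps, dtype=float)
    if X.ndim != 2:
        raise ValueError("maps must be (time, channels)")
    if polarity_mode not in ("sensitive", "ignorant"):
        raise ValueError("polarity_mode must be 'sensitive' or 'ignorant'")
    T, K = X.shape
    ks = [int(k_target)] if np.isscalar(k_target) else sorted({int(k) for k in k_target})
    if min(ks) < 1 or max(ks) > T:
        raise ValueError(f"k_target must be within 1..{T}")

    Xc = X - X.mean(axis=1, keepdims=True)  # enforce average reference
    g = gfp(Xc, axis=1)
    g_tot = float((g ** 2).sum())
    if g_tot <= 0:
        raise ValueError("all maps have zero GFP")

    members: list[list[int]] = [[t] for t in range(T)]
    protos = np.array([_prototype(Xc[[t]], polarity_mode) for t in range(T)])

    def member_corr(idx: np.ndarray, proto: np.ndarray) -> np.ndarray:
        c = _corr_to_prototypes(Xc[idx], proto[None, :])[:, 0]
        return c if polarity_mode == "sensitive" else np.abs(c)

    def contribution(ci: int) -> float:
        idx = np.asarray(members[ci])
        c = member_corr(idx, protos[ci])
        return float(((g[idx] * c) ** 2).sum()) / g_tot

    contrib = [contribution(i) for i in range(len(members))]
    snapshots: dict[int, MicrostateModel] = {}

    def snapshot(k: int) -> MicrostateModel:
        labels = np.empty(T, dtype=int)
        order = np.argsort([min(m) for m in members])  # stable, temporal order
        P = protos[order]
        total = 0.0
        for new_lab, ci in enumerate(order):
            idx = np.asarray(members[ci])
            labels[idx] = new_lab
            c = member_corr(idx, protos[ci])
            total += float(((g[idx] * c) ** 2).sum())
        return MicrostateModel(k=k, prototypes=P.copy(), labels=labels,
                               gev=total / g_tot, polarity_mode=polarity_mode)

    while True:
        n = len(members)
        if n in ks:
            snapshots[n] = snapshot(n)
        if n <= min(ks):
            break
        worst = int(np.argmin(contrib))
        orphans = members.pop(worst)
        protos = np.delete(protos, worst, axis=0)
        contrib.pop(worst)
        # reassign each freed map to the best remaining cluster
        corr = _corr_to_prototypes(Xc[orphans], protos)
        if polarity_mode == "ignorant":
            corr = np.abs(corr)
        best = np.argmax(corr, axis=1)
        touched = set()
        for t, b in zip(orphans, best):
            members[int(b)].append(t)
            touched.add(int(b))
        for ci in touched:
            idx = np.asarray(members[ci])
            protos[ci] = _prototype(Xc[idx], polarity_mode)
            contrib[ci] = contribution(ci)

    if np.isscalar(k_target):
        return snapshots[int(k_target)]
    return snapshots


def assign_states(maps: np.ndarray, prototypes: np.ndarray,
                  polarity_mode: str = "sensitive",
                  min_gfp: float = _EPS_GFP) -> tuple[np.ndarray, np.ndarray]:
    """Label each map with its best-correlating prototype.

    Returns ``(labels, corr)`` where labels are -1 for maps with
    (near-)zero GFP and ``corr`` is the achieved correlation (0 where
    unassigned).
    """
    X = np.asarray(maps, dtype=float)
    c = _corr_to_prototypes(X, prototypes)
    if polarity_mode == "ignorant":
        c = np.abs(c)
    labels = np.argmax(c, axis=1)
    best = c[np.arange(X.shape[0]), labels]
    low = gfp(X, axis=1) <= min_gfp
    labels = np.where(low, -1, labels)
    best = np.where(low, 0.0, best)
    return labels, best


def cross_validate_k(subject_maps: np.ndarray, k_grid: Sequence[int] = range(3, 21),
                     n_repeats: int = 50, seed: Optional[int] = None,
                     polarity_mode: str = "sensitive") -> CVResult:
    """Split-half cross-validation of the microstate class count.

    ``subject_maps`` is (subjects, time, channels); the time axis may be a
    concatenation of condition grand averages.  Each repeat randomly
    splits the subjects in half (one random subject is left out when the
    count is odd) and fits AAHC on the training grand average for every k.
    The score for k is the mean correlation between the two halves under
    the training segmentation: at each time point, the test grand-average
    map is correlated with the prototype that the *training* labels assign
    there.  Evaluating the training segmentation (rather than freely
    re-assigning test maps to whichever prototype fits best) is what makes
    the curve peak at the true class count: freely re-assigned correlations
    can only grow with k, whereas prototypes fitted to training noise fail
    to replicate in the test half.
    """
    X = np.asarray(subject_maps, dtype=float)
    if X.ndim != 3:
        raise ValueError("subject_maps must be (subjects, time, channels)")
    S, T, K = X.shape
    if S < 4:
        raise ValueError("cross-validation needs >= 4 subjects")
    ks = sorted({int(k) for k in k_grid})
    if max(ks) > T:
        raise ValueError(f"k_grid exceeds the number of time points ({T})")
    rng = np.random.default_rng(seed)
    half = S // 2
    scores = np.empty((n_repeats, len(ks)))
    for rep in range(n_repeats):
        order = rng.permutation(S)
        train = X[order[:half]].mean(axis=0)
        test = X[order[half:2 * half]].mean(axis=0)
        models = aahc(train, ks, polarity_mode=polarity_mode)
        for ki, k in enumerate(ks):
            m = models[k]
            c = _corr_to_prototypes(test, m.prototypes)
            if polarity_mode == "ignorant":
                c = np.abs(c)
            scores[rep, ki] = c[np.arange(T), m.labels].mean()
    mean_corr = scores.mean(axis=0)
    chosen = ks[int(np.argmax(mean_corr))]  # argmax ties -> smallest k
    return CVResult(k_grid=tuple(ks), mean_correlation=mean_corr,
                    chosen_k=chosen, n_repeats=n_repeats,
                    split_sizes=(half, half), seed=seed, per_repeat=scores)


_PARAMS = ("duration_ms", "mean_gfp", "occurrence")


def microstate_parameters(series: np.ndarray, time_ms: np.ndarray,
                          model: MicrostateModel,
                          window_ms: tuple[float, float] = (20.0, 600.0)) -> dict:
    """Per-class temporal parameters of one map series inside the window.

    duration_ms: total labeled time; mean_gfp: mean GFP over labeled time
    points (0 if the class never occurs); occurrence: GFP-weighted share of
    the window, sum(gfp | class) / sum(gfp); onset/offset: first/last
    labeled time (NaN if absent).
    """
    sel = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    if not sel.any():
        raise ValueError(f"series does not cover the window {window_ms}")
    X = series[sel]
    t = time_ms[sel]
    dt = float(np.median(np.diff(time_ms)))
    labels, _ = assign_states(X, model.prototypes, model.polarity_mode)
    g = gfp(X, axis=1)
    g_sum = g.sum()
    out = {}
    for j in range(model.k):
        m = labels == j
        out[j] = {
            "onset_ms": float(t[m][0]) if m.any() else float("nan"),
            "offset_ms": float(t[m][-1]) if m.any() else float("nan"),
            "duration_ms": float(m.sum() * dt),
            "mean_gfp": float(g[m].mean()) if m.any() else 0.0,
            "occurrence": float(g[m].sum() / g_sum) if g_sum > 0 else 0.0,
        }
    return out


def assign_and_compare(model: MicrostateModel, subject_series: np.ndarray,
                       time_ms: np.ndarray,
                       window_ms: tuple[float, float] = (20.0, 600.0),
                       condition_labels: Optional[Sequence[str]] = None,
                       n_perm: int = 5000, seed: Optional[int] = None) -> dict:
    """Assign microstate classes per condition and test parameter differences.

    ``subject_series`` is (subjects, conditions, time, channels).  Class
    parameters (duration, mean GFP, GFP-weighted occurrence) are computed
    per subject x condition and compared across conditions with the
    within-subject permutation scheme (statistic: sum over conditions of
    the absolute deviation of the level mean from the grand mean).

    Returns ``{"parameters": (class, condition) tables from the grand
    averages, "subject_parameters": per-subject arrays, "tests": {(class,
    parameter): RandTestResult}}``.
    """
    X = np.asarray(subject_series, dtype=float)
    if X.ndim != 4:
        raise ValueError("subject_series must be (S, C, T, K)")
    S, C, T, K = X.shape
    sel = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    if not sel.any() or time_ms[-1] < window_ms[1] - 1e-9:
        raise ValueError(f"series does not cover the window {window_ms}")
    if condition_labels is None:
        condition_labels = [f"cond{c}" for c in range(C)]

    grand = X.mean(axis=0)  # (C, T, K)
    params = {
        (j, condition_labels[c]): microstate_parameters(grand[c], time_ms, model, window_ms)[j]
        for c in range(C) for j in range(model.k)
    }

    subj = np.zeros((len(_PARAMS), model.k, S, C))
    for s in range(S):
        for c in range(C):
            per = microstate_parameters(X[s, c], time_ms, model, window_ms)
            for pi, pname in enumerate(_PARAMS):
                for j in range(model.k):
                    subj[pi, j, s, c] = per[j][pname]

    rng = np.random.default_rng(seed)
    tests: dict[tuple[int, str], RandTestResult] = {}
    subj_idx = np.arange(S)
    for pi, pname in enumerate(_PARAMS):
        for j in range(model.k):
            v = subj[pi, j]                       # (S, C)
            obs = np.abs(v.mean(axis=0) - v.mean()).sum()
            pidx = np.argsort(rng.random((n_perm, S, C)), axis=2)
            vp = v[subj_idx[None, :, None], pidx]  # (P, S, C)
            L = vp.mean(axis=1)
            null = np.abs(L - L.mean(axis=1, keepdims=True)).sum(axis=1)
            p = float(((null >= obs - 1e-12).sum() + 1) / (n_perm + 1))
            tests[(j, pname)] = RandTestResult(
                f"class{j}:{pname}", np.float64(obs), np.float64(p),
                n_perm, seed)
    return {"parameters": params, "subject_parameters": subj, "tests": tests}
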