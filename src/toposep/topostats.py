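"""Reference-independent map strength and randomization inference.

Global field power (GFP) is the spatial standard deviation of an
average-referenced scalp map (population divisor), i.e. its RMS about the
channel mean — a reference-independent measure of map strength.

Three permutation tests operate on subject x condition map data, time
point by time point:

* **TANOVA** — topographic analysis of variance.  Maps are GFP-normalized
  (so only topography matters) and the effect of a factor is the
  generalized dissimilarity: the sum over factor levels of the GFP of
  (level mean map - grand mean map).  The null is built by permuting
  condition labels within subjects (within-subject factors), subjects
  across groups (between-subject factors), or within-subject labels of the
  double-centered residuals (interaction).
* **GFP test** — the same permutation schemes applied to per-map GFP
  values without normalization, so it is sensitive to map strength and
  blind to topography; together the two tests dissociate strength from
  topography.
* **TCT** — topographic consistency test: the observed statistic is the
  GFP of the mean of GFP-normalized subject maps; the null shuffles
  channel values within each subject's map, destroying across-subject
  alignment while keeping each map's value distribution.

All p values use the permutation convention p = (#{null >= observed} + 1)
/ (n_perm + 1), so p is never 0 and never below 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "gfp",
    "normalize_map",
    "spatial_correlation",
    "DesignSpec",
    "RandTestResult",
    "tanova",
    "gfp_test",
    "tct",
    "t_map",
    "marker_statistics",
]

logger = logging.getLogger(__name__)

_EPS_GFP = 1e-12


def gfp(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Global field power: SD across channels (population divisor).

    Equals the RMS of the map when the channel mean is zero (average
    reference).
    """
    return np.asarray(values, dtype=float).std(axis=axis)


def normalize_map(values: np.ndarray, axis: int = 0,
                  eps: float = _EPS_GFP) -> np.ndarray:
    """Scale map(s) to unit GFP.  Raises on a (near-)zero-GFP map."""
    v = np.asarray(values, dtype=float)
    g = v.std(axis=axis, keepdims=True)
    if np.any(g <= eps):
        raise ValueError("cannot normalize a map with (near-)zero GFP")
    return v / g


def _normalize_or_zero(v: np.ndarray, axis: int) -> np.ndarray:
    """Unit-GFP maps; near-zero-GFP maps become all-zero (logged)."""
    g = v.std(axis=axis, keepdims=True)
    bad = g <= _EPS_GFP
    if bad.any():
        logger.warning("normalize: %d near-zero-GFP map(s) excluded", int(bad.sum()))
    g = np.where(bad, 1.0, g)
    return np.where(bad, 0.0, v / g)


def spatial_correlation(u: np.ndarray, v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Pearson correlation of two maps across channels."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean(axis=axis, keepdims=True)
    vc = v - v.mean(axis=axis, keepdims=True)
    num = (uc * vc).sum(axis=axis)
    den = np.sqrt((uc ** 2).sum(axis=axis) * (vc ** 2).sum(axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


@dataclass(frozen=True)
class DesignSpec:
    """Within/between design for the randomization tests.

    ``within_levels`` names the condition axis (e.g. three stimulation
    frequencies); ``groups`` assigns each subject a between-subject level
    (e.g. stimulation location).  Either may be omitted.
    """

    within_levels: Optional[tuple[str, ...]] = None
    groups: Optional[tuple[str, ...]] = None
    within_name: str = "within"
    between_name: str = "between"
    n_perm: int = 5000
    seed: Optional[int] = None

    def validate(self, n_subjects: int, n_conditions: int) -> None:
        if self.within_levels is not None and len(self.within_levels) != n_conditions:
            raise ValueError("within_levels must match the condition axis")
        if self.within_levels is None and n_conditions > 1:
            raise ValueError("data has a condition axis but no within factor declared")
        if self.groups is not None:
            if len(self.groups) != n_subjects:
                raise ValueError("groups must assign one level per subject")
            counts = {g: self.groups.count(g) for g in set(self.groups)}
            if min(counts.values()) < 1 or len(counts) < 2:
                raise ValueError("between factor needs >= 2 non-empty groups")


@dataclass
class RandTestResult:
    """Per-time-point effect and permutation p for one factor."""

    factor: str
    effect: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: Optional[int] = None
    time_ms: Optional[np.ndarray] = None

    def significant_intervals(self, alpha: float = 0.05) -> list[tuple[float, float]]:
        """Contiguous time intervals with p < alpha (needs ``time_ms``)."""
        if self.time_ms is None:
            raise ValueError("result carries no time axis")
        sig = self.p < alpha
        out = []
        i = 0
        while i < sig.size:
            if sig[i]:
                j = i
                while j + 1 < sig.size and sig[j + 1]:
                    j += 1
                out.append((float(self.time_ms[i]), float(self.time_ms[j])))
                i = j + 1
            else:
                i += 1
        return out


# ---------------------------------------------------------------- helpers

def _as_sckt(X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Canonicalize input to (subjects, conditions, channels, time)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:  # (S, C, K) single maps
        return X[..., None], True
    if X.ndim != 4:
        raise ValueError("map data must be (S, C, K) or (S, C, K, T)")
    return X, False


def _level_stat(level_vals: np.ndarray, maps: bool) -> np.ndarray:
    """Generalized dissimilarity over the level axis (first axis).

    ``level_vals`` is (C, K, T) level means minus the grand mean for map
    data, or (C, T) level-mean differences for scalar (GFP) data.
    """
    if maps:
        return gfp(level_vals, axis=1).sum(axis=0)
    return np.abs(level_vals).sum(axis=0)


def _observed_within(X: np.ndarray, maps: bool) -> np.ndarray:
    L = X.mean(axis=0)            # (C, K, T) or (C, T)
    G = L.mean(axis=0, keepdims=True)
    return _level_stat(L - G, maps)


def _p_from_null(null: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """p = (#{null >= obs} + 1) / (P + 1); null is (P, T), obs (T,)."""
    ge = (null >= obs[None, :] - 1e-12).sum(axis=0)
    return (ge + 1.0) / (null.shape[0] + 1.0)


def _exhaustive_within_perms(C: int, S: int, limit: int = 2_000_000):
    per_subject = list(itertools.permutations(range(C)))
    total = len(per_subject) ** S
    if total > limit:
        raise ValueError(
            f"exhaustive enumeration needs {total} permutations (> {limit})"
        )
    return itertools.product(per_subject, repeat=S), total


def _within_null(X: np.ndarray, maps: bool, n_perm: int,
                 rng: np.random.Generator, exhaustive: bool,
                 chunk: int = 200) -> tuple[np.ndarray, int]:
    """Null distribution of the within-factor statistic.  X is (S, C, K, T)
    for maps or (S, C, T) for scalars."""
    S, C = X.shape[0], X.shape[1]
    if exhaustive:
        perms_iter, total = _exhaustive_within_perms(C, S)
        T = X.shape[-1]
        null = np.empty((total, T))
        subj_idx = np.arange(S)
        for i, perm in enumerate(perms_iter):
            pidx = np.array(perm)  # (S, C)
            Xp = X[subj_idx[:, None], pidx]
            null[i] = _observed_within(Xp, maps)
        return null, total

    if C == 2 and maps:
        # sign-flip fast path: effect = gfp(mean_s +-(x_s0 - x_s1))
        d = X[:, 0] - X[:, 1]                      # (S, K, T)
        signs = rng.integers(0, 2, size=(n_perm, S)) * 2.0 - 1.0
        D = np.einsum("ps,skt->pkt", signs, d) / S
        return gfp(D, axis=1), n_perm

    T = X.shape[-1]
    null = np.empty((n_perm, T))
    subj_idx = np.arange(S)
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        P = stop - start
        # independent label permutation per subject
        pidx = np.argsort(rng.random((P, S, C)), axis=2)
        Xp = X[subj_idx[None, :, None], pidx]      # (P, S, C, ...)
        L = Xp.mean(axis=1)
        G = L.mean(axis=1, keepdims=True)
        if maps:
            null[start:stop] = gfp(L - G, axis=2).sum(axis=1)
        else:
            null[start:stop] = np.abs(L - G).sum(axis=1)
    return null, n_perm


def _group_matrix(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(groups))
    B = np.zeros((len(levels), len(groups)))
    for gi, g in enumerate(levels):
        members = [i for i, lab in enumerate(groups) if lab == g]
        B[gi, members] = 1.0 / len(members)
    return B, levels


def _between_effect(m: np.ndarray, B: np.ndarray, maps: bool) -> np.ndarray:
    """m is (S, K, T) subject means (or (S, T) scalars); B averages groups."""
    gm = np.tensordot(B, m, axes=(1, 0))           # (G, K, T)
    grand = m.mean(axis=0, keepdims=True)
    return _level_stat(gm - grand, maps)


def _between_null(m: np.ndarray, B: np.ndarray, maps: bool, n_perm: int,
                  rng: np.random.Generator, chunk: int = 500) -> np.ndarray:
    S = m.shape[0]
    T = m.shape[-1]
    null = np.empty((n_perm, T))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        P = stop - start
        pidx = np.argsort(rng.random((P, S)), axis=1)
        mp = m[pidx]                               # (P, S, K, T)
        gm = np.einsum("gs,ps...->pg...", B, mp)
        grand = mp.mean(axis=1, keepdims=True)
        if maps:
            null[start:stop] = gfp(gm - grand, axis=2).sum(axis=1)
        else:
            null[start:stop] = np.abs(gm - grand).sum(axis=1)
    return null


def _interaction_stat(X: np.ndarray, B: np.ndarray, maps: bool) -> np.ndarray:
    """Double-centered cell-mean dissimilarity; X is (S, C, ...)."""
    cell = np.einsum("gs,sc...->gc...", B, X)      # (G, C, ...)
    row = cell.mean(axis=1, keepdims=True)
    col = cell.mean(axis=0, keepdims=True)
    grand = cell.mean(axis=(0, 1), keepdims=True)
    resid = cell - row - col + grand
    if maps:
        return gfp(resid, axis=2).sum(axis=(0, 1))
    return np.abs(resid).sum(axis=(0, 1))


def _interaction_null(X: np.ndarray, B: np.ndarray, maps: bool, n_perm: int,
                      rng: np.random.Generator, chunk: int = 100) -> np.ndarray:
    # residualize out subject and level main effects, then permute
    # within-subject labels
    sub = X.mean(axis=1, keepdims=True)
    lev = X.mean(axis=0, keepdims=True)
    grand = X.mean(axis=(0, 1), keepdims=True)
    R = X - sub - lev + grand
    S, C = R.shape[0], R.shape[1]
    T = R.shape[-1]
    null = np.empty((n_perm, T))
    subj_idx = np.arange(S)
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        P = stop - start
        pidx = np.argsort(rng.random((P, S, C)), axis=2)
        Rp = R[subj_idx[None, :, None], pidx]
        cell = np.einsum("gs,psc...->pgc...", B, Rp)
        row = cell.mean(axis=2, keepdims=True)
        col = cell.mean(axis=1, keepdims=True)
        g0 = cell.mean(axis=(1, 2), keepdims=True)
        resid = cell - row - col + g0
        if maps:
            null[start:stop] = gfp(resid, axis=3).sum(axis=(1, 2))
        else:
            null[start:stop] = np.abs(resid).sum(axis=(1, 2))
    return null


# ------------------------------------------------------------ public tests

def _run_factorial(values: np.ndarray, design: DesignSpec, maps: bool,
                   exhaustive: bool, time_ms) -> dict[str, RandTestResult]:
    """Shared engine for tanova (maps=True) and gfp_test (maps=False).

    ``values`` is (S, C, K, T) for maps or (S, C, T) for scalars.
    """
    S, C = values.shape[0], values.shape[1]
    design.validate(S, C)
    if np.isnan(values).any():
        raise ValueError("design has empty cells (NaNs in the data array)")
    rng = np.random.default_rng(design.seed)
    results: dict[str, RandTestResult] = {}

    if design.within_levels is not None and C > 1:
        if S < 2:
            raise ValueError("within-subject test needs >= 2 subjects")
        obs = _observed_within(values, maps)
        null, n_used = _within_null(values, maps, design.n_perm, rng, exhaustive)
        if exhaustive:
            p = (null >= obs[None, :] - 1e-12).sum(axis=0) / n_used
        else:
            p = _p_from_null(null, obs)
        results[design.within_name] = RandTestResult(
            design.within_name, obs, p, n_used, design.seed, time_ms)

    if design.groups is not None:
        if exhaustive:
            raise NotImplementedError("exhaustive mode covers within factors only")
        B, _ = _group_matrix(design.groups)
        m = values.mean(axis=1)                   # subject means over conditions
        obs = _between_effect(m, B, maps)
        null = _between_null(m, B, maps, design.n_perm, rng)
        results[design.between_name] = RandTestResult(
            design.between_name, obs, _p_from_null(null, obs),
            design.n_perm, design.seed, time_ms)

        if design.within_levels is not None and C > 1:
            name = f"{design.within_name}*{design.between_name}"
            obs = _interaction_stat(values, B, maps)
            null = _interaction_null(values, B, maps, design.n_perm, rng)
            results[name] = RandTestResult(
                name, obs, _p_from_null(null, obs), design.n_perm,
                design.seed, time_ms)
    return results


def tanova(maps: np.ndarray, design: DesignSpec, exhaustive: bool = False,
           time_ms: Optional[np.ndarray] = None) -> dict[str, RandTestResult]:
    """Time-wise topographic analysis of variance.

    ``maps`` is (subjects, conditions, channels[, time]) of
    average-referenced maps.  Maps are GFP-normalized internally, so the
    test is blind to map strength.  With ``exhaustive=True`` all
    within-subject label permutations are enumerated and the p value is
    exact (small designs only).
    """
    X, single = _as_sckt(maps)
    Xn = _normalize_or_zero(X, axis=2)
    res = _run_factorial(Xn, design, maps=True, exhaustive=exhaustive,
                         time_ms=time_ms)
    if single:
        for r in res.values():
            r.effect, r.p = r.effect[..., 0], r.p[..., 0]
    return res


def gfp_test(maps: np.ndarray, design: DesignSpec,
             exhaustive: bool = False,
             time_ms: Optional[np.ndarray] = None) -> dict[str, RandTestResult]:
    """Randomization comparison of map strength (GFP) between conditions.

    Maps are *not* normalized: the per-map GFP is the tested quantity.
    """
    X, single = _as_sckt(maps)
    V = gfp(X, axis=2)                            # (S, C, T)
    res = _run_factorial(V, design, maps=False, exhaustive=exhaustive,
                         time_ms=time_ms)
    if single:
        for r in res.values():
            r.effect, r.p = r.effect[..., 0], r.p[..., 0]
    return res


def tct(maps: np.ndarray, n_perm: int = 5000, seed: Optional[int] = None,
        time_ms: Optional[np.ndarray] = None, chunk: int = 250) -> RandTestResult:
    """Topographic consistency test across subjects.

    ``maps`` is (subjects, channels[, time]).  The observed statistic is
    the GFP of the mean GFP-normalized map; the null shuffles channel
    values within each subject's map (one independent channel permutation
    per permutation x subject, shared over time points).
    """
    X = np.asarray(maps, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[..., None]
    if X.ndim != 3:
        raise ValueError("tct input must be (S, K) or (S, K, T)")
    S, K, T = X.shape
    if S < 2:
        raise ValueError("TCT needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    Xn = _normalize_or_zero(X, axis=1)
    obs = gfp(Xn.mean(axis=0), axis=0)            # (T,)
    null = np.empty((n_perm, T))
    subj = np.arange(S)[None, :, None]
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        P = stop - start
        pidx = np.argsort(rng.random((P, S, K)), axis=2)
        Xp = Xn[subj, pidx]                        # (P, S, K, T)
        null[start:stop] = gfp(Xp.mean(axis=1), axis=1)
    r = RandTestResult("consistency", obs, _p_from_null(null, obs),
                       n_perm, seed, time_ms)
    if single:
        r.effect, r.p = r.effect[0], r.p[0]
    return r


def t_map(a: np.ndarray, b: np.ndarray, paired: bool) -> np.ndarray:
    """Channel-wise t statistics between two conditions of window means.

    ``a``/``b`` are (subjects, channels).  Paired uses the dependent t;
    unpaired uses Welch's t.  Descriptive (no multiplicity correction).
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired t-map needs equal subject sets")
        t, _ = stats.ttest_rel(a, b, axis=0)
    else:
        t, _ = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.asarray(t)
    # a 0/0 from identical data is a zero effect, not an undefined one
    zero = np.isnan(t) & np.isclose(a.mean(axis=0), b.mean(axis=0))
    return np.where(zero, 0.0, t)


def marker_statistics(maps_at_peaks: np.ndarray, design: DesignSpec,
                      test: str = "tanova") -> dict[str, RandTestResult]:
    """TANOVA / GFP test on single maps extracted at individual peak
    latencies (subjects x conditions x channels)."""
    if maps_at_peaks.ndim != 3:
        raise ValueError("marker maps must be (S, C, K)")
    fn = {"tanova": tanova, "gfp": gfp_test}[test]
    return fn(maps_at_peaks, design)
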