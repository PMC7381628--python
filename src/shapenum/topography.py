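"""Reference-free topographic measures and the randomization TANOVA.

GFP is the spatial standard deviation of an average-referenced map; DISS
the root-mean-square difference between two GFP-normalized maps (in [0, 2],
related to the spatial Pearson correlation by DISS = sqrt(2 (1 - r))). The
TANOVA tests, at every time point, whether two within-subject conditions
differ in topography: the observed statistic is the DISS between the two
grand-average maps and the null is built by randomly exchanging the two
condition labels within each subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ZeroGFPError(ValueError):
    pass


def average_reference(maps: np.ndarray) -> np.ndarray:
    """Remove the channel mean (last axis is channels)."""
    return maps - maps.mean(axis=-1, keepdims=True)


def gfp(map_: np.ndarray) -> float | np.ndarray:
    """Global field power: RMS of the average-referenced map. Works on a
    single map (K,) or a stack (..., K)."""
    m = average_reference(np.asarray(map_, dtype=float))
    return np.sqrt((m ** 2).mean(axis=-1))


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation across channels of the average-referenced maps."""
    u = average_reference(np.asarray(u, dtype=float))
    v = average_reference(np.asarray(v, dtype=float))
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ZeroGFPError("spatial correlation undefined for a flat map")
    return float(u @ v / (nu * nv))


def diss(u: np.ndarray, v: np.ndarray) -> float:
    """Global dissimilarity between two maps, independent of field strength."""
    u = average_reference(np.asarray(u, dtype=float))
    v = average_reference(np.asarray(v, dtype=float))
    gu, gv = gfp(u), gfp(v)
    if gu == 0 or gv == 0:
        raise ZeroGFPError("DISS undefined for a flat map")
    return float(np.sqrt(((u / gu - v / gv) ** 2).mean()))


def _diss_series(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized DISS between paired map series (..., T, K)."""
    a = average_reference(a)
    b = average_reference(b)
    ga = np.sqrt((a ** 2).mean(axis=-1, keepdims=True))
    gb = np.sqrt((b ** 2).mean(axis=-1, keepdims=True))
    ga[ga == 0] = np.nan
    gb[gb == 0] = np.nan
    return np.sqrt(((a / ga - b / gb) ** 2).mean(axis=-1))


@dataclass
class TanovaResult:
    times_ms: np.ndarray
    observed_diss: np.ndarray
    p: np.ndarray
    windows: list[tuple[float, float]]
    n_permutations: int
    alpha: float
    exhaustive: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms,
                             "diss": self.observed_diss, "p": self.p})


def significant_windows(p: np.ndarray, times_ms: np.ndarray, alpha: float,
                        min_duration_ms: float) -> list[tuple[float, float]]:
    """Runs of consecutive significant samples, discarding periods of
    stability shorter than the duration criterion."""
    sig = p < alpha
    windows = []
    i = 0
    T = len(sig)
    while i < T:
        if sig[i]:
            j = i
            while j + 1 < T and sig[j + 1]:
                j += 1
            if times_ms[j] - times_ms[i] + (times_ms[1] - times_ms[0]) >= min_duration_ms:
                windows.append((float(times_ms[i]), float(times_ms[j])))
            i = j + 1
        else:
            i += 1
    return windows


def tanova(cond_a: np.ndarray, cond_b: np.ndarray,
           times_ms: np.ndarray | None = None,
           n_permutations: int = 5000, alpha: float = 0.05,
           min_duration_ms: float = 10.0,
           seed: int | None = None) -> TanovaResult:
    """Point-wise randomization TANOVA for two within-subject conditions.

    ``cond_a`` and ``cond_b`` are (n_subjects, n_times, n_channels) arrays of
    per-subject map series. The null exchanges the two condition labels
    within each subject with a fair coin; when the full sign-flip set
    (2^n_subjects patterns) is no larger than the requested Monte-Carlo
    count it is enumerated exhaustively and the p-value is exact.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("conditions must be matching (S, T, K) arrays")
    S, T, K = a.shape
    if S < 2:
        raise ValueError("need at least 2 subjects")
    if times_ms is None:
        times_ms = np.arange(T, dtype=float)

    a = average_reference(a)
    b = average_reference(b)
    msum = (a + b).mean(axis=0)          # (T, K)
    d = a - b                            # (S, T, K)
    observed = _diss_series(a.mean(axis=0), b.mean(axis=0))

    exhaustive = 2 ** S <= n_permutations + 1
    if exhaustive:
        bits = np.array(
            [[1 if (pat >> s) & 1 else -1 for s in range(S)]
             for pat in range(2 ** S)], dtype=float)
        signs = bits
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, S))

    # grand averages under sign pattern eps: (msum +- mean(eps_s d_s)) / 2
    flat_d = d.reshape(S, T * K)
    null = np.empty((len(signs), T))
    chunk = max(1, int(2e7 // (T * K)))
    for start in range(0, len(signs), chunk):
        e = signs[start:start + chunk] @ flat_d / S       # (c, T*K)
        e = e.reshape(-1, T, K)
        ga = (msum + e) / 2.0
        gb = (msum - e) / 2.0
        null[start:start + chunk] = _diss_series(ga, gb)

    if exhaustive:
        p = (null >= observed - 1e-12).sum(axis=0) / len(signs)
    else:
        p = (1.0 + (null >= observed - 1e-12).sum(axis=0)) / (len(signs) + 1.0)

    wins = significant_windows(p, np.asarray(times_ms, float), alpha,
                               min_duration_ms)
    return TanovaResult(np.asarray(times_ms, float), observed, p, wins,
                        len(signs), alpha, exhaustive)


def grouped_condition_maps(erps_by_subject: dict[int, dict[str, "object"]],
                           group: list[str]) -> np.ndarray:
    """Average a set of condition labels within each subject, returning a
    (n_subjects, n_times, n_channels) stack for TANOVA."""
    out = []
    for erps in erps_by_subject.values():
        stack = np.mean([erps[g].data for g in group], axis=0)
        out.append(stack.T)      # (T, K)
    return np.array(out)
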