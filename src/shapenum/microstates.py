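"""Microstate segmentation of ERP map series.

Segmentation uses the atomize-and-agglomerate hierarchical clustering
(AAHC) scheme: every time-point map starts as its own cluster; at each step
the cluster contributing least global explained variance (GEV) is
dissolved and its members are reassigned to the cluster whose template
correlates best with them. Clustering is polarity-sensitive (a map and its
inverse are different states), the evoked-potential convention. The number
of templates is chosen by the cross-validation criterion

    CV(q) = sigma_hat^2 * ((K - 1) / (K - 1 - q))^2,

with sigma_hat^2 the label-conditional residual variance of the map series
under unit-norm templates. Selected templates are back-fitted to individual
ERPs by winner-take-all spatial correlation and summarized as GEV per
template within the component analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topography import average_reference


class DegenerateInputError(ValueError):
    pass


class QTooLargeError(ValueError):
    pass


def _unit_norm_rows(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=-1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def to_unit_gfp(templates: np.ndarray) -> np.ndarray:
    """Rescale unit-norm templates to unit GFP (||a|| = sqrt(K))."""
    K = templates.shape[-1]
    return _unit_norm_rows(templates) * np.sqrt(K)


def residual_variance(series: np.ndarray, templates: np.ndarray,
                      labels: np.ndarray) -> float:
    """Label-conditional residual variance with unit-norm templates."""
    u = average_reference(np.asarray(series, dtype=float))
    a = _unit_norm_rows(average_reference(np.asarray(templates, dtype=float)))
    T, K = u.shape
    proj = np.einsum("tk,tk->t", u, a[labels])
    total = np.einsum("tk,tk->t", u, u)
    return float((total - proj ** 2).sum() / (T * (K - 1)))


def cv_criterion(series: np.ndarray, templates: np.ndarray,
                 labels: np.ndarray) -> float:
    """Penalized residual-variance criterion for template-count selection."""
    K = series.shape[-1]
    q = len(templates)
    if q >= K - 1:
        raise QTooLargeError("q must be smaller than K - 1")
    s2 = residual_variance(series, templates, labels)
    return s2 * ((K - 1) / (K - 1 - q)) ** 2


@dataclass
class SegmentationResult:
    times_concat: np.ndarray                 # concatenated sample index
    condition_slices: dict[str, slice]
    templates_by_q: dict[int, np.ndarray]    # q -> (q, K) unit-GFP maps
    labels_by_q: dict[int, np.ndarray]       # q -> (T,) raw AAHC labels
    sigma2_by_q: dict[int, float]
    cv_by_q: dict[int, float]
    q_star: int
    min_segment_samples: int = 10

    @property
    def templates(self) -> np.ndarray:
        return self.templates_by_q[self.q_star]

    def labels(self, q: int | None = None, smooth: bool = True) -> np.ndarray:
        """Per-time-point labels, with sub-criterion segments relabeled to
        the better-correlated neighbouring state inside each condition."""
        q = q or self.q_star
        lab = self.labels_by_q[q].copy()
        if not smooth:
            return lab
        for sl in self.condition_slices.values():
            lab[sl] = _enforce_min_segment(lab[sl], self._series[sl],
                                           self.templates_by_q[q],
                                           self.min_segment_samples)
        return lab

    _series: np.ndarray = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "q_star": int(self.q_star),
            "cv_by_q": {int(k): float(v) for k, v in self.cv_by_q.items()},
            "sigma2_by_q": {int(k): float(v) for k, v in self.sigma2_by_q.items()},
        }


def _segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop_exclusive, label) runs."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, int(labels[start])))
            start = i
    return out


def _enforce_min_segment(labels: np.ndarray, series: np.ndarray,
                         templates: np.ndarray, min_len: int,
                         max_passes: int = 50) -> np.ndarray:
    """Reassign samples of segments shorter than ``min_len`` to the
    neighbouring state that correlates better, point by point."""
    lab = labels.copy()
    a = _unit_norm_rows(average_reference(templates))
    u = average_reference(series)
    for _ in range(max_passes):
        segs = _segments(lab)
        if len(segs) <= 1:
            break
        short = [s for s in segs if s[1] - s[0] < min_len]
        if not short:
            break
        # dissolve the shortest segment first
        start, stop, _ = min(short, key=lambda s: s[1] - s[0])
        idx = segs.index((start, stop, lab[start]))
        left = segs[idx - 1][2] if idx > 0 else None
        right = segs[idx + 1][2] if idx + 1 < len(segs) else None
        for t in range(start, stop):
            if left is None:
                lab[t] = right
            elif right is None:
                lab[t] = left
            else:
                rl = u[t] @ a[left]
                rr = u[t] @ a[right]
                lab[t] = left if rl >= rr else right
    return lab


def aahc(series: np.ndarray, q_range: range | list[int]) -> tuple[
        dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Atomize-and-agglomerate clustering over a (T, K) map series.

    Returns unit-norm templates and per-point labels for every cluster
    count in ``q_range``.
    """
    u = average_reference(np.asarray(series, dtype=float))
    T, K = u.shape
    norms = np.linalg.norm(u, axis=1)
    if np.all(norms == 0):
        raise DegenerateInputError("all maps have zero GFP")

    assignment = np.arange(T)
    active = np.ones(T, dtype=bool)
    templates = u.copy()
    templates = _unit_norm_rows(templates)
    # per-cluster GEV contribution with unit-norm templates: sum (u . a)^2
    contrib = norms ** 2

    want = sorted(set(int(q) for q in q_range), reverse=True)
    templates_by_q: dict[int, np.ndarray] = {}
    labels_by_q: dict[int, np.ndarray] = {}
    n_active = T

    def record(q: int) -> None:
        ids = np.flatnonzero(active)
        remap = {c: i for i, c in enumerate(ids)}
        templates_by_q[q] = templates[ids].copy()
        labels_by_q[q] = np.array([remap[c] for c in assignment])

    if want and want[0] >= n_active:
        for q in [q for q in want if q >= n_active]:
            record_q = q
            # fewer maps than requested clusters: record current partition
            ids = np.flatnonzero(active)
            remap = {c: i for i, c in enumerate(ids)}
            templates_by_q[record_q] = templates[ids].copy()
            labels_by_q[record_q] = np.array([remap[c] for c in assignment])
        want = [q for q in want if q < n_active]

    while n_active > 1:
        ids = np.flatnonzero(active)
        worst = ids[np.argmin(contrib[ids])]
        members = np.flatnonzero(assignment == worst)
        active[worst] = False
        n_active -= 1
        rest = np.flatnonzero(active)
        # reassign orphans to the best-correlated remaining template
        sims = u[members] @ templates[rest].T          # (m, n_active)
        best = rest[np.argmax(sims, axis=1)]
        assignment[members] = best
        # recompute affected templates and contributions
        for c in np.unique(best):
            mem = np.flatnonzero(assignment == c)
            mean_map = u[mem].mean(axis=0)
            nrm = np.linalg.norm(mean_map)
            templates[c] = mean_map / nrm if nrm > 0 else mean_map
            contrib[c] = float(((u[mem] @ templates[c]) ** 2).sum())
        if n_active in want:
            record(n_active)

    if 1 in want and 1 not in templates_by_q:
        record(1)
    return templates_by_q, labels_by_q


def segment(grand_averages: dict[str, np.ndarray],
            q_range: range | list[int] | None = None,
            min_segment_ms: float = 10.0,
            sample_ms: float = 1.0) -> SegmentationResult:
    """Segment concatenated grand-average series into microstates.

    ``grand_averages`` maps condition label -> (T, K) average-referenced map
    series (e.g. the 0..1000 ms post-stimulus window of each condition).
    """
    if q_range is None:
        q_range = range(1, 13)
    labels_order = list(grand_averages)
    slices = {}
    start = 0
    parts = []
    for lab in labels_order:
        arr = np.asarray(grand_averages[lab], dtype=float)
        slices[lab] = slice(start, start + len(arr))
        start += len(arr)
        parts.append(arr)
    series = average_reference(np.vstack(parts))
    T, K = series.shape

    templates_by_q, member_labels = aahc(series, q_range)
    # final labels are competitive (winner-take-all) fits of the recorded
    # templates, which sharpens the partition the agglomeration produced
    labels_by_q = {}
    sigma2, cv = {}, {}
    for q, tmpl in templates_by_q.items():
        labels_by_q[q], _ = backfit(series, tmpl)
        labels_by_q[q][labels_by_q[q] < 0] = 0
        sigma2[q] = residual_variance(series, tmpl, labels_by_q[q])
        if q < K - 1:
            cv[q] = sigma2[q] * ((K - 1) / (K - 1 - q)) ** 2
    q_star = min(cv, key=cv.get)

    res = SegmentationResult(
        times_concat=np.arange(T),
        condition_slices=slices,
        templates_by_q={q: to_unit_gfp(t) for q, t in templates_by_q.items()},
        labels_by_q=labels_by_q,
        sigma2_by_q=sigma2,
        cv_by_q=cv,
        q_star=q_star,
        min_segment_samples=max(1, int(round(min_segment_ms / sample_ms))),
    )
    res._series = series
    return res


def backfit(maps: np.ndarray, templates: np.ndarray) -> tuple[np.ndarray,
                                                              np.ndarray]:
    """Winner-take-all fit of templates to a (T, K) map series.

    Returns the label sequence and the per-template GEV vector
    GEV_m = sum_{t: L_t = m} (GFP_t r_t)^2 / sum_t GFP_t^2. Zero-GFP time
    points get label -1 and contribute only to the denominator (as zero).
    Correlation ties break toward the lowest template index.
    """
    u = average_reference(np.asarray(maps, dtype=float))
    a = _unit_norm_rows(average_reference(np.asarray(templates, dtype=float)))
    T, K = u.shape
    norms = np.linalg.norm(u, axis=1)
    gfp2 = norms ** 2 / K
    denom = gfp2.sum()
    labels = np.full(T, -1, dtype=int)
    gev = np.zeros(len(a))
    if denom == 0:
        return labels, gev
    ok = norms > 0
    corr = (u[ok] / norms[ok, None]) @ a.T          # (t_ok, q)
    win = np.argmax(corr, axis=1)                    # ties -> lowest index
    labels[ok] = win
    r = corr[np.arange(len(win)), win]
    contrib = gfp2[ok] * r ** 2
    for m in range(len(a)):
        gev[m] = contrib[win == m].sum() / denom
    return labels, gev


def synthetic_microstate_series(n_states: int = 3, n_channels: int = 30,
                                n_segments: int = 12, segment_len: int = 30,
                                snr: float = 10.0,
                                seed: int | None = None,
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-truth map series for segmentation validation.

    States are random orthonormal average-referenced templates visited in
    round-robin order; each segment carries its own smooth amplitude
    envelope (0.6-1.4, independent of state identity, so no state is
    systematically weak); iid channel noise is scaled to the requested
    amplitude signal-to-noise ratio. Returns (series, templates, labels).
    """
    rng = np.random.default_rng(seed)
    t = rng.standard_normal((n_states, n_channels))
    t -= t.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(t.T)
    templates = q.T[:n_states]
    labels = np.concatenate([
        np.full(segment_len, i % n_states) for i in range(n_segments)])
    envs = []
    x = np.linspace(0, np.pi, segment_len)
    for _ in range(n_segments):
        peak = rng.uniform(0.6, 1.4)
        envs.append(0.5 + (peak - 0.5) * np.sin(x) ** 2)
    env = np.concatenate(envs)
    series = templates[labels] * env[:, None]
    # per-channel noise sd such that signal RMS / noise RMS = snr
    sig_rms = np.sqrt((series ** 2).mean())
    noise_sd = sig_rms / snr
    series = series + noise_sd * rng.standard_normal(series.shape)
    return series, templates, labels


def microstate_fit_table(erps_by_subject: dict[int, dict[str, "object"]],
                         templates: np.ndarray,
                         windows: dict[str, tuple[float, float]],
                         ) -> pd.DataFrame:
    """MicrostateFit rows: GEV of each template in each subject x condition
    x analysis window, back-fitting the subject's average-referenced ERP."""
    rows = []
    for subj, erps in erps_by_subject.items():
        for label, erp in erps.items():
            for wname, (lo, hi) in windows.items():
                sel = (erp.times_ms >= lo) & (erp.times_ms <= hi)
                maps = erp.data[:, sel].T
                _, gev = backfit(maps, templates)
                for m, g in enumerate(gev):
                    rows.append((subj, label, wname, m, float(g)))
    return pd.DataFrame(rows, columns=["subject", "condition", "window",
                                       "template", "gev"])


def microstate_anova(fit: pd.DataFrame, window: str,
                     factors: list[str] | None = None):
    """Repeated-measures ANOVA on GEV values within one analysis window.

    Adds configuration/numerosity factors parsed from the condition label
    and delegates to the rm_anova implementation.
    """
    from .anova import rm_anova

    work = fit[fit["window"] == window].copy()
    work["configuration"] = work["condition"].str[0]
    work["n_elements"] = work["condition"].str[1:].astype(int)
    if factors is None:
        factors = ["template", "configuration", "n_elements"]
    return rm_anova(work, "gev", "subject", factors)
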