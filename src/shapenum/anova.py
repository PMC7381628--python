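"""Repeated-measures ANOVA with Greenhouse-Geisser correction, partial
eta-squared, and Bonferroni-corrected paired post-hocs.

The implementation uses orthonormal within-subject contrasts: for an effect
A the per-subject data cube is projected with the Kronecker product of
orthonormal contrast bases (factors in A) and orthonormal averaging vectors
(factors not in A). With orthonormal projections,

    SS_effect = S * ||z_bar||^2,    SS_error = sum_s ||z_s - z_bar||^2,

which reproduces the classical univariate partitioning, and the
Greenhouse-Geisser epsilon of the effect is tr(Sigma)^2 / (df * tr(Sigma^2))
computed from the covariance of the projected scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class UnbalancedDesignError(ValueError):
    pass


@dataclass
class EffectResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon: float
    p_uncorrected: float
    p: float                     # GG-corrected when applicable
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult] = field(default_factory=dict)

    def __getitem__(self, key: str) -> EffectResult:
        return self.effects[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.effect, e.F, e.df_num, e.df_den, e.epsilon, e.p,
             e.partial_eta_sq)
            for e in self.effects.values()
        ]
        return pd.DataFrame(rows, columns=["effect", "F", "df_num", "df_den",
                                           "epsilon", "p", "partial_eta_sq"])


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    basis = np.eye(k) - 1.0 / k
    q, r = np.linalg.qr(basis.T)
    # drop the null direction (QR of a rank k-1 matrix): keep k-1 columns
    cols = [i for i in range(k) if abs(r[i, i]) > 1e-10]
    return q[:, cols[: k - 1]].T


def _data_cube(table: pd.DataFrame, dv: str, subject: str,
               factors: list[str]) -> tuple[np.ndarray, list[list]]:
    subjects = sorted(table[subject].unique())
    levels = [sorted(table[f].unique()) for f in factors]
    shape = (len(subjects),) + tuple(len(l) for l in levels)
    cube = np.full(shape, np.nan)
    idx_maps = [{v: i for i, v in enumerate(l)} for l in levels]
    smap = {v: i for i, v in enumerate(subjects)}
    grouped = table.groupby([subject] + factors, sort=False)[dv].mean()
    for key, val in grouped.items():
        key = key if isinstance(key, tuple) else (key,)
        pos = (smap[key[0]],) + tuple(m[k] for m, k in zip(idx_maps, key[1:]))
        cube[pos] = val
    if np.isnan(cube).any():
        raise UnbalancedDesignError("design has empty subject x cell entries")
    return cube, levels


def rm_anova(table: pd.DataFrame, dv: str, subject: str,
             within: list[str], gg_correction: bool = True) -> AnovaResult:
    """Fully-within repeated-measures ANOVA for 1-3 within factors.

    GG correction multiplies the degrees of freedom whenever an effect has
    more than one numerator df (i.e., some involved factor has > 2 levels).
    """
    cube, levels = _data_cube(table, dv, subject, within)
    S = cube.shape[0]
    if S < 2:
        raise UnbalancedDesignError("need at least 2 subjects")
    n_fac = len(within)
    result = AnovaResult()
    for r in range(1, n_fac + 1):
        for combo in itertools.combinations(range(n_fac), r):
            mats = []
            for f in range(n_fac):
                k = cube.shape[1 + f]
                if f in combo:
                    mats.append(_orthonormal_contrasts(k))
                else:
                    mats.append(np.full((1, k), 1.0 / np.sqrt(k)))
            proj = mats[0]
            for m in mats[1:]:
                proj = np.kron(proj, m)
            flat = cube.reshape(S, -1)
            z = flat @ proj.T                       # (S, df)
            zbar = z.mean(axis=0)
            df = z.shape[1]
            ss_eff = S * float(zbar @ zbar)
            resid = z - zbar
            ss_err = float((resid ** 2).sum())
            df_err = (S - 1) * df
            ms_eff = ss_eff / df
            ms_err = ss_err / df_err
            # degenerate case: no variance at all in the projected scores
            tol = 1e-12 * max(1.0, float((flat ** 2).sum()))
            if ss_eff < tol and ss_err < tol:
                F, ss_eff, ss_err = 0.0, 0.0, 0.0
            elif ms_err > 0:
                F = ms_eff / ms_err
            else:
                F = np.inf
            # effect-specific GG epsilon from the projected covariance
            if df > 1:
                sigma = (resid.T @ resid) / (S - 1)
                tr = np.trace(sigma)
                eps = (tr ** 2) / (df * float((sigma * sigma.T).sum()))
                eps = float(np.clip(eps, 1.0 / df, 1.0))
            else:
                eps = 1.0
            p_unc = float(stats.f.sf(F, df, df_err))
            if gg_correction and df > 1:
                p = float(stats.f.sf(F, df * eps, df_err * eps))
            else:
                p = p_unc
            name = " x ".join(within[i] for i in combo)
            result.effects[name] = EffectResult(
                effect=name, F=float(F), df_num=float(df), df_den=float(df_err),
                epsilon=eps, p_uncorrected=p_unc, p=p,
                partial_eta_sq=ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
                ss_effect=ss_eff, ss_error=ss_err,
            )
    return result


def bonferroni_posthoc(table: pd.DataFrame, dv: str, subject: str,
                       factor: str) -> pd.DataFrame:
    """All pairwise paired t-tests on subject-level means of ``factor``,
    with Bonferroni-multiplied p-values clipped at 1."""
    cell = table.groupby([subject, factor], sort=True)[dv].mean().unstack(factor)
    lvls = list(cell.columns)
    if len(lvls) < 2:
        raise ValueError("factor needs at least 2 levels")
    pairs = list(itertools.combinations(lvls, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(cell[a], cell[b])
        rows.append((a, b, float(t), float(p), float(min(1.0, p * m)),
                     float(cell[a].mean() - cell[b].mean())))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "t", "p_raw",
                                       "p_bonferroni", "mean_diff"])


def behavior_stats(behavior: pd.DataFrame,
                   factor_names: tuple[str, str] = ("configuration",
                                                    "n_elements"),
                   ) -> dict[str, AnovaResult]:
    """Accuracy and RT repeated-measures ANOVAs from a trial-level table.

    Cells are per-subject per-condition proportions correct and mean RTs;
    condition labels of the form 'S3'/'R5' are split into the configuration
    and numerosity factors.
    """
    if behavior["subject"].nunique() < 2:
        raise UnbalancedDesignError("need at least 2 subjects")
    work = behavior.copy()
    work["configuration"] = work["condition"].str[0]
    work["n_elements"] = work["condition"].str[1:].astype(int)
    agg = work.groupby(["subject", "configuration", "n_elements"]).agg(
        accuracy=("correct", "mean"), rt_ms=("rt_ms", "mean")).reset_index()
    res = {}
    for dv in ("accuracy", "rt_ms"):
        res[dv] = rm_anova(agg, dv, "subject", list(factor_names))
    return res
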