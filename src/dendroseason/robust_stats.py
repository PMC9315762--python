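"""Robust statistics for season-metric panels.

The experimental design is split-plot: treatment (control vs soil-heated)
varies between trees, year varies within trees.  Effects are tested with a
between-by-within ANOVA on 20%-trimmed means following Wilcox's method:
per-cell trimmed means, covariance of the trimmed-mean vectors estimated
from winsorized covariances as (n-1) S_w / (h (h-1)) with effective sample
size h = n - 2 floor(tr n), and a Johansen-type test statistic with a
Welch-style degrees-of-freedom approximation.  With trim = 0 and a single
within-subject level the treatment test reduces exactly to Welch's t².

Monotone association between metrics is measured with Spearman's rank
correlation (average ranks for ties, t-approximation for the p-value).

Significance stars follow the unusual published thresholds
(* < 0.1, ** < 0.01, *** < 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrimmedAnovaResult",
    "trimmed_mean",
    "winsorize",
    "bw_trimmed_anova",
    "spearman",
    "correlation_table",
    "p_stars",
]


@dataclass(frozen=True)
class TrimmedAnovaResult:
    effect: str  # treatment | year | interaction
    statistic: float
    df1: float
    df2: float
    p_value: float
    trim: float

    @property
    def stars(self) -> str:
        return p_stars(self.p_value)


def p_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def trimmed_mean(x, trim: float = 0.2) -> float:
    """Mean after removing the floor(trim * n) smallest and largest values."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    g = int(trim * n)
    if n - 2 * g < 1:
        raise ValueError(f"over-trimming: n={n}, trim={trim} leaves nothing")
    return float(stats.trim_mean(x, trim))


def winsorize(x: np.ndarray, trim: float) -> np.ndarray:
    """Replace the g = floor(trim*n) extreme values at each tail (per column)
    by the nearest retained order statistic."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    g = int(trim * n)
    if g == 0:
        return x.copy()
    srt = np.sort(x, axis=0)
    lo, hi = srt[g], srt[n - g - 1]
    return np.clip(x, lo, hi)


def _trimmed_mean_cov(x: np.ndarray, trim: float) -> np.ndarray:
    """Estimated covariance matrix of the column trimmed means of ``x``
    (subjects x variables): (n-1) S_winsorized / (h (h-1))."""
    n = x.shape[0]
    h = n - 2 * int(trim * n)
    xw = winsorize(x, trim)
    sw = np.cov(xw, rowvar=False, ddof=1)
    sw = np.atleast_2d(sw)
    return (n - 1) * sw / (h * (h - 1))


def _johansen(cmat: np.ndarray, tmeans: np.ndarray, v: np.ndarray,
              h: np.ndarray, K: int) -> tuple[float, float, float, float]:
    """Johansen-type test of C mu = 0 for trimmed means with covariance v
    (block-diagonal per between-group, block size K)."""
    cv = cmat @ v @ cmat.T
    try:
        inv = np.linalg.solve(cv, np.eye(cv.shape[0]))
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(cv)
    y = tmeans.reshape(-1, 1)
    stat = (y.T @ cmat.T @ inv @ cmat @ y).item()
    mtem = v @ cmat.T @ inv @ cmat
    J = len(h)
    a = 0.0
    for j in range(J):
        q = np.zeros_like(v)
        sl = slice(j * K, (j + 1) * K)
        q[sl, sl] = np.eye(K)
        mq = mtem @ q
        a += (np.trace(mq @ mq) + np.trace(mq) ** 2) / (h[j] - 1)
    a *= 0.5
    df1 = float(cmat.shape[0])
    cval = df1 + 2 * a - 6 * a / (df1 + 2)
    stat = stat / cval
    df2 = df1 * (df1 + 2) / (3 * a) if a > 0 else np.inf
    p = float(stats.f.sf(stat, df1, df2)) if np.isfinite(df2) else float(
        stats.chi2.sf(stat * df1, df1))
    return stat, df1, df2, p


def _group_matrices(panel: pd.DataFrame, metric: str, tree_col: str,
                    treatment_col: str, year_col: str
                    ) -> tuple[list[np.ndarray], list[str], list]:
    wide = panel.pivot_table(index=[treatment_col, tree_col], columns=year_col,
                             values=metric, aggfunc="first")
    n_before = wide.shape[0]
    wide = wide.dropna(axis=0, how="any")  # complete cases per subject
    dropped = n_before - wide.shape[0]
    if dropped:
        warnings.warn(f"bw_trimmed_anova: dropped {dropped} subjects with "
                      f"incomplete '{metric}' records", stacklevel=3)
    groups = sorted(wide.index.get_level_values(0).unique())
    mats = [wide.loc[gname].to_numpy(dtype=float) for gname in groups]
    return mats, list(groups), list(wide.columns)


def bw_trimmed_anova(panel: pd.DataFrame, metric: str, trim: float = 0.2,
                     tree_col: str = "tree_id", treatment_col: str = "treatment",
                     year_col: str = "year") -> dict[str, TrimmedAnovaResult]:
    """Between (treatment) x within (year) ANOVA on trimmed means.

    ``panel`` is tidy: one row per tree-year.  Subjects with a missing year
    are dropped (complete-case) with a warning.  Returns results for the
    ``treatment``, ``year`` and ``interaction`` effects.
    """
    if not 0.0 <= trim <= 0.25:
        raise ValueError("trim must be in [0, 0.25]")
    mats, groups, years = _group_matrices(panel, metric, tree_col,
                                          treatment_col, year_col)
    J, K = len(mats), len(years)
    if J < 2:
        raise ValueError("need at least 2 treatment groups")
    for gname, m in zip(groups, mats):
        if m.shape[0] < 2:
            raise ValueError(f"treatment {gname!r} has fewer than 2 complete trees")
    allvals = np.concatenate([m.ravel() for m in mats])
    if np.ptp(allvals) == 0:
        # degenerate: every observation identical
        out = {}
        for eff, df1 in (("treatment", J - 1), ("year", K - 1),
                         ("interaction", (J - 1) * (K - 1))):
            out[eff] = TrimmedAnovaResult(eff, 0.0, float(df1), np.inf, 1.0, trim)
        return out
    tmeans = np.concatenate([
        np.array([trimmed_mean(m[:, k], trim) for k in range(K)]) for m in mats])
    p = J * K
    v = np.zeros((p, p))
    h = np.zeros(J)
    for j, m in enumerate(mats):
        sl = slice(j * K, (j + 1) * K)
        v[sl, sl] = _trimmed_mean_cov(m, trim)
        h[j] = m.shape[0] - 2 * int(trim * m.shape[0])
    ones_k = np.ones((1, K))
    ones_j = np.ones((1, J))
    cj = np.eye(J - 1, J) - np.eye(J - 1, J, k=1)
    ck = np.eye(K - 1, K) - np.eye(K - 1, K, k=1)
    contrasts = {
        "treatment": np.kron(cj, ones_k),
        "year": np.kron(ones_j, ck),
        "interaction": np.kron(cj, ck),
    }
    out = {}
    for eff, cmat in contrasts.items():
        if cmat.shape[0] == 0:
            continue
        stat, df1, df2, pval = _johansen(cmat, tmeans, v, h, K)
        out[eff] = TrimmedAnovaResult(eff, stat, df1, df2, pval, trim)
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p-value from
    the t-approximation.  Constant input yields (nan, nan) with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman: constant input, correlation undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationMatrix:
    metrics: list[str]
    rho: pd.DataFrame
    p_value: pd.DataFrame
    n: int

    def markdown(self) -> str:
        cells = self.rho.copy().astype(object)
        for a in self.metrics:
            for b in self.metrics:
                r, p = self.rho.loc[a, b], self.p_value.loc[a, b]
                cells.loc[a, b] = f"{r:.2f} {p_stars(p)}".strip()
        return cells.to_markdown()


def correlation_table(panel: pd.DataFrame, metrics: list[str]) -> CorrelationMatrix:
    """Pairwise Spearman correlations among metric columns of a tidy panel
    (complete cases across the listed metrics)."""
    sub = panel[metrics].dropna()
    n = len(sub)
    rho = pd.DataFrame(np.eye(len(metrics)), index=metrics, columns=metrics)
    pv = pd.DataFrame(np.zeros((len(metrics), len(metrics))),
                      index=metrics, columns=metrics)
    for i, a in enumerate(metrics):
        for b in metrics[i + 1:]:
            r, p = spearman(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pv.loc[a, b] = pv.loc[b, a] = p
    return CorrelationMatrix(metrics, rho, pv, n)
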