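"""Shared statistical machinery.

Spearman rank correlation across all feature pairs, Benjamini-Yekutieli
false-discovery-rate control (valid under arbitrary dependence, which the
heavily correlated mutational features require), the Wilcoxon rank-sum test
with continuity correction, and the Pearson chi-squared test on 2x2 tables.
Each multiple-testing family is corrected jointly (all correlation pairs as
one family; all cluster-by-feature association tests as another).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def benjamini_yekutieli(p_values) -> np.ndarray:
    """BY step-up adjusted p-values (harmonic-factor c(m) = sum 1/i, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with tie and continuity correction.

    Returns the rank-sum statistic W of the first group and the two-sided
    normal-approximation p-value.  Fully tied data yields p = 1 with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1 = x.size
    w_stat = float(sps.rankdata(np.concatenate([x, y]))[:n1].sum())
    if np.unique(np.concatenate([x, y])).size == 1:
        log.warning("all values tied across both groups; p set to 1")
        return w_stat, 1.0
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return w_stat, float(res.pvalue)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def spearman_test(x, y, seed: int = 0) -> tuple[float, float]:
    """Spearman correlation of one pair with a sample-size-aware p-value.

    Uses the t-approximation with average ranks for ties; below n = 10 the
    approximation is poor, so the p-value comes from a permutation test
    instead (exact when the permutation space is small enough for scipy to
    enumerate it).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    r, p = sps.spearmanr(x, y)
    if x.size < 10:
        def _stat(perm_y):
            return sps.spearmanr(x, perm_y).statistic

        res = sps.permutation_test(
            (y,), _stat, permutation_type="pairings",
            alternative="two-sided", n_resamples=100000,
            rng=np.random.default_rng(seed),
        )
        p = float(res.pvalue)
    return float(r), float(p)


@dataclass
class CorrelationMatrix:
    """All pairwise Spearman correlations with BY-adjusted significance."""

    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_adjusted <= self.alpha

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered feature pair."""
        cols = list(self.r.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append((a, b, self.r.loc[a, b], self.p_raw.loc[a, b],
                             self.p_adjusted.loc[a, b],
                             bool(self.p_adjusted.loc[a, b] <= self.alpha)))
        return pd.DataFrame(
            rows, columns=["feature_a", "feature_b", "r_s", "p_raw", "p_by", "significant"]
        )


def spearman_matrix(values: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Spearman correlation between all columns, BY-corrected over all pairs.

    Constant columns have undefined correlations; those entries are reported
    as NaN with a warning and excluded from the correction family.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 samples")
    cols = list(values.columns)
    constant = [c for c in cols if values[c].nunique() <= 1]
    if constant:
        log.warning("constant columns with undefined correlations: %s", constant)
    usable = [c for c in cols if c not in constant]
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    if len(usable) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_sub, p_sub = sps.spearmanr(values[usable].to_numpy(), axis=0)
        if np.ndim(r_sub) == 0:  # scipy returns scalars for exactly two columns
            r_sub = np.array([[1.0, r_sub], [r_sub, 1.0]])
            p_sub = np.array([[0.0, p_sub], [p_sub, 0.0]])
        r.loc[usable, usable] = r_sub
        p.loc[usable, usable] = p_sub
    for c in usable:
        r.loc[c, c] = 1.0
        p.loc[c, c] = 0.0
    iu = np.triu_indices(len(cols), k=1)
    raw = p.values[iu]
    ok = ~np.isnan(raw)
    adj_flat = np.full_like(raw, np.nan)
    if ok.any():
        adj_flat[ok] = benjamini_yekutieli(raw[ok])
    adj = np.full(p.shape, np.nan)
    adj[iu] = adj_flat
    adj[(iu[1], iu[0])] = adj_flat
    np.fill_diagonal(adj, 0.0)
    return CorrelationMatrix(
        r=r, p_raw=p, p_adjusted=pd.DataFrame(adj, index=cols, columns=cols),
        n=len(values), alpha=alpha,
    )
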