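"""Two-group and k-group hypothesis tests and the differential-abundance screen.

Wraps the standard tests (Mann-Whitney U, Welch's t, Kruskal-Wallis) and
adds Dunn's post-hoc comparisons with Holm-Sidak adjustment plus the
genus-level Welch/Benjamini-Hochberg screen that defines the PBB-up and
PBB-down sets (genera whose abundance rises or falls with pesticide risk).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ingest import CommunityProfile
from .results import TestResult


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test with midrank ties.

    Uses the exact null distribution when the combined sample size is at
    most 12 and no ties are present; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample vector")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method=f"Mann-Whitney U ({method})",
    )


def welch_t(x, y) -> TestResult:
    """Welch's two-sided t-test (unequal variances).

    t = (mx - my) / sqrt(sx^2/nx + sy^2/ny) with Welch-Satterthwaite
    degrees of freedom. Degenerate inputs (zero variance in both groups)
    resolve to t = 0, p = 1 when the means agree, and p = 0 with a
    warning when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, p_value=1.0, method="Welch t")
        warnings.warn("zero variance in both groups with unequal means")
        return TestResult(statistic=np.inf, p_value=0.0, method="Welch t")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="Welch t", df=float(res.df),
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def holm_sidak(p) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sorted ascending, adj_(i) = max_{j <= i} 1 - (1 - p_(j))^(m - j + 1),
    clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-squared p (k-1 df).

    All pooled values identical resolves to H = 0, p = 1 rather than an
    undefined statistic.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    k = len(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0,
                          method="Kruskal-Wallis", df=float(k - 1))
    res = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="Kruskal-Wallis", df=float(k - 1),
    )


def dunn_posthoc(groups: Sequence, labels: Optional[Sequence] = None) -> list:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values, Holm-Sidak adjusted across the k(k-1)/2 pairs. Identical
    data across all groups gives adjusted p = 1 everywhere.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in arrays]
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start:start + n_i].mean())
        start += n_i
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - T

    pairs, zs, ps = [], [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if denom == 0:
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / denom
            pairs.append((labels[i], labels[j]))
            zs.append(z)
            ps.append(2.0 * sps.norm.sf(abs(z)))
    adj = holm_sidak(ps)
    results = []
    for (a, b), z, p_raw, q in zip(pairs, zs, ps, adj):
        results.append(
            TestResult(
                statistic=float(z), p_value=float(p_raw), q_value=float(q),
                method="Dunn (Holm-Sidak)", extra={"pair": (a, b)},
            )
        )
    return results


# ---------------------------------------------------------------------------
# Differential-abundance screen


def _vectorized_welch(X1: np.ndarray, X2: np.ndarray):
    """Welch t, df, two-sided p for every row of two sample blocks."""
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = np.where(np.isfinite(t), 2.0 * sps.t.sf(np.abs(t), np.where(df > 0, df, 1)), 1.0)
    # zero variance in both groups: equal means -> p = 1; unequal -> p = 0
    degenerate = se2 == 0
    equal_means = degenerate & (m1 == m2)
    diff_means = degenerate & (m1 != m2)
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    p = np.where(diff_means, 0.0, p)
    df = np.where(degenerate, np.nan, df)
    return t, df, p, m1, m2


def differential_abundance(
    profile: CommunityProfile,
    groups: pd.Series,
    low_label: str = "low",
    high_label: str = "high",
    q_threshold: float = 0.05,
    prevalence_min: float = 0.05,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-genus Welch screen between low- and high-risk samples.

    Genera present (nonzero) in at least ``prevalence_min`` of the
    retained samples are tested with a two-sided Welch t-test
    (high vs low); p-values are Benjamini-Hochberg adjusted across tested
    genera and direction is called at q < ``q_threshold``: ``up`` when
    the high-risk mean exceeds the low-risk mean, ``down`` when it falls
    below, ``none`` otherwise. Set ``adjust=False`` to threshold raw
    p-values instead. Rarer genera are reported untested (``tested``
    False, direction ``none``).

    Returns a table indexed by genus with columns mean_low, mean_high,
    t, df, p, q, direction, tested.
    """
    if profile.units != "RPM":
        raise ValueError("differential screen expects an RPM profile")
    groups = groups.reindex(profile.samples)
    low_ids = groups.index[groups == low_label]
    high_ids = groups.index[groups == high_label]
    if len(low_ids) < 2 or len(high_ids) < 2:
        raise ValueError("need >= 2 samples in both the low and high groups")
    sub = profile.matrix[list(low_ids) + list(high_ids)]
    prevalence = (sub > 0).mean(axis=1)
    tested_mask = prevalence >= prevalence_min

    X_low = profile.matrix[low_ids].values
    X_high = profile.matrix[high_ids].values
    t, df, p, m_high, m_low = _vectorized_welch(X_high, X_low)

    out = pd.DataFrame(
        {
            "mean_low": m_low,
            "mean_high": m_high,
            "t": t,
            "df": df,
            "p": p,
            "tested": tested_mask.values,
        },
        index=profile.matrix.index,
    )
    out.loc[~out["tested"], ["t", "df", "p"]] = np.nan
    out["q"] = np.nan
    if out["tested"].any():
        out.loc[out["tested"], "q"] = bh_fdr(out.loc[out["tested"], "p"].values)
    crit = out["q"] if adjust else out["p"]
    sig = out["tested"] & (crit < q_threshold)
    direction = np.where(
        sig & (out["mean_high"] > out["mean_low"]), "up",
        np.where(sig & (out["mean_high"] < out["mean_low"]), "down", "none"),
    )
    out["direction"] = direction
    out.index.name = "genus"
    return out
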