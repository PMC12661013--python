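"""Alpha diversity, Bray-Curtis dissimilarity, and PERMANOVA.

Richness and Shannon diversity are computed per sample on the PBB
sub-community; beta diversity uses Bray-Curtis dissimilarities, and
group differences in composition are tested with a sequential (Type-I)
multi-factor PERMANOVA under whole-sample label permutations.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import CommunityProfile
from .results import TestResult


def richness(profile: CommunityProfile) -> pd.Series:
    """Number of genera with abundance > 0 per sample."""
    s = (profile.matrix > 0).sum(axis=0).astype(int)
    s.name = "richness"
    return s


def shannon(profile: CommunityProfile, base: Optional[float] = None) -> pd.Series:
    """Shannon diversity H' = -sum p_i ln p_i per sample.

    Natural log by default (pass ``base=2`` for bits). Samples with zero
    total abundance, or a single nonzero genus, get H' = 0.
    """
    X = profile.matrix.values.astype(float)
    totals = X.sum(axis=0)
    H = np.zeros(X.shape[1])
    nz = totals > 0
    if nz.any():
        P = X[:, nz] / totals[nz]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(P > 0, P * np.log(P), 0.0)
        H[nz] = -terms.sum(axis=0)
    if base is not None:
        H = H / np.log(base)
    out = pd.Series(H, index=profile.samples, name="shannon")
    return out


def diversity_table(profile: CommunityProfile) -> pd.DataFrame:
    """Per-sample richness and Shannon index, as one table."""
    return pd.DataFrame({"richness": richness(profile), "shannon": shannon(profile)})


def bray_curtis_matrix(profile: CommunityProfile) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(x, y) = sum |x_i - y_i| / sum (x_i + y_i); a pair of all-zero
    samples is assigned 0 by convention (identical emptiness).
    """
    X = profile.matrix.values.T.astype(float)  # samples x genera
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i + 1:] - X[i]).sum(axis=1)
        tot = (X[i + 1:] + X[i]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(tot > 0, diff / tot, 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return pd.DataFrame(D, index=profile.samples, columns=profile.samples)


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D * D
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def _dummy_design(labels: np.ndarray) -> np.ndarray:
    """Full-rank dummy columns (drop-first) for one categorical factor."""
    levels = pd.unique(labels)
    cols = [labels == lv for lv in levels[1:]]
    if not cols:
        return np.empty((len(labels), 0))
    return np.column_stack(cols).astype(float)


def _sequential_ss(G: np.ndarray, factor_labels: Sequence[np.ndarray]):
    """Sequential (Type-I) sums of squares by cumulative projection.

    Returns per-factor SS, per-factor df, residual SS, residual df.
    """
    n = G.shape[0]
    X = np.ones((n, 1))
    prev_trace = 0.0  # intercept projects centered G to 0
    ss, dfs = [], []
    rank_prev = 1
    for labels in factor_labels:
        X = np.column_stack([X, _dummy_design(labels)])
        Q, R = np.linalg.qr(X)
        rank = int((np.abs(np.diag(R)) > 1e-10).sum())
        H = Q[:, :rank] @ Q[:, :rank].T
        tr = float(np.trace(H @ G))
        ss.append(tr - prev_trace)
        dfs.append(rank - rank_prev)
        prev_trace = tr
        rank_prev = rank
    ss_total = float(np.trace(G))
    ss_res = ss_total - prev_trace
    df_res = n - rank_prev
    return np.array(ss), np.array(dfs), ss_res, df_res, ss_total


def permanova(
    D: pd.DataFrame,
    factors: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> list:
    """Sequential multi-factor PERMANOVA on a distance matrix.

    Partitions the Gower-centered inner-product matrix G = -1/2 J (D*D) J
    into sequential (Type-I) sums of squares along the ordered factor
    columns of ``factors``; each factor gets a pseudo-F against the
    residual mean square and a permutation p-value from whole-sample
    label permutations, with the add-one estimator
    p = (1 + #{F* >= F_obs}) / (1 + n_permutations).

    Returns one :class:`TestResult` per factor, in order; ``effect``
    carries R^2 = SS_factor / SS_total.
    """
    Dv = np.asarray(D, dtype=float)
    if np.isnan(Dv).any():
        raise ValueError("distance matrix contains NaN")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    n = Dv.shape[0]
    labels = [np.asarray(factors[c]) for c in factors.columns]
    for c, lab in zip(factors.columns, labels):
        if len(pd.unique(lab)) < 2:
            raise ValueError(f"factor {c!r} has a single level")
    G = _gower_center(Dv)
    ss, dfs, ss_res, df_res, ss_total = _sequential_ss(G, labels)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = ss_res / df_res
    F_obs = (ss / dfs) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(labels))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        perm_labels = [lab[perm] for lab in labels]
        ss_p, dfs_p, ss_res_p, df_res_p, _ = _sequential_ss(G, perm_labels)
        F_p = (ss_p / dfs_p) / (ss_res_p / df_res_p)
        exceed += F_p >= F_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)

    results = []
    for i, c in enumerate(factors.columns):
        results.append(
            TestResult(
                statistic=float(F_obs[i]),
                p_value=float(p[i]),
                method="PERMANOVA (sequential)",
                df=float(dfs[i]),
                effect=float(ss[i] / ss_total),
                n_permutations=n_permutations,
                extra={
                    "factor": c,
                    "ss": float(ss[i]),
                    "ss_residual": float(ss_res),
                    "df_residual": float(df_res),
                    "ss_total": float(ss_total),
                },
            )
        )
    return results
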