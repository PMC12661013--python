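"""Spatial structure: geographic distances, Mantel tests, PCNM, db-RDA.

Soil samples collected near each other tend to share community
composition (distance decay), so an apparent pesticide effect can be a
spatial artifact. This module provides the control battery: Mantel and
partial Mantel permutation tests between distance matrices, principal
coordinates of neighbour matrices (PCNM) as spatial covariates, and
distance-based redundancy analysis (db-RDA) that tests a constraint
after partialling out the spatial eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .results import TestResult

EARTH_RADIUS_KM = 6371.0088


def geodesic_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Haversine great-circle distances (km) between sample coordinates.

    ``coords`` must have ``latitude`` and ``longitude`` columns in decimal
    degrees (WGS84), indexed by sample id.
    """
    lat = np.asarray(coords["latitude"], dtype=float)
    lon = np.asarray(coords["longitude"], dtype=float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (np.abs(lon) > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    D = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=coords.index, columns=coords.index)


def _upper(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def mantel(
    A: pd.DataFrame,
    B: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> TestResult:
    """Mantel permutation correlation between two distance matrices.

    r_M is the Pearson correlation over the n(n-1)/2 upper-triangle
    entries; significance comes from simultaneous row/column permutations
    of B with the add-one estimator. The default alternative is
    ``"greater"`` (positive association, the usual distance-decay
    hypothesis); ``"two-sided"`` compares |r*| with |r_obs|.
    """
    Av, Bv = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if Av.shape != Bv.shape:
        raise ValueError("distance matrices differ in size")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    n = Av.shape[0]
    a = _upper(Av)
    r_obs = _pearson(a, _upper(Bv))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = _pearson(a, _upper(Bv[np.ix_(perm, perm)]))
        if alternative == "greater":
            exceed += r_p >= r_obs
        else:
            exceed += abs(r_p) >= abs(r_obs)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return TestResult(
        statistic=r_obs, p_value=p, method=f"Mantel ({alternative})",
        n_permutations=n_permutations,
    )


def partial_mantel(
    A: pd.DataFrame,
    B: pd.DataFrame,
    C: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> TestResult:
    """Partial Mantel test of A vs B controlling for C.

    Uses the first-order partial correlation
    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))
    over upper-triangle entries, permuting B as in :func:`mantel`.
    A control matrix perfectly collinear with A or B is degenerate.
    """
    Av = np.asarray(A, dtype=float)
    Bv = np.asarray(B, dtype=float)
    Cv = np.asarray(C, dtype=float)
    if not (Av.shape == Bv.shape == Cv.shape):
        raise ValueError("distance matrices differ in size")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    n = Av.shape[0]
    a, c = _upper(Av), _upper(Cv)
    r_ac = _pearson(a, c)
    if abs(r_ac) >= 1.0 - 1e-12:
        raise ValueError("control matrix collinear with A (|r| = 1)")

    def partial_r(b: np.ndarray) -> float:
        r_ab = _pearson(a, b)
        r_bc = _pearson(b, c)
        if abs(r_bc) >= 1.0 - 1e-12:
            raise ValueError("control matrix collinear with B (|r| = 1)")
        return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    r_obs = partial_r(_upper(Bv))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = partial_r(_upper(Bv[np.ix_(perm, perm)]))
        if alternative == "greater":
            exceed += r_p >= r_obs
        else:
            exceed += abs(r_p) >= abs(r_obs)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return TestResult(
        statistic=float(r_obs), p_value=p,
        method=f"partial Mantel ({alternative})", n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# PCNM


@dataclass
class PCNMBasis:
    """Positive spatial eigenvectors from a truncated distance matrix."""

    axes: pd.DataFrame          # sample x axis, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray     # descending, all > 0
    truncation_threshold: float  # km; longest MST edge

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]


def _mst_max_edge(D: np.ndarray) -> float:
    mst = minimum_spanning_tree(D)
    return float(mst.toarray().max())


def pcnm(D_geo: pd.DataFrame) -> PCNMBasis:
    """Principal coordinates of neighbour matrices.

    The truncation threshold t is the longest edge of the minimum
    spanning tree of the geographic distance matrix (the smallest t
    keeping all samples connected). Distances beyond t are replaced by
    4t, the truncated matrix is Gower-centered and eigendecomposed, and
    the positive-eigenvalue axes, scaled by the square root of their
    eigenvalues, form the spatial basis.
    """
    Dv = np.asarray(D_geo, dtype=float)
    n = Dv.shape[0]
    if n < 3:
        raise ValueError("PCNM requires at least 3 samples")
    off = _upper(Dv)
    if np.all(off == 0):
        raise ValueError("all sample locations identical")
    t = _mst_max_edge(Dv)
    Dt = Dv.copy()
    Dt[Dt > t] = 4.0 * t
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt * Dt
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), abs(vals[-1])) * 1e-10
    keep = vals > tol
    vals, vecs = vals[keep], vecs[:, keep]
    axes = vecs * np.sqrt(vals)
    cols = [f"PCNM{i + 1}" for i in range(axes.shape[1])]
    return PCNMBasis(
        axes=pd.DataFrame(axes, index=D_geo.index, columns=cols),
        eigenvalues=vals,
        truncation_threshold=t,
    )


# ---------------------------------------------------------------------------
# db-RDA


def _pcoa_embedding(D: np.ndarray) -> np.ndarray:
    """Principal-coordinate embedding, dropping negative-eigenvalue axes."""
    n = D.shape[0]
    A = -0.5 * D * D
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), abs(vals[-1]), 1.0) * 1e-12
    keep = vals > tol
    return vecs[:, keep] * np.sqrt(vals[keep])


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of M after least-squares projection on [1, Z]."""
    n = M.shape[0]
    X = np.column_stack([np.ones(n), Z]) if Z is not None else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def _rank(X: np.ndarray) -> int:
    if X.size == 0:
        return 0
    return int(np.linalg.matrix_rank(X))


def dbrda(
    D: pd.DataFrame,
    constraint,
    covariates: Optional[PCNMBasis] = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> TestResult:
    """Distance-based redundancy analysis with optional spatial covariates.

    The distance matrix is embedded by principal coordinates (negative
    axes dropped); covariate columns (e.g. PCNM axes) are regressed out
    of both the embedding and the constraint, and the fraction of
    remaining inertia explained by the constraint gives R^2 with a
    pseudo-F. Significance is assessed by permuting the residuals of the
    reduced (covariates-only) model, add-one estimator.
    """
    Dv = np.asarray(D, dtype=float)
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    n = Dv.shape[0]
    X = np.asarray(constraint, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constraint is constant across samples")
    Z = None
    n_cov = 0
    if covariates is not None:
        Z = np.asarray(covariates.axes, dtype=float)
        n_cov = _rank(Z)

    Y = _pcoa_embedding(Dv)
    Yr = _residualize(Y, Z)
    Xr = _residualize(X, Z)
    q = _rank(Xr)
    if q == 0:
        raise ValueError("constraint lies entirely in the covariate space")
    df_res = n - 1 - n_cov - q
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def constrained_ss(Ym: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(Xr, Ym, rcond=None)
        fitted = Xr @ coef
        return float((fitted * fitted).sum())

    ss_total = float((Yr * Yr).sum())
    ss_c = constrained_ss(Yr)
    ss_res = ss_total - ss_c
    F_obs = (ss_c / q) / (ss_res / df_res)
    r2 = ss_c / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Yp = Yr[perm]
        ss_cp = constrained_ss(Yp)
        F_p = (ss_cp / q) / ((ss_total - ss_cp) / df_res)
        exceed += F_p >= F_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return TestResult(
        statistic=float(F_obs), p_value=p, method="db-RDA",
        df=float(q), effect=float(r2), n_permutations=n_permutations,
        extra={"ss_constrained": ss_c, "ss_total": ss_total,
               "n_covariate_axes": n_cov},
    )
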