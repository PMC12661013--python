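import itertools

import numpy as np
import pandas as pd
import pytest

from pbbsoil.spatial import (
    EARTH_RADIUS_KM,
    dbrda,
    geodesic_distance_matrix,
    mantel,
    partial_mantel,
    pcnm,
)


def _coords(lat, lon):
    return pd.DataFrame({"latitude": lat, "longitude": lon})


def _dm(points):
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return pd.DataFrame(d)


class TestGeodesic:
    def test_closed_form_quarter_and_half_circle(self):
        D = geodesic_distance_matrix(_coords([0, 90, 0], [0, 0, 180]))
        quarter = np.pi * EARTH_RADIUS_KM / 2
        assert D.iloc[0, 0] == 0.0
        assert D.iloc[0, 1] == pytest.approx(quarter, abs=1e-6)
        assert D.iloc[0, 2] == pytest.approx(2 * quarter, abs=1e-6)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            geodesic_distance_matrix(_coords([91], [0]))
        with pytest.raises(ValueError, match="longitude"):
            geodesic_distance_matrix(_coords([0], [181]))

    def test_symmetry_and_triangle_inequality(self, rng):
        D = geodesic_distance_matrix(
            _coords(rng.uniform(-80, 80, 15), rng.uniform(-170, 170, 15))
        ).values
        np.testing.assert_allclose(D, D.T, atol=1e-9)
        for i, j, k in itertools.combinations(range(15), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-6


class TestMantel:
    def test_affine_transform_gives_r_one(self, rng):
        A = _dm(rng.standard_normal((10, 2)))
        B = A * 3.0 + 2.0
        B.values[np.diag_indices(10)] = 0.0
        res = mantel(A, B, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_self_comparison_hits_p_floor(self, rng):
        A = _dm(rng.standard_normal((12, 2)))
        res = mantel(A, A, n_permutations=999, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_r_matches_enumerated_pair_oracle(self, rng):
        A = _dm(rng.standard_normal((5, 2)))
        B = _dm(rng.standard_normal((5, 2)))
        pairs_a = [A.iloc[i, j] for i in range(5) for j in range(i + 1, 5)]
        pairs_b = [B.iloc[i, j] for i in range(5) for j in range(i + 1, 5)]
        r_oracle = np.corrcoef(pairs_a, pairs_b)[0, 1]
        res = mantel(A, B, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(r_oracle, abs=1e-12)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="size"):
            mantel(_dm(rng.standard_normal((5, 2))),
                   _dm(rng.standard_normal((6, 2))), 99, 0)


class TestPartialMantel:
    def test_reduces_to_simple_mantel_when_control_uncorrelated(self, rng):
        A = _dm(rng.standard_normal((50, 2)))
        B = _dm(A.values[:, :1] + 0.3 * rng.standard_normal((50, 1)))
        C = _dm(rng.standard_normal((50, 2)))
        simple = mantel(A, B, 99, 0).statistic
        partial = partial_mantel(A, B, C, 99, 0).statistic
        assert abs(simple - partial) < 0.05

    def test_matches_hand_partial_correlation_formula(self, rng):
        A = _dm(rng.standard_normal((6, 2)))
        B = _dm(rng.standard_normal((6, 2)))
        C = _dm(rng.standard_normal((6, 2)))
        iu = np.triu_indices(6, 1)
        a, b, c = A.values[iu], B.values[iu], C.values[iu]
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        oracle = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        res = partial_mantel(A, B, C, 99, 0)
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_collinear_control_rejected(self, rng):
        A = _dm(rng.standard_normal((6, 2)))
        B = _dm(rng.standard_normal((6, 2)))
        with pytest.raises(ValueError, match="collinear"):
            partial_mantel(A, B, A.copy(), 99, 0)

    def test_spatial_confounding_is_absorbed(self, rng):
        # B generated purely from space C: simple test fires, partial does not
        n = 40
        hits_simple, miss_partial = 0, 0
        reps = 20
        for rep in range(reps):
            local = np.random.default_rng(1000 + rep)
            pts = local.standard_normal((n, 2))
            C = _dm(pts)
            B = C * 2.0 + _dm(local.standard_normal((n, 2))) * 0.05
            B.values[np.diag_indices(n)] = 0.0
            A = C * 1.5 + _dm(local.standard_normal((n, 2))) * 0.05
            A.values[np.diag_indices(n)] = 0.0
            if mantel(A, B, 99, rep).p_value <= 0.05:
                hits_simple += 1
            if partial_mantel(A, B, C, 99, rep).p_value > 0.05:
                miss_partial += 1
        assert hits_simple == reps
        assert miss_partial >= 0.9 * reps


class TestPCNM:
    def test_line_transect_axis_count_matches_eigen_oracle(self):
        # 10 equally spaced points on a line
        coords = _coords([0.0] * 10, np.arange(10) * 0.1)
        D = geodesic_distance_matrix(coords)
        basis = pcnm(D)
        # independent oracle: full eigendecomposition of the truncated,
        # Gower-centered matrix built from scratch
        Dv = D.values.copy()
        t = basis.truncation_threshold
        Dt = np.where(Dv > t, 4 * t, Dv)
        np.fill_diagonal(Dt, 0.0)
        n = 10
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (Dt * Dt) @ J
        vals = np.linalg.eigvalsh(G)
        n_positive = int((vals > np.abs(vals).max() * 1e-10).sum())
        assert basis.n_axes == n_positive
        # first axis is sinusoid-like along the transect: one sign change
        v1 = basis.axes.values[:, 0]
        assert np.sum(np.diff(np.sign(v1)) != 0) == 1

    def test_retained_eigenvalues_positive(self, rng):
        coords = _coords(rng.uniform(0, 5, 12), rng.uniform(0, 5, 12))
        basis = pcnm(geodesic_distance_matrix(coords))
        assert (basis.eigenvalues > 0).all()

    def test_truncation_is_mst_max_edge_on_square(self):
        # unit square in degrees at the equator: MST uses three sides
        coords = _coords([0, 0, 1, 1], [0, 1, 0, 1])
        D = geodesic_distance_matrix(coords)
        basis = pcnm(D)
        # brute force: minimal spanning tree over all 16 labelled trees
        # (Cayley) of 4 nodes; the max edge of the best tree
        best = None
        nodes = range(4)
        Dv = D.values
        for edges in itertools.combinations(itertools.combinations(nodes, 2), 3):
            cover = set()
            for e in edges:
                cover |= set(e)
            if len(cover) < 4:
                continue
            # check connectivity
            comp = {0}
            grown = True
            while grown:
                grown = False
                for a, b in edges:
                    if (a in comp) != (b in comp):
                        comp |= {a, b}
                        grown = True
            if len(comp) < 4:
                continue
            weight = sum(Dv[a, b] for a, b in edges)
            if best is None or weight < best[0]:
                best = (weight, max(Dv[a, b] for a, b in edges))
        assert basis.truncation_threshold == pytest.approx(best[1], abs=1e-9)

    def test_axes_centered_and_orthogonal(self, rng):
        coords = _coords(rng.uniform(0, 3, 15), rng.uniform(0, 3, 15))
        basis = pcnm(geodesic_distance_matrix(coords))
        A = basis.axes.values
        assert np.abs(A.mean(axis=0)).max() < 1e-8
        gram = A.T @ A
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            pcnm(pd.DataFrame(np.zeros((4, 4))))
        with pytest.raises(ValueError, match="3 samples"):
            pcnm(pd.DataFrame([[0.0, 1.0], [1.0, 0.0]]))


class TestDbRDA:
    def test_matches_classical_rda_under_euclidean_distance(self, rng):
        n, p = 25, 5
        Y = rng.standard_normal((n, p))
        x = Y[:, 0] + rng.standard_normal(n)
        D = _dm(Y)
        res = dbrda(D, x, n_permutations=99, seed=0)
        Yc = Y - Y.mean(0)
        X = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(X, Yc, rcond=None)
        fitted = X @ coef
        r2_oracle = (fitted**2).sum() / (Yc**2).sum()
        assert res.effect == pytest.approx(r2_oracle, abs=1e-8)

    def test_planted_gradient_hits_permutation_floor(self, rng):
        n = 40
        grad = np.linspace(0, 1, n)
        Y = np.column_stack([5 * grad, rng.standard_normal(n) * 0.05])
        res = dbrda(_dm(Y), grad, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_constant_constraint_rejected(self, rng):
        D = _dm(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="constant"):
            dbrda(D, np.ones(10), n_permutations=99, seed=0)

    def test_null_constraint_not_significant(self, rng):
        # constraint independent of the community structure
        nonsig = 0
        reps = 20
        for rep in range(reps):
            local = np.random.default_rng(2000 + rep)
            D = _dm(local.standard_normal((30, 4)))
            x = local.standard_normal(30)
            if dbrda(D, x, n_permutations=99, seed=rep).p_value > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * reps
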