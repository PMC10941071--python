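"""Network positions, edge masks, partial correlations, mediation, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import molgrad as mg
from molgrad.core import NETWORKS
from molgrad.exceptions import DegenerateInputError, InvalidDataError


class TestNetworkCenterOfMass:
    def test_median_conventions(self):
        labels = np.array(
            [n for n in NETWORKS for _ in range(3)], dtype=object)
        grad = np.arange(21, dtype=float)
        grad[0:3] = [0.1, 0.2, 0.9]
        com = mg.network_center_of_mass(grad, labels)
        assert com["Vis"] == pytest.approx(0.2)

    def test_even_count_mean_of_middle_two(self):
        labels = np.array(["Vis", "Vis"] + [n for n in NETWORKS[1:]],
                          dtype=object)
        grad = np.array([1.0, 3.0] + [0.0] * 6)
        com = mg.network_center_of_mass(grad, labels)
        assert com["Vis"] == pytest.approx(2.0)

    def test_single_parcel_network(self):
        labels = np.array(list(NETWORKS), dtype=object)
        grad = np.linspace(0, 1, 7)
        com = mg.network_center_of_mass(grad, labels)
        assert com["Default"] == pytest.approx(grad[6])

    def test_empty_network_raises(self):
        labels = np.array(["Vis"] * 7, dtype=object)
        with pytest.raises(InvalidDataError):
            mg.network_center_of_mass(np.zeros(7), labels)


class TestHierarchyScore:
    def test_perfect_and_inverse(self, rng):
        ref = rng.normal(size=30)
        assert mg.hierarchy_score(ref[None, :], ref)[0] == pytest.approx(1.0)
        assert mg.hierarchy_score(-ref[None, :], ref)[0] == pytest.approx(-1.0)

    def test_matches_pearson_per_subject(self, rng):
        maps = rng.normal(size=(5, 40))
        ref = rng.normal(size=40)
        scores = mg.hierarchy_score(maps, ref)
        for s in range(5):
            assert scores[s] == pytest.approx(
                stats.pearsonr(maps[s], ref).statistic, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            mg.hierarchy_score(np.ones((2, 5)), np.arange(5.0))


class TestEdgeMasks:
    def test_small_enumeration(self):
        labels = np.array(["Vis", "Vis", "SomMot", "SomMot"], dtype=object)
        masks = mg.edge_masks(labels)
        assert masks.within.sum() == 2
        assert masks.between.sum() == 4

    def test_single_network_between_empty(self):
        labels = np.array(["Cont"] * 5, dtype=object)
        masks = mg.edge_masks(labels)
        assert masks.between.sum() == 0

    def test_cardinality(self, atlas60):
        masks = mg.edge_masks(atlas60.network)
        P = atlas60.n_parcels
        assert masks.n_edges == P * (P - 1) // 2
        assert masks.within.sum() + masks.between.sum() == masks.n_edges

    def test_unknown_label_raises(self):
        with pytest.raises(InvalidDataError):
            mg.edge_masks(np.array(["Vis", "Foo", "Cont"], dtype=object))


class TestWithinBetweenSummary:
    def test_block_matrix_means(self):
        labels = np.array(["Vis", "Vis", "SomMot", "SomMot"], dtype=object)
        masks = mg.edge_masks(labels)
        m = np.full((4, 4), 0.1)
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 0.5
        np.fill_diagonal(m, 0.0)
        s = mg.within_between_summary(mg.AdjacencyMatrix(m), masks)
        assert s["within_mean"] == pytest.approx(0.5)
        assert s["between_mean"] == pytest.approx(0.1)
        assert s["difference"] == pytest.approx(0.4)

    def test_constant_edges_zero_difference(self, atlas60):
        m = np.full((60, 60), 0.3)
        np.fill_diagonal(m, 0.0)
        masks = mg.edge_masks(atlas60.network)
        s = mg.within_between_summary(mg.AdjacencyMatrix(m), masks)
        assert s["difference"] == pytest.approx(0.0)


class TestNodalDensity:
    def test_identical_rows_zero_f(self, atlas60):
        m = np.full((60, 60), 0.4)
        np.fill_diagonal(m, 0.0)
        density, f, p = mg.nodal_density(mg.AdjacencyMatrix(m), atlas60.network)
        assert np.allclose(density, density[0])
        assert f == 0.0 and p == 1.0

    def test_elevated_network_shifted_by_delta(self, atlas60):
        m = np.full((60, 60), 0.2)
        np.fill_diagonal(m, 0.0)
        sel = atlas60.network == "Default"
        delta = 0.3
        m[sel, :] += delta
        m[:, sel] += delta
        m[np.ix_(sel, sel)] -= delta  # keep within-block shift at +delta
        np.fill_diagonal(m, 0.0)
        density, f, p = mg.nodal_density(mg.core.symmetrize_zero_diag(m),
                                         atlas60.network)
        others = density[~sel]
        # Default rows gained ~delta relative to non-Default rows
        assert density[sel].mean() - others.mean() > 0.2
        assert p < 0.05


class TestEuclideanDistances:
    def test_pythagorean_example(self):
        atlas = mg.make_atlas(14, seed=0)
        d = mg.euclidean_distances(atlas)
        i, j = 0, 5
        expect = np.linalg.norm(atlas.centroid_xyz[i] - atlas.centroid_xyz[j])
        assert d[i, j] == pytest.approx(expect)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_triangle_inequality(self, atlas60, rng):
        d = mg.euclidean_distances(atlas60)
        idx = rng.integers(0, 60, size=(1000, 3))
        i, j, k = idx.T
        assert np.all(d[i, j] <= d[i, k] + d[k, j] + 1e-9)

    def test_translation_invariance(self, atlas60):
        d1 = mg.euclidean_distances(atlas60)
        shifted = mg.ParcelAtlas(
            atlas60.parcel_id, atlas60.hemisphere, atlas60.network,
            atlas60.sphere_xyz, atlas60.centroid_xyz + np.array([5.0, -3.0, 2.0]))
        assert np.allclose(d1, mg.euclidean_distances(shifted), atol=1e-9)


class TestPartialSpearmanEdges:
    def test_near_orthogonal_covariate_changes_little(self, rng):
        # an independent covariate only removes its chance projection onto
        # the x/y ranks, so partial and plain Spearman agree to O(1/sqrt(n))
        n = 400
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        cov = rng.normal(size=n)
        rho = mg.partial_spearman_edges(x, y, [cov])
        plain = stats.spearmanr(x, y).statistic
        assert abs(rho - plain) < 4.0 / np.sqrt(n)

    def test_outcome_affine_in_distance_vanishes(self, rng):
        dist = rng.uniform(10, 80, size=60)
        y = 3.0 - 0.02 * dist
        x = rng.normal(size=60)
        rho = mg.partial_spearman_edges(x, y, [dist, dist**2])
        assert abs(rho) < 1e-8

    def test_matches_residual_correlation_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        c1 = rng.normal(size=20)
        c2 = rng.normal(size=20)
        rho = mg.partial_spearman_edges(x, y, [c1, c2])
        rc1 = stats.rankdata(c1)
        rc2 = stats.rankdata(c2)
        X = np.column_stack([np.ones(20), rc1 - rc1.mean(), rc2 - rc2.mean()])
        def res(v):
            v = stats.rankdata(v)
            return v - X @ np.linalg.lstsq(X, v, rcond=None)[0]
        oracle = np.corrcoef(res(x), res(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        c = rng.normal(size=40)
        base = mg.partial_spearman_edges(x, y, [c])
        assert mg.partial_spearman_edges(np.exp(x), y**3 if False else y, [c]) \
            == pytest.approx(base, abs=1e-12)
        assert mg.partial_spearman_edges(x, np.tanh(y), [c]) == \
            pytest.approx(base, abs=1e-12)

    def test_constant_covariate_dropped_with_warning(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        with pytest.warns(UserWarning):
            rho = mg.partial_spearman_edges(x, y, [np.ones(30)])
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-10)


class TestReceptorSimilarity:
    def test_identical_and_negated_profiles(self, rng):
        maps = rng.normal(size=(6, 5))
        maps[1] = maps[0]
        adj = mg.receptor_similarity(maps)
        # z-scoring is per map (column); rebuild profiles to check
        z = (maps - maps.mean(0)) / maps.std(0)
        assert adj.values[0, 1] == pytest.approx(
            np.corrcoef(z[0], z[1])[0, 1], abs=1e-12)
        assert adj.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_equal_weights_match_unweighted_oracle(self, rng):
        maps = rng.normal(size=(12, 18))
        adj = mg.receptor_similarity(maps, weights=np.ones(18))
        z = (maps - maps.mean(0)) / maps.std(0)
        oracle = np.corrcoef(z)
        np.fill_diagonal(oracle, 0.0)
        assert np.allclose(adj.values, oracle, atol=1e-10)
        assert np.allclose(adj.values, adj.values.T)
        assert np.all(np.diag(adj.values) == 0.0)

    def test_too_few_maps_raises(self, rng):
        with pytest.raises(ValueError):
            mg.receptor_similarity(rng.normal(size=(5, 1)))


class TestMatchThreshold:
    def test_worked_example(self):
        mask, frac = mg.match_threshold(np.array([0.1, 0.2, 0.3, 0.4]), 0.35)
        assert mask.tolist() == [False, False, True, True]
        assert frac == pytest.approx(0.5)

    def test_target_already_met(self):
        edges = np.array([0.3, 0.4])
        mask, frac = mg.match_threshold(edges, 0.35)
        assert mask.all() and frac == 0.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(20):
            edges = rng.uniform(0, 1, size=int(rng.integers(5, 21)))
            target = min(edges.mean() + rng.uniform(0, 0.2),
                         edges.max() - 1e-9)
            mask, frac = mg.match_threshold(edges, target)
            # oracle: smallest removal count over weakest-first prefixes
            order = np.argsort(edges, kind="stable")
            best = None
            for r in range(len(edges)):
                kept = edges[order[r:]]
                if kept.mean() >= target:
                    best = r
                    break
            assert best is not None
            assert (~mask).sum() == best
            assert edges[mask].mean() >= target


class TestMediationSobel:
    def test_null_path_a(self, rng):
        n = 2000
        x = rng.normal(size=n)
        m = rng.normal(size=n)           # independent of x: a = 0
        y = 0.5 * m + rng.normal(size=n)
        res = mg.mediation_sobel(x, m, y)
        assert abs(res.sobel_z) < 2.5
        assert res.sobel_p > 0.01

    def test_full_mediation(self, rng):
        n = 1500
        x = rng.normal(size=n)
        m = 0.8 * x + 0.3 * rng.normal(size=n)
        y = 0.7 * m + 0.3 * rng.normal(size=n)  # y depends on x only via m
        res = mg.mediation_sobel(x, m, y)
        assert res.sobel_p < 1e-6
        assert abs(res.direct) < 0.05

    def test_commonality_identity(self, rng):
        n = 300
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * x + 0.3 * m + rng.normal(size=n)
        res = mg.mediation_sobel(x, m, y,
                                 covariates=[rng.normal(size=n)])
        assert res.unique_x + res.unique_m + res.shared == \
            pytest.approx(res.r2_full, abs=1e-9)

    def test_collinear_raises(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(InvalidDataError):
            mg.mediation_sobel(x, x * 1.0000001, rng.normal(size=100))


class TestNetworkPositionRegression:
    def _data(self, rng, n=60, effect=0.0, target="Default"):
        scores = rng.normal(size=n)
        cov = pd.DataFrame({
            "age": rng.uniform(20, 78, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "fd": rng.uniform(0.05, 0.3, n),
        }, index=[f"s{i}" for i in range(n)])
        com = pd.DataFrame({
            net: 0.01 * cov["age"].to_numpy() + rng.normal(size=n)
            for net in NETWORKS})
        com[target] = com[target] + effect * scores
        return com, scores, cov

    def test_planted_effect_detected(self, rng):
        com, scores, cov = self._data(rng, n=120, effect=0.8)
        res = mg.network_position_regression(com, scores, cov)
        row = res[res["network"] == "Default"].iloc[0]
        assert row["significant"]
        assert row["beta"] > 0

    def test_duplicating_subjects_preserves_coefficients(self, rng):
        com, scores, cov = self._data(rng, n=40, effect=0.5)
        res1 = mg.network_position_regression(com, scores, cov)
        com2 = pd.concat([com, com], ignore_index=True)
        cov2 = pd.concat([cov, cov])
        cov2.index = [f"d{i}" for i in range(80)]
        res2 = mg.network_position_regression(
            com2, np.concatenate([scores, scores]), cov2)
        assert np.allclose(res1["beta"], res2["beta"], atol=1e-10)

    def test_adjusted_p_not_below_raw(self, rng):
        com, scores, cov = self._data(rng, n=50)
        res = mg.network_position_regression(com, scores, cov)
        assert np.all(res["p_fdr"].to_numpy() >= res["p"].to_numpy() - 1e-15)

    def test_too_few_subjects_raises(self, rng):
        com, scores, cov = self._data(rng, n=8)
        with pytest.raises(ValueError):
            mg.network_position_regression(com, scores, cov)


class TestReceptorFcCoupling:
    def test_within_network_coupling_positive_between_attenuated(self):
        """When modular structure drives the planted receptor-FC coupling,
        the distance-controlled edgewise association is positive within
        networks and attenuated between networks (directional check)."""
        atlas = mg.make_atlas(200, seed=1)
        masks = mg.edge_masks(atlas.network)
        dist = mg.euclidean_distances(atlas)[masks.iu]
        within, between = [], []
        for rep in range(20):
            spec = mg.CohortSpec(n_subjects=100, n_timepoints=160,
                                 seed=7000 + rep, hierarchy_sd=0.1,
                                 receptor_network_sd=0.4, modularity=0.2)
            cohort = mg.simulate_cohort(spec, atlas)
            adj = mg.irca_matrix(cohort.d1dr)
            grp = mg.group_fc(mg.subject_fc(ts)
                              for ts in cohort.timeseries.values())
            x, y = adj.upper_edges(), grp.upper_edges()
            within.append(mg.partial_spearman_edges(
                x[masks.within], y[masks.within],
                [dist[masks.within], dist[masks.within] ** 2]))
            between.append(mg.partial_spearman_edges(
                x[masks.between], y[masks.between],
                [dist[masks.between], dist[masks.between] ** 2]))
        assert sum(w > 0 for w in within) >= 18
        assert np.mean(within) > np.mean(between)


class TestBhFdr:
    def test_matches_enumerated_oracle(self, rng):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 11)))
            adj, _ = mg.bh_fdr(p)
            assert np.allclose(adj, oracle(p), atol=1e-12)
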