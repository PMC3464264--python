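import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nasrec.codebook import (
    NASSelection,
    StructuralClusterModel,
    assign_nas,
    assign_structural,
    feature_matrix,
    feature_vector,
    fit_structural_clusters,
    nas_correlation,
    nas_histogram,
    nas_info_content,
    nas_sharing_stats,
    select_nas,
)
from nasrec.icbank import ICBasis, ICClusterModel


def make_basis(components):
    components = np.asarray(components, dtype=float)
    return ICBasis(scale_id=0, components=components,
                   mean=np.zeros(components.shape[1]),
                   variance_retained=1.0, n_ic=components.shape[0])


def make_clusters(assignment, n_clusters):
    assignment = np.asarray(assignment)
    return ICClusterModel(scale_id=0, n_clusters=n_clusters,
                          centroids=np.zeros((n_clusters, 6)),
                          assignment=assignment)


class TestFeatureVector:
    def test_orthogonal_patch_gives_zero(self):
        basis = make_basis([[1, 0, 0], [0, 1, 0]])
        model = make_clusters([0, 0], 1)
        p = np.array([0.0, 0.0, 5.0])
        assert feature_vector(p, basis, model)[0] == 0.0

    def test_single_filter_cluster_is_absolute_projection(self):
        basis = make_basis([[1, 0]])
        model = make_clusters([0], 1)
        assert feature_vector(np.array([-3.0, 1.0]), basis, model)[0] == pytest.approx(3.0, abs=1e-12)

    def test_two_filter_cluster_closed_form(self):
        """Projections (3, 4) pooled by RMS: sqrt((9+16)/2) = sqrt(12.5)."""
        basis = make_basis([[1, 0], [0, 1]])
        model = make_clusters([0, 0], 1)
        a = feature_vector(np.array([3.0, 4.0]), basis, model)
        assert a[0] == pytest.approx(np.sqrt(12.5), abs=1e-12)

    def test_positive_homogeneity(self, rng):
        basis = make_basis(rng.normal(size=(6, 10)))
        model = make_clusters([0, 0, 1, 1, 2, 2], 3)
        p = rng.normal(size=10)
        a1 = feature_vector(p, basis, model)
        a3 = feature_vector(3.0 * p, basis, model)
        assert np.allclose(a3, 3.0 * a1, rtol=1e-12)
        assert (a1 >= 0).all()

    def test_length_mismatch_rejected(self, rng):
        basis = make_basis(rng.normal(size=(2, 8)))
        with pytest.raises(ValueError, match="length"):
            feature_vector(rng.normal(size=7), basis, make_clusters([0, 0], 1))


class TestStructuralClusters:
    def test_separated_rays_recovered(self, rng):
        rays = np.eye(4)
        X = np.vstack([r + rng.normal(0, 0.01, size=(20, 4)) for r in rays])
        X = np.abs(X)
        model = fit_structural_clusters(X, n_clusters=4, seed=0)
        labels = model.assign(X)
        for g in range(4):
            assert len(set(labels[20 * g : 20 * (g + 1)])) == 1
        assert len(set(labels[::20])) == 4

    def test_single_cluster_centroid_is_mean(self, rng):
        X = np.abs(rng.normal(size=(50, 6)))
        model = fit_structural_clusters(X, n_clusters=1, seed=0)
        assert np.allclose(model.centroids[0], X.mean(axis=0), atol=1e-10)

    def test_seeded_refit_is_identical(self, rng):
        X = np.abs(rng.normal(size=(60, 5)))
        a = fit_structural_clusters(X, n_clusters=4, seed=9)
        b = fit_structural_clusters(X, n_clusters=4, seed=9)
        assert np.array_equal(a.centroids, b.centroids)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_structural_clusters(rng.random((3, 4)), n_clusters=5)


class TestAssignNAS:
    def test_tie_breaks_to_lowest_index(self):
        centroids = np.array([[0.0], [2.0], [1.0], [1.0]])
        model = StructuralClusterModel(scale_id=0, n_clusters=4, centroids=centroids)
        # 1.0 sits exactly on centroids 2 and 3 -> lowest of the tied, 2
        assert model.assign(np.array([[1.0]]))[0] == 2
        # 0.5 is equidistant to centroids 0 (at 0) and 2,3 (at 1) -> 0
        assert model.assign(np.array([[0.5]]))[0] == 0

    def test_centroid_preimage_maps_to_own_cluster(self, rng):
        X = np.abs(rng.normal(size=(30, 4)))
        model = fit_structural_clusters(X, n_clusters=3, seed=0)
        for c in range(3):
            assert model.assign(model.centroids[c][None])[0] == c

    def test_batch_equals_single(self, rng):
        models = [StructuralClusterModel(scale_id=s, n_clusters=3,
                                         centroids=rng.random((3, 4)))
                  for s in range(3)]
        feats = [rng.random((5, 4)) for _ in range(3)]
        batch = assign_structural(feats, models)
        for i in range(5):
            single = assign_nas([f[i] for f in feats], models)
            assert batch[i] == single


class TestSelectNAS:
    @staticmethod
    def brute_force(table, labels, Mc, Nc):
        """Literal enumeration of the selection rule."""
        classes = sorted(set(labels))
        cols = sorted(table.columns)
        totals = {n: table[n].sum() for n in cols}
        survivors = [n for n in cols if totals[n] > Mc]
        rel = table.div(table.sum(axis=1).replace(0, 1), axis=0)
        freq = {c: {n: rel[n][np.array(labels) == c].mean() for n in survivors}
                for c in classes}
        selected = []
        for a, b in itertools.permutations(classes, 2):
            ranked = sorted(survivors,
                            key=lambda n: (-(freq[a][n] - freq[b][n]), freq[b][n], n))
            for n in ranked[:Nc]:
                if n not in selected:
                    selected.append(n)
        return selected

    @pytest.fixture()
    def hand_table(self):
        cols = [(0,), (1,), (2,), (3,), (4,)]
        data = np.array([
            [5, 0, 1, 2, 0],
            [4, 1, 0, 3, 0],
            [0, 6, 2, 0, 1],
            [1, 5, 1, 0, 0],
        ])
        return pd.DataFrame(data, columns=cols), ["a", "a", "b", "b"]

    def test_matches_brute_force_oracle(self, hand_table):
        table, labels = hand_table
        got = select_nas(table, labels, Mc=0, Nc=2)
        want = self.brute_force(table, labels, Mc=0, Nc=2)
        assert got.selected == want

    def test_large_budget_keeps_all_survivors(self, hand_table):
        table, labels = hand_table
        got = select_nas(table, labels, Mc=0, Nc=100)
        assert sorted(got.selected) == sorted(table.columns)

    def test_mc_boundary_is_strictly_greater(self, hand_table):
        table, labels = hand_table
        # NAS (4,) occurs exactly once in total; Mc=1 must drop it
        got = select_nas(table, labels, Mc=1, Nc=100)
        assert (4,) not in got.selected
        assert (2,) in got.selected  # total 4 > 1 survives

    def test_invariant_to_video_order(self, hand_table, rng):
        table, labels = hand_table
        perm = rng.permutation(len(table))
        shuffled = table.iloc[perm].reset_index(drop=True)
        lab = [labels[i] for i in perm]
        assert select_nas(shuffled, lab, 0, 2).selected == select_nas(table, labels, 0, 2).selected

    def test_argument_validation(self, hand_table):
        table, labels = hand_table
        with pytest.raises(ValueError):
            select_nas(table, labels, Mc=0, Nc=0)
        with pytest.raises(ValueError):
            select_nas(table, ["a"] * 4, Mc=0, Nc=1)


class TestNASHistogram:
    @pytest.fixture()
    def selection(self):
        return NASSelection(Mc=0, Nc=10, selected=[(0, 0, 0), (1, 1, 1), (2, 2, 2)])

    def test_single_cell_totals_retained_points(self, selection):
        pts = [((10, 10, 5), (0, 0, 0)), ((50, 3, 7), (1, 1, 1)),
               ((20, 20, 9), (9, 9, 9))]  # last not selected
        h = nas_histogram(pts, selection, grid=(1, 1, 1), dims=(60, 60, 60))
        assert h.counts.shape == (1, 3)
        assert h.total == 2

    def test_vertical_bands_use_half_open_intervals(self, selection):
        # H=120 split in 3: [0,40), [40,80), [80,120]; y=40 -> middle band
        for y, band in [(0, 0), (39, 0), (40, 1), (79, 1), (80, 2), (119, 2)]:
            h = nas_histogram([((y, 0, 0), (0, 0, 0))], selection,
                              grid=(3, 1, 1), dims=(120, 60, 60))
            assert h.counts[band, 0] == 1 and h.total == 1

    def test_boundary_crossing_moves_one_count(self, selection):
        a = nas_histogram([((39, 0, 0), (0, 0, 0))], selection, (3, 1, 1), (120, 8, 8))
        b = nas_histogram([((40, 0, 0), (0, 0, 0))], selection, (3, 1, 1), (120, 8, 8))
        assert np.abs(a.counts - b.counts).sum() == 2
        assert a.total == b.total == 1

    def test_cell_order_is_y_then_x_then_t(self, selection):
        h = nas_histogram([((0, 50, 50), (1, 1, 1))], selection,
                          grid=(2, 2, 2), dims=(60, 60, 60))
        # y-band 0, x-band 1, t-band 1 -> cell (0*2+1)*2+1 = 3
        assert h.counts[3, 1] == 1

    def test_empty_grid_rejected(self, selection):
        with pytest.raises(ValueError):
            nas_histogram([], selection, grid=(0, 1, 1), dims=(60, 60, 60))


class TestNASStatistics:
    def test_sharing_levels_on_hand_table(self):
        cols = [(0,), (1,), (2,), (3,)]
        table = pd.DataFrame(
            [[2, 1, 0, 0],
             [0, 3, 0, 0],
             [0, 2, 1, 0]],
            columns=cols)
        labels = ["a", "b", "c"]
        levels, dist = nas_sharing_stats(table, labels)
        assert levels[(0,)] == 1 and levels[(1,)] == 3 and levels[(2,)] == 1
        assert (3,) not in levels.index  # empty NAS excluded
        assert dist.sum() == pytest.approx(100.0)
        assert dist[3] == pytest.approx(100.0 / 3)

    def test_correlation_properties(self, rng):
        table = pd.DataFrame({
            (0,): [1, 2, 3, 4.0],
            (1,): [1, 2, 3, 4.0],   # duplicate of (0,)
            (2,): [5, 5, 5, 5.0],   # constant
            (3,): [4, 1, 2, 2.0],
        })
        C = nas_correlation(table)
        assert C.loc[[(0,)], [(0,)]].iloc[0, 0] == pytest.approx(1.0)
        assert C.loc[[(0,)], [(1,)]].iloc[0, 0] == pytest.approx(1.0)
        assert (C.loc[[(2,)]].to_numpy() == 0).all()
        assert np.allclose(C.to_numpy(), C.to_numpy().T)

    def test_independent_counts_weakly_correlated(self, rng):
        table = pd.DataFrame(rng.poisson(5, size=(200, 8)),
                             columns=[(i,) for i in range(8)])
        C = nas_correlation(table).to_numpy()
        off = C[~np.eye(8, dtype=bool)]
        assert np.quantile(np.abs(off), 0.95) < 0.25

    def test_info_content_chance_level_for_identical_classes(self, rng):
        vals = rng.normal(0.5, 0.1, size=(100, 1))
        table = pd.DataFrame(vals, columns=[(0,)])
        labels = ["a"] * 50 + ["b"] * 50
        acc = nas_info_content(table, labels, relative=True)
        assert abs(acc.loc[[(0,)], "a"].iloc[0] - 0.5) <= 0.1

    def test_info_content_perfect_separation(self, rng):
        vals = np.concatenate([rng.normal(0, 0.01, 30), rng.normal(1, 0.01, 30)])
        table = pd.DataFrame({(0,): vals})
        labels = ["a"] * 30 + ["b"] * 30
        acc = nas_info_content(table, labels, relative=True)
        assert acc.loc[[(0,)], "a"].iloc[0] == 1.0

    def test_info_content_matches_bayes_rate(self, rng):
        """mu=(0,2), sigma=1: threshold 1.0, Bayes accuracy Phi(1)=0.8413."""
        n = 250
        vals = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        table = pd.DataFrame({(0,): vals})
        labels = ["a"] * n + ["b"] * n
        acc = nas_info_content(table, labels, relative=True).loc[[(0,)], "a"].iloc[0]
        assert abs(acc - norm.cdf(1.0)) < 0.05
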