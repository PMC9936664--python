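"""Distances, PERMANOVA, NMDS and PCA summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from dimetab.errors import ValidationError
from dimetab.multivariate import (
    DistanceMatrix,
    compute_distance,
    magnitude_averaged_indices,
    nmds,
    pca_summaries,
    permanova,
)
from dimetab.preprocessing import IntensityMatrix, annotate_peaks
from conftest import make_metadata, make_peaks


def _im(cols: dict, normalization="raw") -> IntensityMatrix:
    return IntensityMatrix(pd.DataFrame(cols, dtype=float), normalization=normalization)


class TestComputeDistance:
    def test_identical_columns_have_zero_distance(self):
        d = compute_distance(_im({"A": [1, 2, 3], "B": [1, 2, 3]}), "bray_curtis")
        assert d.values[0, 1] == 0.0

    def test_disjoint_columns_have_bray_curtis_one(self):
        d = compute_distance(_im({"A": [1, 0, 3], "B": [0, 5, 0]}), "bray_curtis")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(1, 1, (30, 5))
        vals[rng.random((30, 5)) < 0.2] = 0.0
        cols = {f"S{i}": vals[:, i] for i in range(5)}
        d = compute_distance(_im(cols), "bray_curtis")
        for i in range(5):
            for j in range(5):
                x, y = vals[:, i], vals[:, j]
                expected = np.abs(x - y).sum() / (x + y).sum()
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_jaccard_uses_presence_absence(self):
        d = compute_distance(_im({"A": [1, 0, 3], "B": [9, 0, 4]}), "jaccard")
        assert d.values[0, 1] == 0.0

    def test_negative_values_reject_bray_curtis(self):
        m = _im({"A": [1, -2], "B": [3, 4]}, normalization="zscore")
        with pytest.raises(ValidationError, match="euclidean"):
            compute_distance(m, "bray_curtis")

    def test_default_metric_follows_normalization(self):
        signed = _im({"A": [1.0, -1.0], "B": [0.5, 0.2]}, normalization="zscore")
        assert compute_distance(signed).metric == "euclidean"
        nonneg = _im({"A": [1.0, 2.0], "B": [0.5, 0.2]}, normalization="sum")
        assert compute_distance(nonneg).metric == "bray_curtis"


def _null_distance(n_per_group=5, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = rng.normal(0, 1, (n, 20))
    X[n_per_group:] += shift
    ids = [f"S{i}" for i in range(n)]
    D = squareform(pdist(X))
    meta = make_metadata({s: ("a" if i < n_per_group else "b") for i, s in enumerate(ids)})
    return DistanceMatrix(ids, "euclidean", D), meta


class TestPermanova:
    def test_planted_shift_reaches_minimum_p(self):
        # 2 groups x 10: permutations reproducing the group partition (which
        # tie F exactly) are vanishingly rare, so a huge shift attains the
        # minimal attainable p of (1 + 0) / (1 + n_perm)
        dist, meta = _null_distance(n_per_group=10, seed=5, shift=25.0)
        table = permanova(dist, meta, "Group", n_perm=199, seed=0)
        assert table.loc[0, "p_perm"] == pytest.approx(1 / 200)
        assert table.loc[0, "pseudo_F"] > 50

    def test_r_squared_partitions_to_one(self):
        dist, meta = _null_distance(seed=2)
        table = permanova(dist, meta, "Group", n_perm=99, seed=1)
        terms = table[~table["term"].isin(["Total"])]
        assert terms["R2"].sum() == pytest.approx(1.0, abs=1e-12)
        p = table.loc[0, "p_perm"]
        assert 1 / 100 <= p <= 1.0

    def test_matches_reference_pseudo_f(self):
        # independent cross-check against scikit-bio's PERMANOVA
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        dist, meta = _null_distance(seed=3, shift=1.0)
        table = permanova(dist, meta, "Group", n_perm=99, seed=0)
        dm = skbio.DistanceMatrix(dist.values, ids=dist.sample_ids)
        ref = skbio_permanova(dm, meta.loc[dist.sample_ids, "Group"].to_numpy(),
                              permutations=99)
        assert table.loc[0, "pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_two_way_with_interaction_terms(self):
        rng = np.random.default_rng(9)
        ids = [f"S{i}" for i in range(12)]
        X = rng.normal(0, 1, (12, 8))
        D = squareform(pdist(X))
        g1 = {s: ("a" if i < 6 else "b") for i, s in enumerate(ids)}
        g2 = {s: ("x" if i % 2 else "y") for i, s in enumerate(ids)}
        meta = make_metadata(g1, g2)
        table = permanova(
            DistanceMatrix(ids, "euclidean", D), meta, ["Group", "Group2"],
            n_perm=99, seed=0,
        )
        assert list(table["term"]) == ["Group", "Group2", "Group:Group2",
                                       "Residual", "Total"]
        assert table[table["term"] != "Total"]["R2"].sum() == pytest.approx(1.0)

    def test_degenerate_distances_rejected(self):
        ids = ["a", "b", "c", "d"]
        meta = make_metadata({s: ("x" if i < 2 else "y") for i, s in enumerate(ids)})
        with pytest.raises(ValidationError, match="zero"):
            permanova(DistanceMatrix(ids, "euclidean", np.zeros((4, 4))), meta,
                      "Group", n_perm=99)

    def test_too_few_permutations_rejected(self):
        dist, meta = _null_distance()
        with pytest.raises(ValidationError, match="99"):
            permanova(dist, meta, "Group", n_perm=10)


class TestNmds:
    def _planted(self, n=10, seed=1):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1, 1, (n, 2))
        D = squareform(pdist(pts))
        ids = [f"S{i}" for i in range(n)]
        return DistanceMatrix(ids, "euclidean", D)

    def test_planted_2d_configuration_recovers_low_stress(self):
        res = nmds(self._planted(), k=2, n_restarts=10, seed=0)
        assert res.stress < 0.01

    def test_stress_history_is_non_increasing(self):
        res = nmds(self._planted(seed=4), k=2, n_restarts=3, seed=2)
        hist = np.array(res.stress_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_planar_point_set_embeds_with_near_zero_stress(self):
        # 4 points drawn in the plane (equilateral triangle + centroid-ish
        # point) reproduce their distances exactly in a 2-D embedding
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0.5, np.sqrt(3) / 6]])
        Dp = squareform(pdist(pts))
        res = nmds(DistanceMatrix(list("abcd"), "euclidean", Dp), k=2,
                   n_restarts=10, seed=1)
        assert res.stress < 1e-3

    def test_result_invariant_under_sample_reordering(self):
        dist = self._planted(seed=6)
        res1 = nmds(dist, k=2, n_restarts=5, seed=3)
        perm = np.random.default_rng(0).permutation(len(dist.sample_ids))
        dist2 = DistanceMatrix(
            [dist.sample_ids[i] for i in perm], "euclidean",
            dist.values[np.ix_(perm, perm)],
        )
        res2 = nmds(dist2, k=2, n_restarts=5, seed=3)
        assert res1.stress == pytest.approx(res2.stress, abs=1e-3)

    def test_too_few_samples_rejected(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValidationError, match="at least"):
            nmds(DistanceMatrix(["a", "b", "c"], "euclidean", D), k=2)


class TestPcaSummaries:
    def _study(self):
        rng = np.random.default_rng(15)
        rows = []
        samples = [f"S{i}" for i in range(6)]
        for i in range(40):
            c = int(rng.integers(5, 30))
            row = {
                "mass": 100.0 + i,
                "C": c,
                "H": max(1, int(round(c * rng.uniform(0.6, 2.2)))),
                "O": int(round(c * rng.uniform(0, 1.0))),
            }
            for s in samples:
                row[s] = float(rng.lognormal(3, 1)) * (rng.random() > 0.2)
            rows.append(row)
        peaks = annotate_peaks(make_peaks(rows, samples))
        return peaks, IntensityMatrix(peaks[samples].astype(float))

    def test_magnitude_averaged_nosc_hand_example(self):
        rows = [
            {"mass": 100.0, "C": 2, "H": 6, "O": 1, "SampA": 1.0},   # ethanol: NOSC -2
            {"mass": 200.0, "C": 2, "H": 2, "O": 3, "SampA": 3.0},   # glyoxylic-ish: NOSC +2
        ]
        peaks = annotate_peaks(make_peaks(rows, ["SampA"]))
        assert peaks["nosc"].tolist() == [-2.0, 2.0]
        m = IntensityMatrix(peaks[["SampA"]].astype(float))
        mag = magnitude_averaged_indices(peaks, m)
        # (1*(-2) + 3*(+2)) / 4 = 1.0; with NOSC -1/+1 at 1:3 it would be 0.5
        assert mag.loc["SampA", "nosc"] == pytest.approx(1.0)

    def test_explained_variance_sums_to_one(self):
        peaks, m = self._study()
        comp, mag = pca_summaries(peaks, m)
        assert mag.explained_variance.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(mag.explained_variance) <= 1e-12).all()

    def test_identical_samples_give_zero_scores(self):
        rows = [
            {"mass": 100.0 + i, "C": 6 + i, "H": 12, "O": i % 3,
             "S1": 2.0, "S2": 2.0, "S3": 2.0}
            for i in range(8)
        ]
        peaks = annotate_peaks(make_peaks(rows, ["S1", "S2", "S3"]))
        m = IntensityMatrix(peaks[["S1", "S2", "S3"]].astype(float))
        with pytest.warns(UserWarning, match="constant"):
            comp, mag = pca_summaries(peaks, m)
        assert np.allclose(comp.scores.to_numpy(), 0.0)
        assert np.allclose(mag.scores.to_numpy(), 0.0)

    def test_perfectly_correlated_variables_load_on_pc1(self):
        from dimetab.multivariate import _pca

        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        res = _pca(t, "PCA")
        assert res.explained_variance[0] == pytest.approx(1.0)
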