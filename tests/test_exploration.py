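"""Diagnostics counts, composition summaries, pairwise comparisons and
per-index group tests."""

import numpy as np
import pytest
from scipy import stats

from dimetab.exploration import (
    composition_summary,
    diagnostics_counts,
    error_distribution,
    index_group_tests,
    pairwise_compare,
    van_krevelen_data,
)
from dimetab.preprocessing import annotate_peaks
from conftest import make_metadata, make_peaks


def _annotated(rows, samples):
    return annotate_peaks(make_peaks(rows, samples))


class TestDiagnostics:
    def test_counts_per_sample(self):
        peaks = _annotated(
            [
                {"mass": 100.0, "C": 5, "H": 10, "SampA": 1.0, "SampB": 1.0},
                {"mass": 200.0, "C": 8, "H": 14, "SampA": 2.0},
                {"mass": 300.0, "SampA": 3.0},  # detected, no formula
            ],
            ["SampA", "SampB"],
        )
        table = diagnostics_counts(peaks)
        assert table.loc["SampA", "n_peaks"] == 3
        assert table.loc["SampA", "n_with_formula"] == 2
        assert table.loc["SampB", "n_peaks"] == 1
        assert (table["n_with_formula"] <= table["n_peaks"]).all()

    def test_empty_sample_counts_zero(self):
        peaks = _annotated(
            [{"mass": 100.0, "C": 5, "H": 10, "SampA": 1.0}], ["SampA", "SampB"]
        )
        table = diagnostics_counts(peaks)
        assert table.loc["SampB", "n_peaks"] == 0
        assert table.loc["SampB", "n_with_formula"] == 0

    def test_formula_poor_sample_flagged_as_minimum(self):
        rows = [
            {"mass": 100.0 + i, "C": 6, "H": 12, "SampA": 1.0, "SampB": float(i < 1)}
            for i in range(5)
        ]
        table = diagnostics_counts(_annotated(rows, ["SampA", "SampB"]))
        assert table.loc["SampB", "is_min_formulas"]
        assert not table.loc["SampA", "is_min_formulas"]

    def test_error_distribution_covers_detected_assigned_peaks(self):
        peaks = _annotated(
            [
                {"mass": 100.0, "C": 5, "H": 10, "error_ppm": 0.2, "SampA": 1.0},
                {"mass": 200.0, "SampA": 3.0},
            ],
            ["SampA"],
        )
        errs = error_distribution(peaks)
        assert len(errs) == 1
        assert errs.loc[0, "error_ppm"] == 0.2


class TestComposition:
    def test_single_class_group_is_100_percent(self):
        rows = [
            {"mass": 200.0 + i, "C": 20, "H": 36, "O": 2, "SampA": 1.0}
            for i in range(4)
        ]  # O/C = 0.1, H/C = 1.8 -> Lipid
        peaks = _annotated(rows, ["SampA"])
        meta = make_metadata({"SampA": "g1"})
        classes, elements = composition_summary(peaks, meta, "Group")
        assert classes.loc["Lipid", "g1"] == pytest.approx(100.0)
        assert elements.loc["CHO", "g1"] == pytest.approx(100.0)

    def test_planted_three_to_one_split(self):
        rows = []
        for i in range(3):  # lignin-like: O/C 0.4, H/C 1.2
            rows.append({"mass": 300.0 + i, "C": 10, "H": 12, "O": 4, "SampA": 1.0})
        rows.append({"mass": 400.0, "C": 10, "H": 18, "O": 4, "SampA": 1.0})  # protein-like
        peaks = _annotated(rows, ["SampA"])
        meta = make_metadata({"SampA": "g"})
        classes, _ = composition_summary(peaks, meta, "Group")
        assert classes.loc["Lignin", "g"] == pytest.approx(75.0)
        assert classes.loc["Protein", "g"] == pytest.approx(25.0)
        assert classes["g"].sum() == pytest.approx(100.0, abs=1e-9)


class TestPairwiseCompare:
    def _two_group_peaks(self, pattern):
        """pattern: list of (in_a, in_b) detection tuples."""
        rows = []
        for i, (a, b) in enumerate(pattern):
            rows.append(
                {"mass": 100.0 + i, "C": 6, "H": 12, "O": 3,
                 "SampA": float(a), "SampB": float(b)}
            )
        peaks = _annotated(rows, ["SampA", "SampB"])
        meta = make_metadata({"SampA": "a", "SampB": "b"})
        return peaks, meta

    def test_identical_detection_has_no_uniques(self):
        peaks, meta = self._two_group_peaks([(1, 1)] * 5)
        comps, _ = pairwise_compare(peaks, meta, "Group")
        assert len(comps) == 1
        assert len(comps[0].shared) == 5
        assert not comps[0].unique_a and not comps[0].unique_b

    def test_disjoint_detection_has_no_shared(self):
        peaks, meta = self._two_group_peaks([(1, 0)] * 3 + [(0, 1)] * 2)
        comps, _ = pairwise_compare(peaks, meta, "Group")
        assert not comps[0].shared
        assert len(comps[0].unique_a) == 3
        assert len(comps[0].unique_b) == 2

    def test_planted_shared_and_unique_counts(self):
        pattern = [(1, 1)] * 10 + [(1, 0)] * 3 + [(0, 1)] * 2
        peaks, meta = self._two_group_peaks(pattern)
        comps, presence = pairwise_compare(peaks, meta, "Group")
        c = comps[0]
        assert (len(c.shared), len(c.unique_a), len(c.unique_b)) == (10, 3, 2)
        union = presence["a"] | presence["b"]
        assert len(c.shared) + len(c.unique_a) + len(c.unique_b) == int(union.sum())

    def test_single_group_warns_and_returns_empty(self):
        rows = [{"mass": 100.0, "C": 6, "H": 12, "SampA": 1.0}]
        peaks = _annotated(rows, ["SampA"])
        meta = make_metadata({"SampA": "only"})
        with pytest.warns(UserWarning, match="one group"):
            comps, _ = pairwise_compare(peaks, meta, "Group")
        assert comps == []


class TestIndexGroupTests:
    def _study(self, offset=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            c = int(rng.integers(5, 30))
            h = max(1, int(round(c * rng.uniform(0.7, 2.0))))
            o = int(round(c * rng.uniform(0, 1.0)))
            rows.append(
                {"mass": 150.0 + i, "C": c, "H": h, "O": o,
                 "SampA1": 1.0, "SampA2": 1.0, "SampB1": 0.0, "SampB2": 0.0}
            )
        for i in range(n):
            c = int(rng.integers(5, 30))
            h = max(1, int(round(c * rng.uniform(0.7, 2.0))))
            # offset shifts O/C hence NOSC upward for group B's peaks
            o = int(round(c * min(1.0, rng.uniform(0, 1.0) + offset)))
            rows.append(
                {"mass": 550.0 + i, "C": c, "H": h, "O": o,
                 "SampA1": 0.0, "SampA2": 0.0, "SampB1": 1.0, "SampB2": 1.0}
            )
        peaks = _annotated(rows, ["SampA1", "SampA2", "SampB1", "SampB2"])
        meta = make_metadata(
            {"SampA1": "A", "SampA2": "A", "SampB1": "B", "SampB2": "B"}
        )
        return peaks, meta

    def test_identical_groups_have_zero_mean_difference(self):
        rows = [
            {"mass": 100.0 + i, "C": 6 + i, "H": 12, "O": i % 4,
             "SampA": 1.0, "SampB": 1.0}
            for i in range(10)
        ]
        peaks = _annotated(rows, ["SampA", "SampB"])
        meta = make_metadata({"SampA": "A", "SampB": "B"})
        res = index_group_tests(peaks, meta, "Group")
        assert (res["mean_diff"].abs() < 1e-12).all()

    def test_large_offset_is_detected(self):
        peaks, meta = self._study(offset=0.9, n=60, seed=1)
        res = index_group_tests(peaks, meta, "Group", indices=("nosc",))
        assert (res["p_adj"] < 0.001).all()

    def _one_sample_per_group(self, n_per_group, seed, n_groups=2):
        """Independent random formulas per group, one sample per group, so
        the per-index observations are iid draws under the null."""
        rng = np.random.default_rng(seed)
        names = [f"S{g}" for g in range(n_groups)]
        rows = []
        for g, s in enumerate(names):
            for i in range(n_per_group):
                c = int(rng.integers(5, 30))
                h = max(1, int(round(c * rng.uniform(0.7, 2.0))))
                o = int(round(c * rng.uniform(0, 1.0)))
                row = {"mass": 100.0 + 500 * g + i, "C": c, "H": h, "O": o}
                row.update({t: float(t == s) for t in names})
                rows.append(row)
        peaks = _annotated(rows, names)
        meta = make_metadata({s: f"g{g}" for g, s in enumerate(names)})
        return peaks, meta

    def test_null_false_positive_rate_is_controlled(self):
        # both groups' peaks drawn from the same formula distribution: the
        # Tukey-adjusted p should exceed 0.05 in the vast majority of repeats
        nonsig = 0
        for seed in range(100):
            peaks, meta = self._one_sample_per_group(30, seed)
            res = index_group_tests(peaks, meta, "Group", indices=("nosc",))
            nonsig += (res["p_adj"] > 0.05).all()
        assert nonsig >= 94

    def test_tukey_p_at_least_pairwise_t_p(self):
        for seed in range(5):
            peaks, meta = self._one_sample_per_group(15, seed, n_groups=3)
            res = index_group_tests(peaks, meta, "Group", indices=("nosc",))
            samples_of = {f"g{g}": f"S{g}" for g in range(3)}
            for _, r in res.iterrows():
                obs = {}
                for g in (r["group_a"], r["group_b"]):
                    s = samples_of[g]
                    obs[g] = peaks.loc[peaks[s] > 0, "nosc"].dropna()
                _, p_t = stats.ttest_ind(obs[r["group_a"]], obs[r["group_b"]])
                assert r["p_adj"] >= p_t - 1e-9


def test_van_krevelen_table_lists_formula_peaks_per_group():
    rows = [
        {"mass": 100.0, "C": 6, "H": 12, "O": 6, "SampA": 1.0},
        {"mass": 200.0, "SampA": 1.0},  # no formula, excluded
    ]
    peaks = annotate_peaks(make_peaks(rows, ["SampA"]))
    meta = make_metadata({"SampA": "g"})
    vk = van_krevelen_data(peaks, meta, "Group")
    assert len(vk) == 1
    assert vk.loc[0, "compound_class"] == "Carbohydrate"
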