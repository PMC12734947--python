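"""Rank tests, effect sizes, volcano feature sets and UpSet-style counts."""

import numpy as np
import pandas as pd
import pytest

from soilstoich.stats import (
    benjamini_hochberg,
    cliffs_delta,
    cohens_d,
    compare_ratio_groups,
    effect_size_label,
    kruskal_wallis,
    kruskal_wallis_exact,
    pairwise_vs_reference,
    significant_feature_sets,
    upset_counts,
    upset_counts_frame,
)
from soilstoich.synthetic import make_design, sample_formula_library, simulate_feature_table


class TestKruskalWallis:
    def test_all_equal_gives_zero_h(self):
        h, p = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_hand_derived_toy(self):
        # ranks 1..6: R1=6, R2=15; H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 3.857
        h, _ = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert h == pytest.approx(27 / 7, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=12)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        h1, p1 = kruskal_wallis(vals, groups)
        h2, p2 = kruskal_wallis(np.exp(vals * 3), groups)  # strictly monotone
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_exact_toy_p_is_two_of_twenty(self):
        # only the two fully separated splits of {1..6} into 3+3 reach H=3.857
        h, p = kruskal_wallis_exact([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert h == pytest.approx(27 / 7)
        assert p == pytest.approx(2 / 20)

    def test_exact_limited_to_small_n(self):
        with pytest.raises(ValueError):
            kruskal_wallis_exact(list(range(12)), ["a", "b"] * 6)


class TestEffectSizes:
    def test_identical_groups_give_zero_d(self):
        vals = {"ref": np.array([1.0, 2.0, 3.0]), "g": np.array([1.0, 2.0, 3.0])}
        res = pairwise_vs_reference(vals, "ref")
        assert res.loc[0, "cohens_d"] == 0.0
        assert res.loc[0, "label"] == "negligible"

    def test_unit_shift_unit_sd_gives_d_one(self):
        # means 0 vs 1, each group's sample sd exactly 1 -> pooled sd 1, d = 1
        a = np.array([-1.0, 0.0, 1.0])
        b = a + 1.0
        assert cohens_d(b, a) == pytest.approx(1.0, abs=1e-12)
        assert effect_size_label(1.0) == "large"

    def test_d_sign_positive_when_group_exceeds_reference(self):
        res = pairwise_vs_reference(
            {"ref": np.array([0.0, 0.1, -0.1, 0.05]), "up": np.array([1.0, 1.1, 0.9, 1.05])},
            "ref",
        )
        assert res.loc[0, "cohens_d"] > 0

    def test_disjoint_distributions_give_cliffs_delta_one(self):
        assert cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0
        assert cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0

    @pytest.mark.parametrize(
        "d, label",
        [(0.1, "negligible"), (-0.3, "small"), (0.6, "medium"), (-2.0, "large")],
    )
    def test_labels_at_cutpoints(self, d, label):
        assert effect_size_label(d) == label


def test_compare_ratio_groups_excludes_nan_per_ratio():
    df = pd.DataFrame(
        {
            "group": ["ref"] * 4 + ["g"] * 4,
            "ratio_cp": [1.0, 2.0, 1.5, np.nan, 5.0, 6.0, 5.5, 6.5],
        }
    )
    (res,) = compare_ratio_groups(df, ratio_columns=("ratio_cp",), reference="ref")
    assert res.kw_p < 0.05
    assert res.pairwise.loc[0, "cohens_d"] > 0.8


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
        adj = benjamini_hochberg(p)
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()
        assert (adj <= 1.0).all() and (adj >= p - 1e-15).all()

    def test_matches_hand_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])


class TestSignificantFeatureSets:
    def _simulated(self, seed, effect=2.0, frac=0.2, n=300):
        design = make_design(
            groups=("pasture", "treated"), n_per_group=4, n_blanks=0, seed=seed
        )
        lib = sample_formula_library(n, (85, 500), seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        planted = rng.choice(n, size=int(frac * n), replace=False)
        eff = np.zeros(n)
        eff[planted] = effect
        table, truth = simulate_feature_table(
            design, lib, effects={"treated": eff, "pasture": 0.0},
            seed=seed, add_internal_standards=False,
        )
        return table, design, {table.feature_ids[i] for i in planted}

    def test_planted_fourfold_features_recovered(self):
        """4-fold planted features: >= 80% recovered, <= 5% false memberships."""
        recs, fps = [], []
        for seed in range(20):
            table, design, planted = self._simulated(seed)
            sets = significant_feature_sets(table, design)
            got = sets["treated"]
            recs.append(len(got & planted) / len(planted))
            null = set(table.feature_ids) - planted
            fps.append(len(got & null) / len(null))
        assert np.mean(recs) >= 0.80
        assert np.mean(fps) <= 0.05

    def test_zero_alpha_gives_empty_sets(self):
        table, design, _ = self._simulated(0)
        sets = significant_feature_sets(table, design, alpha=0.0)
        assert all(len(s) == 0 for s in sets.values())

    def test_sets_are_subsets_of_feature_universe(self):
        table, design, _ = self._simulated(1)
        sets = significant_feature_sets(table, design)
        universe = set(table.feature_ids)
        assert all(s <= universe for s in sets.values())


class TestUpsetCounts:
    def test_two_set_hand_example(self):
        counts = upset_counts({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 1
        assert counts[frozenset({"A", "B"})] == 2

    def test_disjoint_sets_only_singletons(self):
        counts = upset_counts({"A": {1}, "B": {2}, "C": {3, 4}})
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"C"})] == 2
        assert all(v == 0 for k, v in counts.items() if len(k) > 1)

    def test_exclusive_counts_partition_union(self):
        rng = np.random.default_rng(9)
        sets = {
            name: set(rng.choice(100, size=rng.integers(5, 40), replace=False).tolist())
            for name in "ABCDE"
        }
        counts = upset_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_long_format_frame(self):
        df = upset_counts_frame({"A": {1, 2}, "B": {2}})
        assert set(df.columns) == {"combination", "degree", "count"}
        assert df.loc[df.combination == "A&B", "count"].item() == 1
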