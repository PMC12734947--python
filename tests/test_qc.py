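"""Blank-retention rule, internal-standard CV, mass normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilstoich.qc import blank_filter, internal_standard_cv, mass_normalize
from soilstoich.tables import FeatureTable, StudyDesign


class TestBlankFilter:
    def test_hand_derived_retention(self, toy_blank_table, toy_design):
        """Means 400/100, 300/100, 50/0, 10/100, 90/30 at ratio 3 keep f1 and f3.

        400 > 300 keeps f1; 300 > 300 is false (strict) so f2 drops; f3 is
        absent from blanks with positive signal, kept; 10 < 300 and 90 = 90
        drop f4 and f5.
        """
        kept = blank_filter(toy_blank_table, toy_design)
        assert kept.feature_ids == ["f1", "f3"]

    def test_boundary_is_strict(self, toy_blank_table, toy_design):
        assert "f2" not in blank_filter(toy_blank_table, toy_design, 3.0).feature_ids
        assert "f2" in blank_filter(toy_blank_table, toy_design, 2.99).feature_ids

    def test_idempotent(self, toy_blank_table, toy_design):
        once = blank_filter(toy_blank_table, toy_design)
        twice = blank_filter(once, toy_design)
        assert twice.feature_ids == once.feature_ids
        np.testing.assert_array_equal(twice.intensities, once.intensities)

    def test_zero_ratio_keeps_everything_with_signal(self, toy_blank_table, toy_design):
        kept = blank_filter(toy_blank_table, toy_design, ratio=0.0)
        assert kept.feature_ids == ["f1", "f2", "f3", "f4", "f5"]

    def test_max_statistic_is_stricter(self, toy_design):
        table = FeatureTable(
            feature_ids=["f"], mz=[100.0], rt_min=[1.0],
            samples=["s1", "s2", "b1"],
            intensities=np.array([[400.0, 400.0, 100.0]]),
        )
        design = StudyDesign(
            sample_groups={"s1": "A", "s2": "A", "b1": "blank", "b2": "blank"},
            blanks={"b1", "b2"}, reference_group="A",
        )
        t2 = FeatureTable(
            feature_ids=["f"], mz=[100.0], rt_min=[1.0],
            samples=["s1", "s2", "b1", "b2"],
            intensities=np.array([[400.0, 400.0, 20.0, 180.0]]),
        )
        assert blank_filter(t2, design, blank_statistic="mean").n_features == 1
        assert blank_filter(t2, design, blank_statistic="max").n_features == 0

    def test_no_blanks_is_an_explicit_error(self, toy_blank_table):
        design = StudyDesign(sample_groups={"s1": "A", "s2": "A"}, reference_group="A")
        with pytest.raises(ValueError, match="skip"):
            blank_filter(toy_blank_table, design)


class TestInternalStandardCV:
    def _table(self, values):
        return FeatureTable(
            feature_ids=["is1"], mz=[164.07], rt_min=[3.0],
            samples=[f"s{i}" for i in range(len(values))],
            intensities=np.array([values], dtype=float),
        )

    def _design(self, n):
        return StudyDesign(sample_groups={f"s{i}": "A" for i in range(n)}, reference_group="A")

    def test_constant_signal_has_zero_cv(self):
        res = internal_standard_cv(self._table([500, 500, 500]), "is1", self._design(3))
        assert res.cv_percent == 0.0 and res.passed

    def test_hand_computed_cv(self):
        # sd({1,2,3}) = 1, mean = 2 -> 50%
        res = internal_standard_cv(self._table([1, 2, 3]), "is1", self._design(3))
        assert res.cv_percent == pytest.approx(50.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 1e6))
    def test_cv_is_scale_invariant(self, c):
        base = internal_standard_cv(self._table([1, 2, 3]), "is1", self._design(3))
        scaled = internal_standard_cv(self._table([c, 2 * c, 3 * c]), "is1", self._design(3))
        assert scaled.cv_percent == pytest.approx(base.cv_percent, rel=1e-9)

    def test_zero_mean_is_an_error(self):
        with pytest.raises(ValueError, match="zero mean"):
            internal_standard_cv(self._table([0, 0, 0]), "is1", self._design(3))

    def test_synthetic_is_near_target_cv(self):
        """IS generated at 5% target CV over 24 samples estimates within [2, 9]%."""
        from soilstoich.synthetic import make_design, sample_formula_library, simulate_feature_table

        design = make_design(seed=0)
        lib = sample_formula_library(5, (85, 500), seed=0)
        cvs = []
        for seed in range(20):
            table, _ = simulate_feature_table(design, lib, seed=seed, is_cv_target_percent=5.0)
            cvs.append(internal_standard_cv(table, "IS_phenylalanine", design).cv_percent)
        assert all(2.0 <= cv <= 9.0 for cv in cvs)


class TestMassNormalize:
    def test_equal_masses_rescale_globally(self, toy_blank_table):
        design = StudyDesign(
            sample_groups={"s1": "A", "s2": "A", "b1": "blank"}, blanks={"b1"},
            reference_group="A", sample_mass_mg={"s1": 20.0, "s2": 20.0},
        )
        out = mass_normalize(toy_blank_table, design)
        np.testing.assert_allclose(
            out.intensities[:, :2], toy_blank_table.intensities[:, :2] / 20.0
        )
        # blanks untouched
        np.testing.assert_array_equal(out.intensities[:, 2], toy_blank_table.intensities[:, 2])

    def test_half_mass_doubles_normalized_signal(self, toy_blank_table, toy_design):
        out = mass_normalize(toy_blank_table, toy_design)  # masses 30 and 15
        np.testing.assert_allclose(out.intensities[:, 1], 2.0 * out.intensities[:, 0])

    def test_round_trip_restores_matrix(self, toy_blank_table, toy_design):
        out = mass_normalize(toy_blank_table, toy_design)
        back = out.intensities.copy()
        back[:, 0] *= 30.0
        back[:, 1] *= 15.0
        np.testing.assert_allclose(back, toy_blank_table.intensities, atol=1e-12)

    def test_missing_mass_names_sample(self, toy_blank_table):
        design = StudyDesign(
            sample_groups={"s1": "A", "s2": "A", "b1": "blank"}, blanks={"b1"},
            reference_group="A", sample_mass_mg={"s1": 30.0},
        )
        with pytest.raises(ValueError, match="s2"):
            mass_normalize(toy_blank_table, design)
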