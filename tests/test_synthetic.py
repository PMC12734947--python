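"""Ground-truth properties of the synthetic feature-table generator."""

import numpy as np
import pytest

from soilstoich.assign import ElementBounds
from soilstoich.formula import (
    DEFAULT_RULES,
    PROTON_MASS,
    FormulaRules,
    element_ratio_rules,
    monoisotopic_mass,
    parse_formula,
    rdbe,
)
from soilstoich.synthetic import (
    make_design,
    sample_formula_library,
    simulate_feature_table,
    simulate_stoichiometric_cohort,
)


class TestFormulaLibrary:
    def test_forced_water_window(self):
        """In [18,19] Da with only H and O allowed, water is the unique formula."""
        lib = sample_formula_library(
            1,
            (18.0, 19.0),
            seed=0,
            rules=FormulaRules(min_carbon=0),
            bounds=ElementBounds(c=0, h=5, n=0, o=2, p=0, s=0),
            isotope_gate=False,
        )
        assert lib[0].hill_formula() == "H2O"

    def test_same_seed_same_library(self):
        a = sample_formula_library(100, (85, 500), seed=7)
        b = sample_formula_library(100, (85, 500), seed=7)
        assert a == b

    def test_all_formulas_pass_assignment_rules(self):
        lib = sample_formula_library(100, (85, 500), seed=3)
        for f in lib:
            report = element_ratio_rules(f, DEFAULT_RULES)
            assert report.passed
            assert rdbe(f) >= 0
            assert 85 <= monoisotopic_mass(f) <= 500

    def test_impossible_range_raises(self):
        with pytest.raises(ValueError):
            sample_formula_library(1, (10, 5), seed=0)
        with pytest.raises(RuntimeError):
            sample_formula_library(
                1, (18.0, 18.2), seed=0, max_tries=2000
            )  # no CHNOPS organic passes default gates there

    def test_p_lambda_shifts_phosphorus_content(self):
        low = sample_formula_library(300, (150, 800), seed=5, p_lambda=0.4)
        high = sample_formula_library(300, (150, 800), seed=5, p_lambda=5.0)
        assert np.mean([f.p for f in high]) > np.mean([f.p for f in low]) + 1.0


class TestSimulatedTable:
    def _design(self):
        return make_design(groups=("pasture", "treated"), n_per_group=3, seed=0)

    def test_zero_noise_zero_effect_constant_rows(self):
        design = self._design()
        lib = sample_formula_library(10, (85, 400), seed=1)
        table, _ = simulate_feature_table(
            design, lib, noise_sigma=0.0, ppm_sigma=0.0, seed=1,
            add_internal_standards=False,
        )
        cols = [table.sample_index(s) for s in design.non_blank_samples]
        sub = table.intensities[:, cols]
        assert (sub == sub[:, [0]]).all()

    def test_glutamine_mz_at_zero_ppm(self):
        design = self._design()
        lib = [parse_formula("C5H10N2O3")]
        table, _ = simulate_feature_table(
            design, lib, ppm_sigma=0.0, seed=0, add_internal_standards=False
        )
        assert table.mz[0] == pytest.approx(145.0619, abs=5e-5)

    def test_recorded_mz_recomputable_from_truth(self):
        design = self._design()
        lib = sample_formula_library(50, (85, 500), seed=2)
        table, truth = simulate_feature_table(design, lib, seed=2, add_internal_standards=False)
        expect = (truth.true_masses - PROTON_MASS) * (1 + truth.ppm_errors * 1e-6)
        np.testing.assert_array_equal(table.mz, expect)
        assert (np.abs(truth.ppm_errors) <= 1.5).all()  # 3 sigma at 0.5 ppm

    def test_zero_ppm_round_trip_to_true_mass(self):
        design = self._design()
        lib = sample_formula_library(20, (85, 500), seed=4)
        table, truth = simulate_feature_table(
            design, lib, ppm_sigma=0.0, seed=4, add_internal_standards=False
        )
        np.testing.assert_allclose(table.mz + PROTON_MASS, truth.true_masses, atol=1e-9)

    def test_same_seed_byte_identical(self):
        design = self._design()
        lib = sample_formula_library(30, (85, 500), seed=6)
        t1, _ = simulate_feature_table(design, lib, seed=6)
        t2, _ = simulate_feature_table(design, lib, seed=6)
        np.testing.assert_array_equal(t1.intensities, t2.intensities)
        np.testing.assert_array_equal(t1.mz, t2.mz)
        np.testing.assert_array_equal(t1.rt_min, t2.rt_min)

    def test_planted_twofold_effect_realized(self):
        """Mean realized log2 FC across 300 features within +-0.1 of the planted 1.0."""
        design = make_design(groups=("pasture", "treated"), n_per_group=4, seed=0)
        lib = sample_formula_library(300, (85, 500), seed=8)
        table, _ = simulate_feature_table(
            design, lib, effects={"treated": 1.0, "pasture": 0.0}, seed=8,
            add_internal_standards=False,
        )
        tr = [table.sample_index(s) for s in design.samples_in_group("treated")]
        ref = [table.sample_index(s) for s in design.samples_in_group("pasture")]
        log2fc = np.log2(table.intensities[:, tr].mean(axis=1)) - np.log2(
            table.intensities[:, ref].mean(axis=1)
        )
        assert abs(log2fc.mean() - 1.0) <= 0.1

    def test_scan_window_consistency(self):
        design = self._design()
        lib = sample_formula_library(120, (85, 1000), seed=9)
        table, _ = simulate_feature_table(design, lib, seed=9, add_internal_standards=False)
        early = table.rt_min < 9.0
        assert (table.mz[early] <= 800.0).all()
        assert (table.mz[~early] >= 110.0).all()

    def test_blank_features_low_and_subset(self):
        design = make_design(groups=("pasture", "treated"), n_per_group=3, n_blanks=2, seed=1)
        lib = sample_formula_library(50, (85, 500), seed=10)
        table, truth = simulate_feature_table(design, lib, seed=10, add_internal_standards=False)
        bl = [table.sample_index(s) for s in design.blank_samples]
        nz = {table.feature_ids[i] for i in np.nonzero(table.intensities[:, bl].sum(axis=1))[0]}
        assert nz == truth.blank_features
        assert len(nz) == round(0.2 * 50)

    def test_invalid_parameters_rejected(self):
        design = self._design()
        lib = sample_formula_library(5, (85, 400), seed=0)
        with pytest.raises(ValueError):
            simulate_feature_table(design, lib, noise_sigma=-1.0, seed=0)
        lonely = make_design(groups=("pasture", "treated"), n_per_group=1, seed=0)
        with pytest.raises(ValueError, match="two samples"):
            simulate_feature_table(lonely, lib, seed=0)


def test_cohort_plants_reference_low_phosphorus_ratios():
    coh = simulate_stoichiometric_cohort(seed=0, n_features_per_group=150)
    med = coh.groupby("group")["ratio_cp"].median()
    assert med["pasture"] == med.min()
    control = simulate_stoichiometric_cohort(
        seed=0, n_features_per_group=150, p_lambda_reference=0.4
    )
    med_c = control.groupby("group")["ratio_cp"].median()
    assert med_c.max() - med_c.min() < med.max() - med.min()
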