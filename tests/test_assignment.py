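"""Candidate enumeration vs an independent brute-force oracle, ranking, library match."""

import numpy as np
import pytest

from soilstoich.assign import (
    AssignmentConfig,
    ElementBounds,
    enumerate_candidates,
    match_library,
    ppm_tolerance,
    rank_candidates,
    LibraryEntry,
)
from soilstoich.formula import PROTON_MASS, monoisotopic_mass, parse_formula
from soilstoich.tables import FeatureTable

from conftest import brute_force_candidates

SMALL_BOUNDS = ElementBounds(c=20, h=40, n=8, o=12, p=3, s=3)
SMALL_CONFIG = AssignmentConfig(bounds=SMALL_BOUNDS)


@pytest.mark.parametrize(
    "mass, expected", [(180.06, 2.0), (750.0, 5.0), (500.0, 5.0), (499.999, 2.0)]
)
def test_ppm_tolerance_mass_regimes(mass, expected):
    assert ppm_tolerance(mass) == expected


def test_glucose_mz_yields_glucose_candidate():
    mz = monoisotopic_mass(parse_formula("C6H12O6")) - PROTON_MASS
    cands = enumerate_candidates(mz)
    formulas = [c.formula for c in cands]
    assert "C6H12O6" in formulas
    hit = cands[formulas.index("C6H12O6")]
    assert abs(hit.mz_error_ppm) < 1e-6
    assert hit.rdbe == 1.0
    assert hit.isotope_score >= 30.0


def test_mz_far_from_any_formula_gives_empty_list():
    # 85.00000 Da: nearest CHNOPS formulas sit far outside a 2 ppm window
    assert enumerate_candidates(85.00000) == []


def test_widening_tolerance_never_removes_candidates():
    mz = 231.02765
    tight = {c.formula for c in enumerate_candidates(mz, AssignmentConfig(ppm_low=2.0))}
    wide = {c.formula for c in enumerate_candidates(mz, AssignmentConfig(ppm_low=5.0))}
    assert tight <= wide


def test_enumeration_matches_brute_force_oracle_spot_checks():
    """Vectorised enumeration must set-equal the naive nested-loop oracle."""
    rng = np.random.default_rng(42)
    for mz in rng.uniform(85.0, 300.0, size=8):
        fast = {c.formula for c in enumerate_candidates(float(mz), SMALL_CONFIG)}
        slow = brute_force_candidates(float(mz), SMALL_BOUNDS)
        assert fast == slow, f"mismatch at m/z {mz}"


def test_candidates_respect_all_gates():
    for c in enumerate_candidates(445.123):
        assert abs(c.mz_error_ppm) <= 2.0
        assert c.rdbe >= 0
        assert c.isotope_score >= 30.0
        assert c.rule_report.passed


class TestRanking:
    def _mk(self, formula, score, ppm):
        from soilstoich.assign import CandidateFormula
        from soilstoich.formula import rdbe, element_ratio_rules

        f = parse_formula(formula)
        return CandidateFormula(
            elements=f,
            theoretical_mass=monoisotopic_mass(f),
            mz_error_ppm=ppm,
            rdbe=rdbe(f),
            isotope_score=score,
            rule_report=element_ratio_rules(f),
        )

    def test_single_candidate_gets_rank_one(self):
        (only,) = rank_candidates([self._mk("C6H12O6", 50, 0.5)])
        assert only.rank == 1

    def test_at_most_three_returned(self):
        cands = [self._mk("C6H12O6", 50 - i, 0.1 * i) for i in range(5)]
        top = rank_candidates(cands)
        assert len(top) == 3 and [c.rank for c in top] == [1, 2, 3]

    def test_order_score_then_ppm_then_hill(self):
        a = self._mk("C7H14O6", 60, 1.0)
        b = self._mk("C6H12O6", 70, 1.5)   # higher score wins despite worse ppm
        c = self._mk("C8H16O6", 60, 0.2)   # same score as a, better ppm
        top = rank_candidates([a, b, c])
        assert [x.formula for x in top] == ["C6H12O6", "C8H16O6", "C7H14O6"]

    def test_full_tie_breaks_on_hill_string(self):
        a = self._mk("C9H16O4", 40, 0.3)
        b = self._mk("C5H8N4O3", 40, 0.3)
        top = rank_candidates([a, b])
        assert [x.formula for x in top] == sorted([a.formula, b.formula])


def test_match_library_two_gates():
    """3-entry library vs 4 features; one RT off by 1.6 min -> 2 annotations."""
    glucose = monoisotopic_mass(parse_formula("C6H12O6"))
    glutamine = monoisotopic_mass(parse_formula("C5H10N2O3"))
    citrate = monoisotopic_mass(parse_formula("C6H8O7"))
    library = [
        LibraryEntry("glucose", glucose, 3.0),
        LibraryEntry("glutamine", glutamine, 5.0),
        LibraryEntry("citrate", citrate, 8.0),
    ]
    table = FeatureTable(
        feature_ids=["hit1", "hit2", "rt_off", "mass_off"],
        mz=[
            glucose - PROTON_MASS,
            glutamine - PROTON_MASS,
            citrate - PROTON_MASS,              # RT 1.6 min away -> rejected
            glucose * (1 + 6e-6) - PROTON_MASS,  # 6 ppm heavy -> rejected
        ],
        rt_min=[3.2, 4.8, 9.6, 3.0],
        samples=["s1"],
        intensities=np.ones((4, 1)),
    )
    ann = match_library(table, library)
    assert ann == {"hit1": "glucose", "hit2": "glutamine"}


def test_match_library_nearest_ppm_wins():
    base = 200.0
    library = [
        LibraryEntry("close", base * (1 + 1e-6), 5.0),
        LibraryEntry("closer", base, 5.0),
    ]
    table = FeatureTable(
        feature_ids=["f"], mz=[base - PROTON_MASS], rt_min=[5.0],
        samples=["s1"], intensities=np.ones((1, 1)),
    )
    assert match_library(table, library) == {"f": "closer"}
    with pytest.raises(ValueError):
        match_library(table, [])
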