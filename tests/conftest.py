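"""Shared fixtures: tiny hand-checkable tables and synthetic helpers."""

from __future__ import annotations

import numpy as np
import pytest

from soilstoich.formula import (
    DEFAULT_RULES,
    MONOISOTOPIC_MASS,
    ElementCounts,
    element_ratio_rules,
    monoisotopic_mass,
)
from soilstoich.isotopes import placeholder_isotope_score, theoretical_isotope_pattern
from soilstoich.tables import FeatureTable, StudyDesign


@pytest.fixture
def toy_blank_table() -> FeatureTable:
    """Five features with sample/blank means (400/100, 300/100, 50/0, 10/100, 90/30)."""
    return FeatureTable(
        feature_ids=[f"f{i}" for i in range(1, 6)],
        mz=[100.0, 110.0, 120.0, 130.0, 140.0],
        rt_min=[1.0, 2.0, 3.0, 4.0, 5.0],
        samples=["s1", "s2", "b1"],
        intensities=np.array(
            [
                [400.0, 400.0, 100.0],
                [300.0, 300.0, 100.0],
                [50.0, 50.0, 0.0],
                [10.0, 10.0, 100.0],
                [90.0, 90.0, 30.0],
            ]
        ),
    )


@pytest.fixture
def toy_design() -> StudyDesign:
    return StudyDesign(
        sample_groups={"s1": "A", "s2": "A", "b1": "blank"},
        blanks={"b1"},
        reference_group="A",
        sample_mass_mg={"s1": 30.0, "s2": 15.0},
    )


def separated_groups(seed: int, n_groups: int = 6, n_per: int = 4,
                     n_vars: int = 50, sd_ratio: float = 3.0):
    """Strongly separated gaussian clusters (between/within variance >= sd_ratio^2)."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, sd_ratio, (n_groups, n_vars))
    X = np.vstack([means[g] + rng.normal(0.0, 1.0, (n_per, n_vars)) for g in range(n_groups)])
    y = np.repeat([f"g{g}" for g in range(n_groups)], n_per)
    return X, y


def brute_force_candidates(mz: float, bounds, rules=DEFAULT_RULES,
                           tol_low: float = 2.0, tol_high: float = 5.0,
                           isotope_score_min: float = 30.0) -> set[str]:
    """Independent naive nested-loop formula enumeration with identical filters.

    Loops every (C, N, O, P, S) combination inside ``bounds``; for each, the
    hydrogen loop is bounded by the mass window (hydrogen's ~1.008 Da step
    makes the admissible range explicit).  Returns Hill-formula strings.
    """
    from soilstoich.formula import PROTON_MASS

    target = mz + PROTON_MASS
    tol_ppm = tol_low if target < 500.0 else tol_high
    tol = tol_ppm * 1e-6 * target
    mc, mh, mn, mo, mp, ms = (MONOISOTOPIC_MASS[e] for e in "chnops")
    found: set[str] = set()
    for c in range(bounds.c + 1):
        base_c = c * mc
        if base_c > target + tol:
            break
        for n in range(bounds.n + 1):
            base_n = base_c + n * mn
            if base_n > target + tol:
                break
            for o in range(bounds.o + 1):
                base_o = base_n + o * mo
                if base_o > target + tol:
                    break
                for p in range(bounds.p + 1):
                    base_p = base_o + p * mp
                    if base_p > target + tol:
                        break
                    for s in range(bounds.s + 1):
                        base = base_p + s * ms
                        if base > target + tol:
                            break
                        h_min = max(0, int(np.ceil((target - tol - base) / mh)))
                        h_max = min(bounds.h, int(np.floor((target + tol - base) / mh)))
                        for h in range(h_min, h_max + 1):
                            mass = base + h * mh
                            if abs(mass - target) > tol:
                                continue
                            if c + h + n + o + p + s < 1:
                                continue
                            f = ElementCounts(c=c, h=h, n=n, o=o, p=p, s=s)
                            if not element_ratio_rules(f, rules).passed:
                                continue
                            score = placeholder_isotope_score(
                                theoretical_isotope_pattern(f)
                            )
                            if score < isotope_score_min:
                                continue
                            found.add(f.hill_formula())
    return found


def perturbed_mz(formulas, ppm_sigma: float, seed: int) -> np.ndarray:
    """[M-H]- m/z values with truncated (+-3 sigma) gaussian ppm errors."""
    from soilstoich.formula import PROTON_MASS

    rng = np.random.default_rng(seed)
    out = []
    for f in formulas:
        e = rng.normal(0.0, ppm_sigma)
        while abs(e) > 3 * ppm_sigma:
            e = rng.normal(0.0, ppm_sigma)
        out.append((monoisotopic_mass(f) - PROTON_MASS) * (1.0 + e * 1e-6))
    return np.asarray(out)
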