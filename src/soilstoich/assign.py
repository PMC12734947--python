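"""Candidate molecular-formula assignment for unknown [M-H]- features.

For each unknown m/z the assigner enumerates every CHNOPS formula whose
deprotonated ion falls inside a mass-dependent ppm window (2 ppm below 500 Da,
5 ppm at and above), keeps those that pass the element-ratio/RDBE plausibility
rules and the isotope-match gate, and ranks the survivors.  Unknown features
that match nothing stay at MSI level 4; known features are annotated against a
compound library on exact mass and retention time.

The enumeration is exhaustive within configurable element bounds.  It runs on
a vectorised precomputed grid over (C, N, O, P, S); because the hydrogen mass
(~1.008 Da) dwarfs any ppm window, the hydrogen count is solved rather than
looped, which makes per-feature assignment a handful of numpy passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .formula import (
    DEFAULT_RULES,
    ELEMENTS,
    MONOISOTOPIC_MASS,
    ElementCounts,
    FormulaRules,
    RuleReport,
    element_ratio_rules,
    monoisotopic_mass,
    mz_from_neutral_mass,
    neutral_mass_from_mz,
)
from .isotopes import (
    PLACEHOLDER_ABUNDANCE_ERROR,
    PLACEHOLDER_OBSERVED,
    isotope_match_score,
    theoretical_isotope_pattern,
)

#: Mass regime boundary: below this neutral mass the tighter window applies.
PPM_REGIME_BOUNDARY_DA = 500.0


def ppm_tolerance(neutral_mass: float, low: float = 2.0, high: float = 5.0) -> float:
    """Mass-accuracy window in ppm: `low` below 500 Da, `high` at/above.

    The 500 Da boundary itself is assigned to the wider (high-mass) regime.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return low if neutral_mass < PPM_REGIME_BOUNDARY_DA else high


@dataclass(frozen=True)
class ElementBounds:
    """Inclusive upper bounds on atom counts during enumeration.

    Defaults are sized so exhaustive enumeration to 1000 Da stays fast while
    covering plausible soil-metabolite compositions.
    """

    c: int = 70
    h: int = 120
    n: int = 20
    o: int = 30
    p: int = 8
    s: int = 8

    def as_tuple(self) -> tuple[int, ...]:
        return (self.c, self.h, self.n, self.o, self.p, self.s)


DEFAULT_BOUNDS = ElementBounds()


@dataclass(frozen=True)
class AssignmentConfig:
    """Tolerances, bounds and gates for candidate enumeration."""

    bounds: ElementBounds = DEFAULT_BOUNDS
    rules: FormulaRules = DEFAULT_RULES
    ppm_low: float = 2.0
    ppm_high: float = 5.0
    isotope_score_min: float = 30.0
    abundance_error: float = PLACEHOLDER_ABUNDANCE_ERROR
    top_k: int = 3


DEFAULT_CONFIG = AssignmentConfig()


@dataclass
class CandidateFormula:
    """One enumerated candidate formula for an unknown feature."""

    elements: ElementCounts
    theoretical_mass: float
    mz_error_ppm: float  # signed: (observed m/z - theoretical m/z)/theoretical * 1e6
    rdbe: float
    isotope_score: float
    rule_report: RuleReport
    rank: int | None = None

    @property
    def formula(self) -> str:
        return self.elements.hill_formula()


@lru_cache(maxsize=4)
def _candidate_grid(bounds: ElementBounds):
    """Precomputed (C,N,O,P,S) grid with hydrogen-free masses."""
    c = np.arange(bounds.c + 1, dtype=np.int16)
    n = np.arange(bounds.n + 1, dtype=np.int16)
    o = np.arange(bounds.o + 1, dtype=np.int16)
    p = np.arange(bounds.p + 1, dtype=np.int16)
    s = np.arange(bounds.s + 1, dtype=np.int16)
    C, N, O, P, S = np.meshgrid(c, n, o, p, s, indexing="ij", copy=False)
    grid = np.stack([g.ravel() for g in (C, N, O, P, S)], axis=1)
    mass = (
        grid[:, 0] * MONOISOTOPIC_MASS["c"]
        + grid[:, 1] * MONOISOTOPIC_MASS["n"]
        + grid[:, 2] * MONOISOTOPIC_MASS["o"]
        + grid[:, 3] * MONOISOTOPIC_MASS["p"]
        + grid[:, 4] * MONOISOTOPIC_MASS["s"]
    )
    order = np.argsort(mass, kind="stable")
    return grid[order], mass[order]


def enumerate_candidates(
    mz: float, config: AssignmentConfig = DEFAULT_CONFIG,
    observed_pattern: tuple[float, ...] | None = None,
) -> list[CandidateFormula]:
    """All retained candidate formulas for an observed [M-H]- m/z, ranked.

    A formula is retained iff its deprotonated m/z lies within the
    mass-regime ppm window of the observation, it passes the element-ratio and
    RDBE rules, and its isotope-match score against the observed pattern (the
    5% placeholder unless measured abundances are supplied) is at least the
    configured minimum.  An empty list means the feature stays unassigned.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    target = neutral_mass_from_mz(mz)
    tol_ppm = ppm_tolerance(target, config.ppm_low, config.ppm_high)
    tol_da = tol_ppm * 1e-6 * target

    grid, base_mass = _candidate_grid(config.bounds)
    stop = int(np.searchsorted(base_mass, target + tol_da, side="right"))
    grid, base_mass = grid[:stop], base_mass[:stop]
    mh = MONOISOTOPIC_MASS["h"]
    h = np.rint((target - base_mass) / mh).astype(np.int64)
    total = base_mass + h * mh
    ok = (h >= 0) & (h <= config.bounds.h) & (np.abs(total - target) <= tol_da)
    # a window can straddle two hydrogen counts only if tol_da > mh/2 (never
    # at ppm scale), so the rounded h is the unique solution

    obs = PLACEHOLDER_OBSERVED if observed_pattern is None else observed_pattern
    out: list[CandidateFormula] = []
    for idx in np.nonzero(ok)[0]:
        ci, ni, oi, pi, si = (int(v) for v in grid[idx])
        f = ElementCounts(c=ci, h=int(h[idx]), n=ni, o=oi, p=pi, s=si)
        report = element_ratio_rules(f, config.rules)
        if not report.passed:
            continue
        score = isotope_match_score(
            obs, theoretical_isotope_pattern(f), config.abundance_error
        )
        if score < config.isotope_score_min:
            continue
        theo_mass = float(total[idx])
        theo_mz = mz_from_neutral_mass(theo_mass)
        out.append(
            CandidateFormula(
                elements=f,
                theoretical_mass=theo_mass,
                mz_error_ppm=(mz - theo_mz) / theo_mz * 1e6,
                rdbe=report.rdbe,
                isotope_score=score,
                rule_report=report,
            )
        )
    return rank_candidates(out, k=len(out)) if out else out


def rank_candidates(cands: list[CandidateFormula], k: int = 3) -> list[CandidateFormula]:
    """Top-k candidates under the deterministic ranking.

    Stable sort by isotope score (descending), then |ppm error| (ascending),
    then Hill-order formula string (ascending) as a final tiebreak; the rank
    field on the returned candidates is set 1..k.
    """
    ranked = sorted(
        cands, key=lambda c: (-c.isotope_score, abs(c.mz_error_ppm), c.formula)
    )[: max(k, 0)]
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


@dataclass(frozen=True)
class LibraryEntry:
    """A known compound: name, neutral monoisotopic mass, expected RT."""

    name: str
    neutral_mass: float
    rt_min: float
    elements: ElementCounts | None = None

    def __post_init__(self):
        if self.neutral_mass <= 0:
            raise ValueError(f"library entry {self.name!r}: mass must be positive")
        if self.rt_min < 0:
            raise ValueError(f"library entry {self.name!r}: RT must be non-negative")

    @classmethod
    def from_formula(cls, name: str, elements: ElementCounts, rt_min: float) -> "LibraryEntry":
        return cls(name=name, neutral_mass=monoisotopic_mass(elements),
                   rt_min=rt_min, elements=elements)


def match_library(
    table, library: list[LibraryEntry], ppm: float = 5.0, rt_window_min: float = 1.5
) -> dict[str, str]:
    """Annotate features against a compound library; returns feature id -> name.

    A feature matches an entry iff the observed neutral mass agrees within
    ±ppm of the entry mass AND retention times agree within the RT window.
    When several entries match, the smallest ppm deviation wins.  Features
    with no match remain unannotated (MSI level 4).
    """
    if not library:
        raise ValueError("compound library is empty")
    annotations: dict[str, str] = {}
    for fid, mz, rt in zip(table.feature_ids, table.mz, table.rt_min):
        obs_mass = neutral_mass_from_mz(float(mz))
        best: tuple[float, str] | None = None
        for entry in library:
            dmass = abs(obs_mass - entry.neutral_mass)
            if dmass <= ppm * 1e-6 * entry.neutral_mass and abs(float(rt) - entry.rt_min) <= rt_window_min:
                dppm = dmass / entry.neutral_mass * 1e6
                if best is None or dppm < best[0]:
                    best = (dppm, entry.name)
        if best is not None:
            annotations[fid] = best[1]
    return annotations


def assign_table(table, config: AssignmentConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Enumerate and rank candidates for every feature in a table.

    Returns a long-format frame: feature_id, rank, formula (Hill order),
    theoretical_mass, mz_error_ppm, rdbe, isotope_score, rdbe_integer.
    Unassigned features contribute no rows.
    """
    rows = []
    for fid, mz in zip(table.feature_ids, table.mz):
        for cand in rank_candidates(enumerate_candidates(float(mz), config), config.top_k):
            rows.append(
                {
                    "feature_id": fid,
                    "rank": cand.rank,
                    "formula": cand.formula,
                    "theoretical_mass": cand.theoretical_mass,
                    "mz_error_ppm": cand.mz_error_ppm,
                    "rdbe": cand.rdbe,
                    "isotope_score": cand.isotope_score,
                    "rdbe_integer": cand.rule_report.rdbe_integer,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "rank", "formula", "theoretical_mass",
            "mz_error_ppm", "rdbe", "isotope_score", "rdbe_integer",
        ],
    )
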