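"""Composite formulas and elemental stoichiometric ratios.

A feature with up to three retained candidate formulas is summarised by a
*composite formula*: the element-wise average of its candidates, treating all
top-ranked formulas equally.  Elemental ratios (C/N, C/P, N/P; H/C and O/C
descriptively) computed from composites carry the structural uncertainty of
MSI-level-4 features into the group comparison without committing to any one
assignment.

Two averaging conventions are shipped, because "ratios were calculated using
a simple average" supports both:

* ``average-counts`` (default): average the element counts, then take ratios
  of the mean counts — the composite formula is the primary object;
* ``average-ratios``: compute each candidate's ratio, then average the
  defined ones.

A ratio is undefined (NaN, excluded per-ratio downstream) whenever its
denominator is zero; no pseudocounts are introduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import CandidateFormula
from .formula import ELEMENTS, ElementCounts, hill_formula

RATIO_NAMES = ("cn", "cp", "np")
_RATIO_ELEMENTS = {"cn": ("c", "n"), "cp": ("c", "p"), "np": ("n", "p"),
                   "hc": ("h", "c"), "oc": ("o", "c")}


@dataclass(frozen=True)
class CompositeFormula:
    """Per-feature averaged element counts with stoichiometric ratios.

    ``mean_counts`` maps element -> mean count (rational); ratios are NaN when
    undefined.  ``mode`` records which averaging convention produced the
    ratios.
    """

    feature_id: str
    mean_counts: dict[str, float]
    n_candidates: int
    ratio_cn: float
    ratio_cp: float
    ratio_np: float
    mode: str = "average-counts"

    def hill_formula(self) -> str:
        return hill_formula(self.mean_counts)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def composite_formula(
    cands: list[CandidateFormula | ElementCounts],
    mode: str = "average-counts",
    feature_id: str = "",
) -> CompositeFormula:
    """Average up to three candidate formulas into a composite.

    Candidates may be :class:`CandidateFormula` or bare :class:`ElementCounts`;
    all are weighted equally and order does not matter.
    """
    if not cands:
        raise ValueError("cannot build a composite from zero candidates")
    if mode not in ("average-counts", "average-ratios"):
        raise ValueError(f"unknown composite mode {mode!r}")
    counts = [c.elements if isinstance(c, CandidateFormula) else c for c in cands]
    mean_counts = {
        el: float(np.mean([getattr(f, el) for f in counts])) for el in ELEMENTS
    }
    if mode == "average-counts":
        ratios = {
            name: _safe_ratio(mean_counts[a], mean_counts[b])
            for name, (a, b) in _RATIO_ELEMENTS.items()
            if name in RATIO_NAMES
        }
    else:
        ratios = {}
        for name in RATIO_NAMES:
            a, b = _RATIO_ELEMENTS[name]
            per = [
                getattr(f, a) / getattr(f, b) for f in counts if getattr(f, b) > 0
            ]
            ratios[name] = float(np.mean(per)) if per else math.nan
    return CompositeFormula(
        feature_id=feature_id,
        mean_counts=mean_counts,
        n_candidates=len(counts),
        ratio_cn=ratios["cn"],
        ratio_cp=ratios["cp"],
        ratio_np=ratios["np"],
        mode=mode,
    )


def elemental_ratios(comp: CompositeFormula) -> tuple[float, float, float]:
    """(C/N, C/P, N/P) of the composite's mean counts; NaN where undefined."""
    m = comp.mean_counts
    return (
        _safe_ratio(m["c"], m["n"]),
        _safe_ratio(m["c"], m["p"]),
        _safe_ratio(m["n"], m["p"]),
    )


def descriptive_ratios(comp: CompositeFormula) -> dict[str, float]:
    """H/C and O/C of the mean counts, reported descriptively only."""
    m = comp.mean_counts
    return {"hc": _safe_ratio(m["h"], m["c"]), "oc": _safe_ratio(m["o"], m["c"])}


def composite_table(
    candidates: pd.DataFrame, mode: str = "average-counts"
) -> pd.DataFrame:
    """Composite formulas + ratios for a long-format candidate frame.

    Expects the output of :func:`soilstoich.assign.assign_table` (columns
    feature_id, rank, formula).  Returns one row per assigned feature:
    feature_id, composite_formula, n_candidates, mean element counts,
    ratio_cn/cp/np (NaN = undefined), ratio_hc/ratio_oc descriptive.
    """
    from .formula import parse_formula

    rows = []
    for fid, sub in candidates.groupby("feature_id", sort=False):
        cands = [parse_formula(f) for f in sub.sort_values("rank")["formula"]]
        comp = composite_formula(cands, mode=mode, feature_id=str(fid))
        desc = descriptive_ratios(comp)
        rows.append(
            {
                "feature_id": comp.feature_id,
                "composite_formula": comp.hill_formula(),
                "n_candidates": comp.n_candidates,
                **{f"mean_{el}": comp.mean_counts[el] for el in ELEMENTS},
                "ratio_cn": comp.ratio_cn,
                "ratio_cp": comp.ratio_cp,
                "ratio_np": comp.ratio_np,
                "ratio_hc": desc["hc"],
                "ratio_oc": desc["oc"],
                "mode": comp.mode,
            }
        )
    return pd.DataFrame(rows)


def ratio_outlier_trim(values) -> list[float]:
    """Values inside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (type 7).  Intended ONLY for rendering
    violin-style distribution summaries; statistical tests always run on the
    complete data.  Output preserves input order and is a subset of the input.
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        raise ValueError("need at least 4 values to trim outliers")
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [v for v in vals if lo <= v <= hi]
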