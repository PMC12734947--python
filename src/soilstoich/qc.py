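"""QA/QC gates: blank-based feature retention, internal-standard CV,
mass normalisation, and an injection-order drift diagnostic.

No batch or drift *correction* is applied anywhere — small runs do not support
the usual correction methods, so drift is only reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import FeatureTable, StudyDesign


def blank_filter(
    table: FeatureTable,
    design: StudyDesign,
    ratio: float = 3.0,
    blank_statistic: str = "mean",
) -> FeatureTable:
    """Retain features whose biological signal exceeds ``ratio`` x blank signal.

    A feature is kept iff mean non-blank intensity > ratio * blank signal
    (strict inequality, the conservative reading of "at least >3x").  The
    blank signal is the mean across blank samples by default; ``"max"`` is the
    stricter alternative.  Features entirely absent from blanks are kept
    whenever they carry any non-blank signal.  Feature order is preserved, so
    the filter is idempotent.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    blank_idx = [table.sample_index(s) for s in design.blank_samples if s in table.samples]
    if not blank_idx:
        raise ValueError(
            "blank filtering requested but the design contains no blank samples "
            "present in the table; skip this step instead"
        )
    sample_idx = [table.sample_index(s) for s in design.non_blank_samples if s in table.samples]
    if not sample_idx:
        raise ValueError("no non-blank samples in table")
    sample_mean = table.intensities[:, sample_idx].mean(axis=1)
    if blank_statistic == "mean":
        blank_sig = table.intensities[:, blank_idx].mean(axis=1)
    elif blank_statistic == "max":
        blank_sig = table.intensities[:, blank_idx].max(axis=1)
    else:
        raise ValueError(f"unknown blank statistic {blank_statistic!r}")
    keep = sample_mean > ratio * blank_sig
    return table.subset_features(keep)


@dataclass(frozen=True)
class CvResult:
    """Internal-standard coefficient of variation, in percent."""

    feature_id: str
    cv_percent: float
    passed: bool
    threshold_percent: float
    n_samples: int


def internal_standard_cv(
    table: FeatureTable,
    feature_id: str,
    design: StudyDesign,
    threshold_percent: float = 30.0,
) -> CvResult:
    """CV (%) of an internal-standard feature across non-blank samples.

    CV = 100 * sample standard deviation / mean (ddof=1).  A zero mean leaves
    the CV undefined and raises.
    """
    if feature_id not in table.feature_ids:
        raise KeyError(f"internal standard {feature_id!r} not in table")
    idx = [table.sample_index(s) for s in design.non_blank_samples if s in table.samples]
    if len(idx) < 2:
        raise ValueError("need at least 2 non-blank samples for a CV")
    values = table.intensities[table.feature_index(feature_id), idx]
    mean = values.mean()
    if mean == 0:
        raise ValueError(f"internal standard {feature_id!r} has zero mean; CV undefined")
    cv = 100.0 * values.std(ddof=1) / mean
    return CvResult(
        feature_id=feature_id,
        cv_percent=float(cv),
        passed=bool(cv <= threshold_percent),
        threshold_percent=threshold_percent,
        n_samples=len(idx),
    )


def mass_normalize(
    table: FeatureTable, design: StudyDesign, drop_blanks: bool = False
) -> FeatureTable:
    """Divide each non-blank sample's intensity column by its sample mass (mg).

    Blank columns are left untouched, or dropped when ``drop_blanks``.  Raises
    naming the first sample with a missing mass.
    """
    matrix = table.intensities.copy()
    keep_cols = []
    for j, s in enumerate(table.samples):
        if s in design.blanks:
            if not drop_blanks:
                keep_cols.append(j)
            continue
        if s not in design.sample_mass_mg:
            raise ValueError(f"sample {s!r} has no recorded mass; cannot mass-normalize")
        matrix[:, j] = matrix[:, j] / design.sample_mass_mg[s]
        keep_cols.append(j)
    return FeatureTable(
        feature_ids=list(table.feature_ids),
        mz=table.mz.copy(),
        rt_min=table.rt_min.copy(),
        samples=[table.samples[j] for j in keep_cols],
        intensities=matrix[:, keep_cols],
    )


def injection_order_drift(
    table: FeatureTable, feature_id: str, design: StudyDesign
) -> dict:
    """Report-only diagnostic: IS intensity regressed on injection order.

    Returns the slope per injection, Pearson r and n; no correction is made.
    """
    if not design.injection_order:
        raise ValueError("design has no injection-order information")
    row = table.intensities[table.feature_index(feature_id)]
    pairs = [
        (design.injection_order[s], row[table.sample_index(s)])
        for s in design.non_blank_samples
        if s in design.injection_order and s in table.samples
    ]
    order = np.array([p[0] for p in pairs], dtype=float)
    inten = np.array([p[1] for p in pairs], dtype=float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 ordered samples for a drift diagnostic")
    slope, intercept = np.polyfit(order, inten, 1)
    r = float(np.corrcoef(order, inten)[0, 1]) if inten.std() > 0 else 0.0
    return {"feature_id": feature_id, "slope": float(slope),
            "intercept": float(intercept), "pearson_r": r, "n": len(pairs)}
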