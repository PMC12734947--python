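"""Intensity-matrix preprocessing.

Two fixed preprocessing chains are used downstream, mirroring the distinct
treatment of identified metabolites and unknown spectral features:

* identified metabolites: mass-normalize -> log -> Pareto;
* unknown features: quantile-normalize -> IQR filter -> log -> Pareto.

All operations take and return (features x samples) arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every sample (column) onto the common quantile profile.

    The target profile is the row-wise mean of the column-sorted matrix; tied
    values within a column receive the average of the target values their rank
    range spans.  After the transform every column has an identical sorted
    value vector.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.any(X):
        raise ValueError("all-zero matrix cannot be quantile-normalized")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # 1-based, ties averaged
        # average rank r maps to linear interpolation of the target at r-1
        out[:, j] = np.interp(ranks - 1.0, np.arange(X.shape[0]), target)
    return out


def iqr_filter(
    matrix: np.ndarray, drop_fraction: float = 0.25, feature_ids: list[str] | None = None
) -> np.ndarray:
    """Drop the least-variable features by interquartile range.

    Removes floor(drop_fraction * n_features) features with the smallest IQR
    across samples; ties broken by feature id (or row order when ids are
    absent) so the result is deterministic.  Returns the boolean keep-mask;
    apply it to the matrix and any parallel metadata.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    n_drop = int(np.floor(drop_fraction * n))
    keep = np.ones(n, dtype=bool)
    if n_drop == 0:
        return keep
    q1, q3 = np.percentile(X, [25, 75], axis=1)
    iqr = q3 - q1
    tiebreak = feature_ids if feature_ids is not None else list(range(n))
    order = sorted(range(n), key=lambda i: (iqr[i], tiebreak[i]))
    keep[order[:n_drop]] = False
    return keep


def log_offset(matrix: np.ndarray) -> float:
    """Zero-handling offset: half the smallest positive value in the matrix."""
    X = np.asarray(matrix, dtype=float)
    positive = X[X > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive entries")
    return float(positive.min() / 2.0)


def log_pareto(
    matrix: np.ndarray, offset: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform then Pareto-scale each feature (row).

    x -> (log(x + offset) - mean) / sqrt(sd), with the sample sd (ddof=1) of
    the logged values; Pareto scaling divides by the square root of the sd,
    damping fold-change dominance less aggressively than unit-variance
    scaling.  Zero-variance features are centered only (all-zero rows) and
    flagged.  Returns (scaled matrix, constant-feature flag vector).
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("intensities must be non-negative before log transform")
    if offset is None:
        offset = log_offset(X)
    logged = np.log(X + offset)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    scale = np.sqrt(np.where(sd > 0, sd, 1.0))
    return (logged - mean) / scale, constant


def preprocess_unknown(
    matrix: np.ndarray, drop_fraction: float = 0.25, feature_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-normalize -> IQR filter -> log -> Pareto (unknown features).

    Returns (processed matrix, keep-mask into the original feature axis).
    """
    qn = quantile_normalize(matrix)
    keep = iqr_filter(qn, drop_fraction, feature_ids)
    scaled, _ = log_pareto(qn[keep])
    return scaled, keep


def preprocess_identified(matrix: np.ndarray) -> np.ndarray:
    """log -> Pareto for an already mass-normalized identified-metabolite matrix."""
    scaled, _ = log_pareto(matrix)
    return scaled
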