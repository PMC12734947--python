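"""Theoretical isotope patterns and isotopic-abundance match scoring.

With survey-scan (MS1-only) data and no curated isotopic measurements, isotope
scoring runs against a fixed placeholder pattern of 5% relative abundance for
the A+1..A+3 isotopologue peaks with a 5% abundance error, so that the score
still discriminates between candidate formulas whose *theoretical* patterns
differ.  The theoretical pattern itself is computed exactly, by polynomial
convolution of the per-element natural isotope distributions, truncated after
the A+3 peak.
"""

from __future__ import annotations

import numpy as np

from .formula import ELEMENTS, ElementCounts

#: Natural isotopic abundance by nucleon offset from the lightest isotope,
#: as fractions summing to ~1 (IUPAC representative values).
ISOTOPE_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "c": (0.9893, 0.0107),
    "h": (0.999885, 0.000115),
    "n": (0.99636, 0.00364),
    "o": (0.99757, 0.00038, 0.00205),
    "p": (1.0,),
    # 32S, 33S, 34S, (35S absent), 36S
    "s": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: Placeholder observed A+1..A+3 relative abundances (% of the monoisotopic
#: peak) used when no measured isotope data accompany a feature table.
PLACEHOLDER_OBSERVED = (5.0, 5.0, 5.0)
#: Matching abundance error (percentage points) for the placeholder regime.
PLACEHOLDER_ABUNDANCE_ERROR = 5.0


def _power_truncated(dist: np.ndarray, count: int, n_peaks: int) -> np.ndarray:
    """dist convolved with itself `count` times, truncated to n_peaks+1 terms.

    Exponentiation by squaring; truncation after each convolution is exact for
    the retained low-order terms because convolution is lower-triangular in
    nucleon offset.
    """
    result = np.zeros(n_peaks + 1)
    result[0] = 1.0
    base = dist[: n_peaks + 1].copy()
    while count:
        if count & 1:
            result = np.convolve(result, base)[: n_peaks + 1]
        count >>= 1
        if count:
            base = np.convolve(base, base)[: n_peaks + 1]
    return result


def theoretical_isotope_pattern(f: ElementCounts, n_peaks: int = 3) -> tuple[float, ...]:
    """Relative abundances of the A+1..A+n_peaks peaks, in % of the A peak.

    Exact polynomial expansion: the isotopologue distribution of the molecule
    is the convolution product over elements of each element's single-atom
    distribution raised to its atom count, truncated after A+n_peaks.
    """
    pattern = np.zeros(n_peaks + 1)
    pattern[0] = 1.0
    for el in ELEMENTS:
        count = getattr(f, el)
        if count:
            dist = np.asarray(ISOTOPE_ABUNDANCE[el])
            pattern = np.convolve(pattern, _power_truncated(dist, count, n_peaks))
            pattern = pattern[: n_peaks + 1]
    if pattern[0] <= 0:  # cannot happen for finite counts, guard anyway
        raise ValueError("monoisotopic abundance vanished")
    return tuple(100.0 * pattern[1:] / pattern[0])


def isotope_match_score(
    observed: tuple[float, ...] | np.ndarray,
    theoretical: tuple[float, ...] | np.ndarray,
    abundance_error: float = PLACEHOLDER_ABUNDANCE_ERROR,
) -> float:
    """Similarity (0-100) between observed and theoretical A+1..A+3 abundances.

    score = 100 * mean_i max(0, 1 - |obs_i - theo_i| / max(obs_i, theo_i, err)),
    where err is the abundance error in percentage points.  Equals 100 iff the
    patterns agree exactly, and is monotone non-increasing in each peak's
    absolute deviation.
    """
    obs = np.asarray(observed, dtype=float)
    theo = np.asarray(theoretical, dtype=float)
    if obs.shape != theo.shape:
        raise ValueError("observed and theoretical patterns differ in length")
    if (obs < 0).any() or (theo < 0).any() or abundance_error < 0:
        raise ValueError("abundances and abundance_error must be non-negative")
    denom = np.maximum.reduce([obs, theo, np.full_like(obs, abundance_error)])
    denom = np.where(denom == 0, 1.0, denom)  # obs=theo=err=0 scores 1 exactly
    per_peak = np.maximum(0.0, 1.0 - np.abs(obs - theo) / denom)
    return float(100.0 * per_peak.mean())


def placeholder_isotope_score(theoretical: tuple[float, ...] | np.ndarray) -> float:
    """Score of a theoretical pattern against the 5%/5%/5% placeholder."""
    return isotope_match_score(PLACEHOLDER_OBSERVED, theoretical)
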