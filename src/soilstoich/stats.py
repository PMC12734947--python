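"""Group comparison of stoichiometric ratios and features.

The design is anchored on a reference group (pasture in the motivating
study): a Kruskal-Wallis test across all groups is followed by pairwise
comparisons of each other group against the reference only, with Cohen's d
(primary, because rank tests alone say nothing about magnitude) and Cliff's
delta (rank-based, robust on skewed ratios) as effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

EFFECT_SIZE_CUTPOINTS = (0.2, 0.5, 0.8)  # negligible / small / medium / large


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (df = k - 1).

    ``groups`` labels each value; every group needs at least one value and
    there must be at least two groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one value")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def kruskal_wallis_exact(values, groups) -> tuple[float, float]:
    """Exact permutation p for the Kruskal-Wallis H (small samples only).

    Enumerates every assignment of the pooled values to groups of the
    observed sizes and reports P(H >= H_obs), observed arrangement included.
    Limited to total n <= 10, where the enumeration is cheap.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    n = len(values)
    if n > 10:
        raise ValueError("exact permutation p is limited to total n <= 10")
    h_obs, _ = kruskal_wallis(values, labels)
    uniq = list(pd.unique(labels))
    sizes = [int((labels == g).sum()) for g in uniq]

    idx_all = list(range(n))
    count = 0
    total = 0

    def splits(remaining: list[int], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield [remaining]
            return
        k = sizes_left[0]
        # fix the smallest remaining index into the first group to avoid
        # counting identical partitions when later sizes repeat? group labels
        # are distinguishable, so enumerate plain combinations
        for combo in combinations(remaining, k):
            rest = [i for i in remaining if i not in combo]
            for tail in splits(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    for parts in splits(idx_all, sizes):
        perm_labels = np.empty(n, dtype=object)
        for g, part in zip(uniq, parts):
            perm_labels[part] = g
        h, _ = kruskal_wallis(values, perm_labels)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return h_obs, count / total


def cohens_d(x, y) -> float:
    """Pooled-sd Cohen's d; positive when mean(x) exceeds mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("Cohen's d needs at least two values per group")
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        return 0.0 if x.mean() == y.mean() else math.inf * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross-group pairs."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    greater = (x > y).sum()
    less = (x < y).sum()
    return float((greater - less) / (x.size * y.size))


def effect_size_label(d: float) -> str:
    """Qualitative label at |d| cutpoints 0.2 / 0.5 / 0.8."""
    a = abs(d)
    if a < EFFECT_SIZE_CUTPOINTS[0]:
        return "negligible"
    if a < EFFECT_SIZE_CUTPOINTS[1]:
        return "small"
    if a < EFFECT_SIZE_CUTPOINTS[2]:
        return "medium"
    return "large"


@dataclass
class TestResult:
    """Statistics for one target (a ratio name or a feature id)."""

    target: str
    kw_h: float
    kw_p: float
    pairwise: pd.DataFrame  # group, p_value, cohens_d, cliffs_delta, label, significant
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.kw_p < self.alpha


def pairwise_vs_reference(
    values_by_group: dict[str, np.ndarray],
    reference: str,
    alpha: float = 0.05,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Each non-reference group vs the reference: MWU p and effect sizes.

    Returns a frame with one row per comparison group: two-sided
    Mann-Whitney U p-value, Cohen's d (positive when the group's mean exceeds
    the reference's), Cliff's delta, a qualitative |d| label, and the
    significance flag at ``alpha``.  ``test="dunn"`` is not implemented here;
    MWU is the shipped pairwise test.
    """
    if reference not in values_by_group:
        raise ValueError(f"reference group {reference!r} missing")
    ref = np.asarray(values_by_group[reference], dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("reference group has no finite values")
    if test != "mannwhitney":
        raise NotImplementedError(f"pairwise test {test!r} not implemented")
    rows = []
    for g, vals in values_by_group.items():
        if g == reference:
            continue
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"comparison group {g!r} has no finite values")
        _, p = sps.mannwhitneyu(v, ref, alternative="two-sided")
        d = cohens_d(v, ref)
        rows.append(
            {
                "group": g,
                "p_value": float(p),
                "cohens_d": d,
                "cliffs_delta": cliffs_delta(v, ref),
                "label": effect_size_label(d),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def compare_ratio_groups(
    ratio_values: pd.DataFrame,
    ratio_columns: tuple[str, ...] = ("ratio_cn", "ratio_cp", "ratio_np"),
    group_column: str = "group",
    reference: str | None = None,
    alpha: float = 0.05,
) -> list[TestResult]:
    """KW across groups plus pairwise-vs-reference for each ratio column.

    ``ratio_values`` holds one row per feature with its group label and ratio
    columns; NaN ratios (undefined denominators) are excluded per-ratio only.
    No multiple-testing correction is applied at the ratio level.
    """
    if reference is None:
        raise ValueError("a reference group is required")
    results = []
    for col in ratio_columns:
        sub = ratio_values[[group_column, col]].dropna()
        by_group = {
            g: grp[col].to_numpy() for g, grp in sub.groupby(group_column, sort=False)
        }
        h, p = kruskal_wallis(sub[col].to_numpy(), sub[group_column].to_numpy())
        pw = pairwise_vs_reference(by_group, reference, alpha=alpha)
        results.append(TestResult(target=col, kw_h=h, kw_p=p, pairwise=pw, alpha=alpha))
    return results


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def significant_feature_sets(
    table,
    design,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    correction: str = "bh",
    test: str = "welch",
) -> dict[str, set[str]]:
    """Per-group sets of features differing from the reference (volcano gates).

    For each non-reference group, a feature belongs to the set iff it passes
    both the p-value gate (vs the reference group, BH-adjusted across features
    by default) and the fold-change gate |log2 FC| >= ``min_abs_log2fc``
    computed from group means of the raw intensities.  The p-value comes from
    a Welch t-test on log2 intensities by default (``test="mannwhitney"`` for
    the rank alternative); these gates are package defaults, configurable.
    """
    if design.reference_group is None:
        raise ValueError("design has no reference group")
    if correction not in ("bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    ref_cols = [table.sample_index(s) for s in design.samples_in_group(design.reference_group)]
    offset = np.min(table.intensities[table.intensities > 0]) / 2.0 if np.any(table.intensities > 0) else 1.0
    log2x = np.log2(table.intensities + offset)
    sets: dict[str, set[str]] = {}
    for g in design.groups():
        if g == design.reference_group:
            continue
        cols = [table.sample_index(s) for s in design.samples_in_group(g)]
        a, b = log2x[:, cols], log2x[:, ref_cols]
        if test == "welch":
            _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        elif test == "mannwhitney":
            p = np.array(
                [sps.mannwhitneyu(a[i], b[i], alternative="two-sided")[1] for i in range(a.shape[0])]
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        p = np.nan_to_num(p, nan=1.0)
        if correction == "bh":
            p = benjamini_hochberg(p)
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        mask = (p < alpha) & (np.abs(log2fc) >= min_abs_log2fc)
        sets[g] = {table.feature_ids[i] for i in np.nonzero(mask)[0]}
    return sets


def upset_counts(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive intersection counts over every non-empty combination of sets.

    Each member of the union is counted under exactly the combination of set
    names it belongs to, so the counts partition the union (the quantities an
    UpSet plot displays).  Combinations with zero members are reported too.
    """
    if not sets:
        raise ValueError("need at least one set")
    names = list(sets)
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for item in set().union(*sets.values()):
        membership = frozenset(n for n in names if item in sets[n])
        counts[membership] += 1
    return counts


def upset_counts_frame(sets: dict[str, set]) -> pd.DataFrame:
    """Long-format exclusive intersection counts (combination, degree, count)."""
    counts = upset_counts(sets)
    rows = [
        {"combination": "&".join(sorted(k)), "degree": len(k), "count": v}
        for k, v in counts.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["degree", "combination"])
        .reset_index(drop=True)
    )
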