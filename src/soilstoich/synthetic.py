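"""Seeded synthetic LC-MS feature tables with known ground truth.

The generator emulates what the instrument workflow hands to the analysis:
negative-mode [M-H]- features from known CHNOPS formulas inside the scan
ranges (85-800 m/z before 9 min, 110-1000 m/z after), with Gaussian ppm-scale
mass error, log-normal intensities, group-dependent intensity and composition
effects, water blanks and two spiked internal standards.  Because every
feature's true formula, mass error and planted effect are recorded in a
:class:`SyntheticTruth` sidecar, every downstream stage has a recovery test.

All randomness flows through one integer seed; the same seed reproduces the
table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import DEFAULT_BOUNDS, ElementBounds
from .formula import (
    DEFAULT_RULES,
    ELEMENTS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    ElementCounts,
    FormulaRules,
    element_ratio_rules,
    monoisotopic_mass,
    parse_formula,
)
from .isotopes import placeholder_isotope_score, theoretical_isotope_pattern
from .tables import FeatureTable, StudyDesign

#: The six land-management groups of the motivating system; pasture is the
#: reference (its soils carry the planted phosphorus enrichment, so C/P and
#: N/P are lowest there).
DEFAULT_GROUPS = (
    "pasture",
    "conventional_cultivation",
    "organic_cultivation",
    "hardwood_forest",
    "white_pine",
    "tulip_poplar",
)

#: The two spiked internal standards of the emulated workflow.
INTERNAL_STANDARDS = {
    "IS_phenylalanine": "C9H11NO2",
    "IS_tryptophan": "C11H12N2O2",
}

# truncated-Poisson means for heteroatom counts in sampled formulas; the
# phosphorus mean is the knob the planted stoichiometric contrast turns
DEFAULT_N_LAMBDA = 1.5
DEFAULT_P_LAMBDA = 0.4
#: Reference-group phosphorus enrichment for the planted C/P and N/P contrast,
#: sized so the planted group difference is a large effect (Cohen's |d| ~ 1 or
#: more on both C/P and N/P at the default cohort size).
REFERENCE_P_LAMBDA = 5.0


def sample_formula_library(
    n: int,
    mass_range: tuple[float, float] = (85.0, 800.0),
    seed: int = 0,
    *,
    rules: FormulaRules = DEFAULT_RULES,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    n_lambda: float = DEFAULT_N_LAMBDA,
    p_lambda: float = DEFAULT_P_LAMBDA,
    s_prob: float = 0.08,
    isotope_gate: bool = True,
    isotope_score_min: float = 30.0,
    max_tries: int = 500_000,
) -> list[ElementCounts]:
    """Draw ``n`` plausible CHNOPS formulas with masses in ``mass_range``.

    Rejection sampling: carbon is sized from the target mass (carbon mass
    fractions typical of organic matter), N and P are truncated-Poisson, S is
    a rare coin flip, oxygen takes a random share of the remaining mass and
    hydrogen soaks up the rest.  Every returned formula passes the same
    element-ratio and RDBE rules the assignment stage enforces and, by
    default, the placeholder isotope-score gate — the generator and the filter
    stay consistent, so planted truths are recoverable in principle.

    ``p_lambda`` controls mean phosphorus content; sampling group sub-libraries
    with different ``p_lambda`` plants a stoichiometric composition shift.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    lo, hi = mass_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid mass range {mass_range!r}")
    mh = MONOISOTOPIC_MASS["h"]
    rng = np.random.default_rng(seed)
    out: list[ElementCounts] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not sample {n} formulas in {mass_range} Da after "
                f"{max_tries} proposals; constraints may be unsatisfiable"
            )
        target = rng.uniform(lo, hi)
        if rules.min_carbon >= 1 or bounds.c > 0:
            c = int(round(target * rng.uniform(0.30, 0.65) / MONOISOTOPIC_MASS["c"]))
            c = min(max(c, rules.min_carbon, 0), bounds.c)
        else:
            c = 0
        nn = min(int(rng.poisson(n_lambda)), bounds.n)
        p = min(int(rng.poisson(p_lambda)), bounds.p)
        s = int(rng.random() < s_prob) if bounds.s else 0
        partial = (
            c * MONOISOTOPIC_MASS["c"]
            + nn * MONOISOTOPIC_MASS["n"]
            + p * MONOISOTOPIC_MASS["p"]
            + s * MONOISOTOPIC_MASS["s"]
        )
        rest = target - partial
        if rest < 0:
            continue
        o = min(int(rest * rng.uniform(0.2, 0.9) / MONOISOTOPIC_MASS["o"]), bounds.o)
        partial += o * MONOISOTOPIC_MASS["o"]
        h_lo = int(np.ceil((lo - partial) / mh))
        h_hi = int(np.floor((hi - partial) / mh))
        h_lo, h_hi = max(h_lo, 0), min(h_hi, bounds.h)
        if h_hi < h_lo:
            continue
        h = int(rng.integers(h_lo, h_hi + 1))
        try:
            f = ElementCounts(c=c, h=h, n=nn, o=o, p=p, s=s)
        except ValueError:
            continue
        mass = monoisotopic_mass(f)
        if not (lo <= mass <= hi):
            continue
        if not element_ratio_rules(f, rules).passed:
            continue
        if isotope_gate and (
            placeholder_isotope_score(theoretical_isotope_pattern(f)) < isotope_score_min
        ):
            continue
        out.append(f)
    return out


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated feature table.

    For every feature: the true formula, true neutral monoisotopic mass, the
    applied signed ppm mass error (so the recorded m/z is exactly
    ``(mass - m_p) * (1 + ppm * 1e-6)``), the planted per-group log2 intensity
    effect, plus the generator's noise and blank parameters and the seed.
    """

    feature_ids: list[str]
    formulas: list[ElementCounts]
    true_masses: np.ndarray
    ppm_errors: np.ndarray
    group_log2_effects: dict[str, np.ndarray]
    noise_sigma: float
    blank_fraction: float
    blank_level: float
    blank_features: set[str]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "formula": [f.hill_formula() for f in self.formulas],
                "true_mass": self.true_masses,
                "ppm_error": self.ppm_errors,
                "in_blank": [fid in self.blank_features for fid in self.feature_ids],
            }
        )
        for g, eff in self.group_log2_effects.items():
            df[f"log2_effect_{g}"] = eff
        return df


def _truncated_normal(rng: np.random.Generator, sigma: float, size: int, nsig: float = 3.0) -> np.ndarray:
    """Gaussian draws with |x| <= nsig*sigma, by redrawing the tails."""
    if sigma == 0:
        return np.zeros(size)
    x = rng.normal(0.0, sigma, size)
    bad = np.abs(x) > nsig * sigma
    while bad.any():
        x[bad] = rng.normal(0.0, sigma, int(bad.sum()))
        bad = np.abs(x) > nsig * sigma
    return x


def simulate_feature_table(
    design: StudyDesign,
    library: list[ElementCounts],
    effects: dict[str, np.ndarray | float] | None = None,
    noise_sigma: float = 0.35,
    ppm_sigma: float = 0.5,
    seed: int = 0,
    *,
    blank_fraction: float = 0.2,
    blank_level: float = 0.1,
    is_cv_target_percent: float = 5.0,
    base_log_intensity: float = np.log(1e6),
    feature_spread: float = 1.0,
    add_internal_standards: bool = True,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate an [M-H]- feature table over a study design.

    * m/z: true neutral mass minus a proton, perturbed by a Gaussian ppm error
      truncated at +-3 sigma (Orbitrap-like accuracy envelope);
    * retention times: uniform over the 25-min gradient, constrained so each
      feature's m/z lies in the active scan window (85-800 before 9 min,
      110-1000 after);
    * intensities: log-normal around a per-feature baseline; group effects are
      per-feature log2 multipliers added on the log scale;
    * blanks: a random ``blank_fraction`` of features appears in blank samples
      at ``blank_level`` x the feature's baseline;
    * internal standards: two spiked features present in every non-blank
      sample at a target CV.
    """
    if noise_sigma < 0 or ppm_sigma < 0:
        raise ValueError("noise and ppm sigmas must be non-negative")
    groups = design.groups()
    if len(groups) < 2:
        raise ValueError("design needs at least two non-blank groups")
    for g in groups:
        if len(design.samples_in_group(g)) < 2:
            raise ValueError(f"group {g!r} needs at least two samples")
    rng = np.random.default_rng(seed)
    m = len(library)
    ids = [f"F{i+1:05d}" for i in range(m)]
    masses = np.array([monoisotopic_mass(f) for f in library])
    ppm = _truncated_normal(rng, ppm_sigma, m)
    mz = (masses - PROTON_MASS) * (1.0 + ppm * 1e-6)

    rt = np.empty(m)
    for i, v in enumerate(mz):
        if v < 110.0:
            rt[i] = rng.uniform(0.0, 9.0)
        elif v > 800.0:
            rt[i] = rng.uniform(9.0, 25.0)
        else:
            rt[i] = rng.uniform(0.0, 25.0)

    eff: dict[str, np.ndarray] = {}
    for g in groups:
        e = (effects or {}).get(g, 0.0)
        eff[g] = np.full(m, float(e)) if np.isscalar(e) else np.asarray(e, dtype=float)
        if eff[g].shape != (m,):
            raise ValueError(f"effects for group {g!r} must be scalar or length {m}")

    base = base_log_intensity + rng.normal(0.0, feature_spread, m)
    samples = list(design.sample_groups)
    matrix = np.zeros((m, len(samples)))
    blank_ids = set()
    if design.blank_samples:
        n_blank_feat = int(round(blank_fraction * m))
        chosen = rng.choice(m, size=n_blank_feat, replace=False) if n_blank_feat else []
        blank_ids = {ids[i] for i in chosen}
    # contamination sits at blank_level x the *median* feature intensity, so
    # low-abundance contaminated features genuinely fail the 3x retention rule
    # while abundant ones clear it
    blank_signal = blank_level * float(np.exp(np.median(base)))
    for j, s in enumerate(samples):
        if s in design.blanks:
            for i in range(m):
                if ids[i] in blank_ids:
                    jitter = rng.normal(0.0, noise_sigma) if noise_sigma else 0.0
                    matrix[i, j] = blank_signal * np.exp(jitter)
        else:
            g = design.sample_groups[s]
            noise = rng.normal(0.0, noise_sigma, m) if noise_sigma else np.zeros(m)
            matrix[:, j] = np.exp(base + np.log(2.0) * eff[g] + noise)

    table = FeatureTable(
        feature_ids=ids, mz=mz, rt_min=rt, samples=samples, intensities=matrix
    )

    if add_internal_standards:
        is_sigma = float(np.sqrt(np.log1p((is_cv_target_percent / 100.0) ** 2)))
        is_rows, is_ids, is_mz, is_rt = [], [], [], []
        for name, formula in INTERNAL_STANDARDS.items():
            f = parse_formula(formula)
            is_ids.append(name)
            is_mz.append(monoisotopic_mass(f) - PROTON_MASS)
            is_rt.append(rng.uniform(1.0, 9.0))
            row = np.zeros(len(samples))
            for j, s in enumerate(samples):
                if s not in design.blanks:
                    row[j] = 5e6 * np.exp(rng.normal(0.0, is_sigma) - is_sigma**2 / 2)
            is_rows.append(row)
        table = FeatureTable(
            feature_ids=ids + is_ids,
            mz=np.concatenate([mz, is_mz]),
            rt_min=np.concatenate([rt, is_rt]),
            samples=samples,
            intensities=np.vstack([matrix, np.array(is_rows)]),
        )

    truth = SyntheticTruth(
        feature_ids=ids,
        formulas=list(library),
        true_masses=masses,
        ppm_errors=ppm,
        group_log2_effects=eff,
        noise_sigma=noise_sigma,
        blank_fraction=blank_fraction,
        blank_level=blank_level,
        blank_features=blank_ids,
        seed=seed,
    )
    return table, truth


def make_design(
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    n_per_group: int = 4,
    n_blanks: int = 2,
    reference: str = "pasture",
    seed: int = 0,
    sample_mass_mg: float = 30.0,
) -> StudyDesign:
    """A balanced study design with water blanks and randomized injection order."""
    rng = np.random.default_rng(seed)
    sample_groups: dict[str, str] = {}
    masses: dict[str, float] = {}
    for g in groups:
        for i in range(n_per_group):
            sid = f"{g}_{i+1}"
            sample_groups[sid] = g
            masses[sid] = float(sample_mass_mg * rng.uniform(0.9, 1.1))
    blanks = set()
    for i in range(n_blanks):
        sid = f"blank_{i+1}"
        sample_groups[sid] = "blank"
        blanks.add(sid)
    order = list(sample_groups)
    rng.shuffle(order)
    return StudyDesign(
        sample_groups=sample_groups,
        blanks=blanks,
        reference_group=reference,
        sample_mass_mg=masses,
        injection_order={s: i + 1 for i, s in enumerate(order)},
        internal_standard_ids=list(INTERNAL_STANDARDS),
    )


def simulate_stoichiometric_cohort(
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    reference: str = "pasture",
    n_features_per_group: int = 300,
    seed: int = 0,
    *,
    p_lambda_reference: float = REFERENCE_P_LAMBDA,
    p_lambda_other: float = DEFAULT_P_LAMBDA,
    mass_range: tuple[float, float] = (150.0, 800.0),
) -> pd.DataFrame:
    """Per-group feature formulas with a planted reference phosphorus shift.

    Each group's features are drawn from its own formula sub-library; the
    reference group's library is enriched in phosphorus (higher truncated-
    Poisson mean P count), so its C/P and N/P ratios are planted lowest —
    the qualitative pattern the package is meant to recover.  Setting both
    lambdas equal gives the no-effect control.

    Returns a long frame: group, feature_id, formula, ratio_cn/cp/np (NaN
    where the denominator element is absent).
    """
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups")
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        lam = p_lambda_reference if g == reference else p_lambda_other
        sub_seed = int(rng.integers(0, 2**31 - 1))
        lib = sample_formula_library(
            n_features_per_group, mass_range, seed=sub_seed, p_lambda=lam
        )
        for i, f in enumerate(lib):
            rows.append(
                {
                    "group": g,
                    "feature_id": f"{g}_F{i+1:04d}",
                    "formula": f.hill_formula(),
                    "ratio_cn": f.c / f.n if f.n else np.nan,
                    "ratio_cp": f.c / f.p if f.p else np.nan,
                    "ratio_np": f.n / f.p if f.p else np.nan,
                }
            )
    return pd.DataFrame(rows)
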