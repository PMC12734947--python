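# Methods

`soilstoich` implements an MS¹-only untargeted metabolomics analysis for soil
extracts measured by negative-mode LC-HRMS: it carries unknown spectral
features (accurate m/z + retention time, MSI level 4) through molecular-formula
assignment, composite-formula stoichiometry, and group statistics, without ever
requiring MS² spectra or structural identification. This note records the
models, the defaults and why they are what they are, what the synthetic-data
generator does and does not emulate, and the numerical choices a maintainer
would want written down.

## 1. Formula assignment from accurate mass

**Adduct model.** Every feature is treated as the deprotonated ion [M-H]⁻,
so the neutral monoisotopic mass is `M = m/z + 1.007276466` Da. The constant
is the proton mass with the electron mass implicitly included — the standard
negative-mode convention. No other adducts, halogens or silicon are
considered; the chemistry is restricted to C, H, N, O, P, S.

**Mass windows.** Candidates must match within 2 ppm for neutral masses below
500 Da and 5 ppm at or above 500 Da (the boundary is assigned to the wider,
high-mass regime), reflecting typical Orbitrap accuracy after external
calibration.

**Enumeration.** The assigner enumerates *every* CHNOPS formula inside the
window, exhaustively within element bounds (defaults C ≤ 70, H ≤ 120, N ≤ 20,
O ≤ 30, P ≤ 8, S ≤ 8, chosen so enumeration at 1000 Da completes in
milliseconds per feature; all configurable). Implementation: a cached grid
over (C, N, O, P, S) with hydrogen-free masses, sorted by mass; because the
hydrogen mass (~1.008 Da) is vastly larger than any ppm window, the hydrogen
count is solved by rounding rather than looped, making each assignment a few
vectorised passes. The test suite holds this path set-equal to an independent
naive nested-loop enumeration.

**Plausibility rules.** A candidate is retained only if (a) it passes
element-ratio ranges of the Seven-Golden-Rules family — C ≥ 1,
H/C ∈ [0.2, 3.1], N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8 — and (b) its
ring-and-double-bond equivalents are non-negative. RDBE is computed as
`C − H/2 + (N+P)/2 + 1` (O, S divalent, P trivalent; a pentavalent-P variant
would subtract differently and is deliberately not the default, since the
trivalent convention is the usual one for screening organics). RDBE
*integrality* — the nitrogen-rule parity — is reported per candidate but never
used to reject, because even/odd-electron bookkeeping for deprotonated ions
is ambiguous. All numeric bounds are config-overridable.

**Isotope scoring without isotope data.** With survey scans only, measured
isotopologue abundances are usually unavailable, so scoring uses a placeholder
observed pattern of 5% for A+1, A+2 and A+3 with a 5% abundance error, and
retains candidates scoring ≥ 30%. The theoretical pattern is exact: per-element
isotope distributions are raised to their atom counts and convolved
(exponentiation by squaring, truncated after A+3 — exact for the retained
terms because convolution is lower-triangular in nucleon offset). The score is

```
score = 100 × mean_i max(0, 1 − |obs_i − theo_i| / max(obs_i, theo_i, err))
```

which is 100 exactly when the patterns agree and decreases monotonically in
each peak's deviation. Under the placeholder this gate passes typical organics
(roughly C ≥ 4–5, since A+1 ≈ 1.08% per carbon) and rejects patterns far from
5%; it is a *comparative* device, not a claim about the true isotopologues.

**Ranking.** Up to three candidates are kept per feature, sorted by isotope
score (descending), then |ppm error| (ascending), then Hill-order formula
string — fully deterministic. A caveat measured on synthetic data: at 300-500
Da a 2-ppm window contains on average ~9-25 gate-passing formulas, so the
*ranked* position of the true formula is limited by candidate density; the
candidate *set* contains the truth essentially always (100% in the shipped
recovery run), but top-3 membership is ~40-50%. Downstream stoichiometry
therefore leans on composites over the top candidates rather than on any
single assignment being right.

**Known compounds.** Features are matched against an in-house library by
neutral mass (±5 ppm of the entry mass) and retention time (|ΔRT| ≤ 1.5 min);
the nearest-ppm entry wins ties. Everything unmatched stays MSI level 4.

## 2. Composite formulas and stoichiometric ratios

Each assigned feature is summarised by the element-wise mean of its retained
candidates — the *composite formula* — treating all top-ranked candidates
equally. Ratios C/N, C/P and N/P are then taken from the mean counts
(`average-counts`, the default). The alternative reading, averaging
per-candidate ratios over candidates where defined (`average-ratios`), is also
shipped because the averaging order is genuinely ambiguous in words; the two
agree whenever candidates share the denominator count, and every report names
the mode used. H/C and O/C are computed descriptively only.

A ratio is undefined exactly when its denominator mean count is zero; such
features are excluded from that ratio's statistics only (no pseudocounts — a
nitrogen-free phosphometabolite still contributes C/P and an N/P of zero).

For distribution plots an IQR trim (Tukey fences at 1.5×IQR, type-7 linear
quartiles — the convention matters because it changes which points are
trimmed) is available; statistics always run on untrimmed values.

## 3. QA/QC

* **Blank rule.** A feature is retained iff its mean non-blank intensity is
  *strictly* greater than `ratio ×` the blank signal, default ratio 3. The
  blank signal is the mean over blank samples (a max-over-blanks option
  exists); features absent from blanks are kept whenever they carry signal —
  this division-free form avoids 0/0. The filter is idempotent.
* **Internal standards.** CV (%) = 100 × sd/mean (sample sd, ddof = 1) over
  non-blank samples, with a configurable pass threshold (default 30%,
  deliberately loose — the emulated workflow's standards ran at 2-6%).
* **Mass normalisation.** Identified-metabolite intensities are divided by
  sample mass (mg) before log transformation; blanks are left untouched or
  dropped.
* **Drift.** Internal-standard intensity versus injection order is available
  as a report-only regression; no batch or drift *correction* is applied —
  runs this small do not support the usual correction methods.

## 4. Preprocessing and group statistics

Two fixed chains, logged with feature counts at every step:

* identified metabolites: mass-normalise → log → Pareto;
* unknown features: quantile-normalise → IQR filter (drop the least-variable
  25% by default, ties broken by feature id) → log → Pareto.

Quantile normalisation maps every sample column onto the row-wise mean of the
column-sorted matrix, averaging ties; afterwards all columns share one sorted
value vector. The log offset for zeros is half the smallest positive matrix
entry. Pareto scaling divides centred logged values by the square root of
their sd, so the scaled variance equals the sd of the logged values —
an identity the tests assert; zero-variance features are centred and flagged.

Ratios are compared across land-management groups with a tie-corrected
Kruskal-Wallis test (chi-square p, df = k−1; an exhaustive-permutation p is
available for total n ≤ 10 — at such sizes the chi-square approximation can
be off by more than 0.2 in absolute p, which is why the exact option exists),
followed by pairwise two-sided Mann-Whitney U tests of each group against the
reference (pasture) only. Effect sizes: Cohen's d on the ratio scale
(pooled sd; positive when the comparison group exceeds the reference;
labels negligible/small/medium/large at |d| = 0.2/0.5/0.8) with Cliff's delta
reported alongside, since d on skewed ratios is fragile. No multiplicity
correction is applied across the five ratio-level comparisons (mirroring how
such panels are usually presented); feature-level volcano screening defaults
to Benjamini-Hochberg.

Volcano-style feature sets per group use a Welch t-test on log2 intensities
(rank alternative available) with gates p < 0.05 (BH-adjusted) and
|log2 FC| ≥ 1 — package defaults, flagged as such in reports since the
emulated workflow never printed its thresholds. Exclusive intersection counts
over the per-group sets (the quantities an UpSet plot draws) are exported in
long format; they partition the union by construction.

## 5. PLS-DA, VIP and Q²

PLS-DA regresses the centred one-hot class matrix on the preprocessed
intensity matrix by PLS2/NIPALS (scikit-learn's `PLSRegression` provides the
core decomposition). Determinism is guaranteed by fixing the sign convention:
per component, the largest-magnitude weight entry is made positive, flipping
(w, t, p, q) together.

* **R²** = 1 − RSS/TSS on the class matrix, full fit.
* **Q²** = 1 − PRESS/TSS, PRESS pooled over stratified k-fold held-out
  predictions, TSS from the centred full class matrix. Folds are seeded;
  each class's members are dealt round-robin to folds from a random start, so
  classes smaller than k degrade gracefully (they skip folds) instead of
  erroring.
* **VIP** for the first *a* components:
  `vip_j = sqrt( p · Σ_a ssy_a w_aj² / Σ_a ssy_a )` with unit-norm weight
  vectors and `ssy_a = (t_aᵀt_a)(q_aᵀq_a)` the class variance explained by
  component a. Mean squared VIP is exactly 1; VIP > 1 is the conventional
  importance threshold. VIP is reported for component 1 and cumulatively.

With six balanced classes the one-hot matrix has five degrees of freedom, so
two latent components cannot exceed R²Y ≈ 0.4 even on perfectly separated
data; the shipped six-group control therefore validates at five components,
where strongly separated clusters (between/within sd ratio 3) reach Q² ≳ 0.97
and label-permuted controls go negative.

## 6. The synthetic-data generator

The generator is the package's ground-truth instrument: it emulates what the
instrument workflow hands the analysis, not the instrument itself.

* **Formulas.** Rejection sampling: target mass uniform over the requested
  range (85-800 Da by default, inside the instrument scan limits); carbon
  sized from an organic-matter-like mass fraction U(0.30, 0.65); N and P
  truncated-Poisson (defaults λ_N = 1.5, λ_P = 0.4 — most metabolites carry
  no phosphorus); sulfur a rare coin flip (8%); oxygen a random share of the
  remaining mass; hydrogen solves the mass. Every emitted formula passes the
  assignment stage's ratio/RDBE rules *and* the placeholder isotope gate, so
  planted truths are recoverable in principle — generator and filter are one
  consistent system.
* **m/z.** Recorded m/z is exactly `(M − m_p)(1 + ppm·10⁻⁶)` with the ppm
  error Gaussian (σ = 0.5 ppm default) truncated at ±3σ by redrawing —
  an Orbitrap-like accuracy envelope with no outliers.
* **Retention times** are uniform over the 25-min gradient, constrained so
  each m/z lies in the active scan window (85-800 before 9 min, 110-1000
  after).
* **Intensities** are log-normal around a per-feature baseline (median 10⁶,
  feature spread σ = 1) with sample noise σ = 0.35 on the natural log
  (≈ 36% CV, typical for untargeted soil runs); group effects add
  `ln(2) × log2-effect` on the log scale.
* **Blanks** receive a random 20% of features at 1/10 of the *median* feature
  intensity, so the >3× rule removes low-abundance contaminated features and
  keeps abundant ones — the rule is exercised in both directions.
* **Internal standards** (the two spiked amino-acid standards of the emulated
  workflow) appear in every non-blank sample as log-normals at a 5% target CV
  (σ = sqrt(ln(1+CV²)), mean-corrected).
* **Planted stoichiometric contrast.** Group sub-libraries differ only in
  λ_P: the reference (pasture) library uses λ_P = 5 against 0.4 elsewhere,
  which realises Cohen's |d| ≈ 2 on C/P and ≈ 1 on N/P at 300 features per
  group — a deliberately *large* planted effect, the regime the motivating
  observations describe as moderate-to-large, with reference C/P and N/P
  planted lowest. These λ values are free parameters of the generator, not
  estimates of any real soil.

**What is not emulated:** chromatographic peak shapes, raw spectra or mzML,
measured isotopologue intensities, adducts beyond [M-H]⁻, in-source
fragments, instrument drift, or batch structure. Passing tests therefore
demonstrate correctness of the *analysis* under a clean feature-table model;
they do not certify behaviour under peak-picking artefacts or matrix effects,
which enter upstream of this package's inputs.

## 7. Problem sizes, seeds and determinism

Shipped validation runs use 200 features for formula recovery, 50 random m/z
for oracle equivalence, 20-seed Monte-Carlo panels for planted-effect
recovery and Q² controls, and a ~60-feature demo pipeline — sizes chosen so
the whole suite re-runs in well under a minute per stage on one core while
keeping Monte-Carlo margins wide. One master seed drives everything; per-stage
seeds are derived by hashing `seed:stage`, and rerunning any pipeline with the
same config and seed reproduces every output file byte-for-byte (floats are
written as `%.17g`, which round-trips IEEE doubles exactly). Output tables
carry the config hash and seed in `#` header lines.

## 8. Known limitations

* Ranked (top-3) identity of the true formula degrades above ~300 Da for the
  density reasons in §1; composites absorb much of this, single-candidate
  interpretations should not be made there.
* The placeholder isotope gate biases retention toward mid-carbon formulas;
  with measured isotopologue abundances (supported via the observed-pattern
  argument) both the gate and the ranking become far more informative.
* Cohen's d on ratio scales is sensitive to skew; Cliff's delta is co-reported
  and should be preferred when the two disagree.
* The exhaustive-permutation Kruskal-Wallis p is limited to n ≤ 10 by
  combinatorics.
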