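# soilstoich

Elemental stoichiometry of the *dark metabolome*: an MS¹-only analysis
pipeline for untargeted soil metabolomics.

Most spectral features detected in an untargeted LC-HRMS run of soil extracts
never get a structural identity — there are no MS² spectra for them and no
library matches. `soilstoich` is built on the observation that such MSI
level-4 features still carry usable chemistry: from accurate mass alone one
can enumerate the plausible CHNOPS molecular formulas, average them into a
*composite formula*, and compare elemental ratios (C/N, C/P, N/P) across
land-management groups — turning thousands of unidentified peaks into
stoichiometric evidence about nutrient cycling, without fragmentation data.

It is intended for environmental metabolomics practitioners with a
feature table (m/z, retention time, per-sample intensities) exported from
their peak-picking software, a sample design (groups, water blanks, sample
masses, spiked internal standards), and optionally an in-house compound
library.

## What it computes

For each unknown feature with observed m/z (negative mode, [M-H]⁻, so
M = m/z + 1.007276466 Da):

1. **Formula assignment** — exhaustive CHNOPS enumeration within a
   mass-dependent window (2 ppm below 500 Da, 5 ppm above), filtered by
   Seven-Golden-Rules-style element ratios (H/C ∈ [0.2, 3.1], N/C ≤ 1.3,
   O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8), RDBE = C − H/2 + (N+P)/2 + 1 ≥ 0, and an
   isotope-pattern match score ≥ 30% (against a 5%/5%/5% placeholder pattern
   when no measured isotopologue abundances exist). Up to three candidates are
   kept, ranked deterministically.
2. **Composite stoichiometry** — the element-wise mean over the retained
   candidates, with ratios C/N = C̄/N̄ etc. (an average-of-ratios mode is also
   shipped); ratios with zero denominators are flagged undefined and excluded
   per-ratio.
3. **QA/QC** — blank-based retention (keep iff mean sample signal > 3× mean
   blank signal), internal-standard CV, mass normalisation; drift is reported,
   never corrected.
4. **Group statistics** — Kruskal-Wallis across groups plus pairwise
   Mann-Whitney U against the reference group only, with Cohen's d and
   Cliff's delta; volcano-style significant-feature sets per group and their
   exclusive intersection counts (UpSet-ready).
5. **Multivariate** — PLS-DA (NIPALS PLS2 on the one-hot class matrix) with
   VIP scores (mean VIP² = 1; VIP > 1 flags importance) and seeded stratified
   k-fold R²/Q².

A seeded synthetic-data generator emulates the whole input side — [M-H]⁻
features from known formulas in the instrument scan ranges, ppm-scale mass
error, log-normal intensities, water blanks, spiked internal standards, and
planted group effects — so every stage has a ground-truth recovery test.
See `docs/methods.md` for the full model description and defaults.

## Worked example

Assign a formula to the deprotonated glucose ion and build its composite:

```python
from soilstoich import enumerate_candidates, rank_candidates, composite_formula

cands = rank_candidates(enumerate_candidates(179.05612), 3)
for c in cands:
    print(f"rank {c.rank}: {c.formula}  mass {c.theoretical_mass:.5f}  "
          f"{c.mz_error_ppm:+.2f} ppm  RDBE {c.rdbe:.1f}  isotope score {c.isotope_score:.1f}")
```

```
rank 1: C6H12O6  mass 180.06339  +0.05 ppm  RDBE 1.0  isotope score 34.4
```

At this mass the 2-ppm window contains exactly one rule-passing formula; the
composite equals it, C/N and C/P are undefined (no N, no P), and the feature
would be reported as a pure-CHO composite.

Run the whole pipeline on a self-generated synthetic study (six
land-management groups of four samples, two water blanks, two internal
standards):

```
$ soilstoich run-all --seed 0 --out demo
pipeline complete; outputs in demo
  input: 62 features
  post_blank_filter: 61 features
  assigned: 59 features
  composites: 59 features
  IS_phenylalanine: CV 4.22%
  IS_tryptophan: CV 5.45%
```

One contaminated low-abundance feature failed the >3× blank rule; 59 of the
remaining 59 unknowns (the two internal standards are treated as identified)
received at least one candidate formula; both spiked standards pass the 30%
CV gate comfortably. The output directory then holds `candidates.csv`,
`composites.csv`, `ratio_stats.csv` (Kruskal-Wallis H and p per ratio with
pairwise effect sizes vs pasture), `significant_features.csv`,
`upset_counts.csv`, `vip.csv`, `plsda_scores.csv` and `plsda_summary.csv`,
every file stamped with the config hash and seed. Rerunning with the same
seed reproduces each CSV byte-for-byte.

Single stages are available as `soilstoich simulate | qc | assign | ratios |
stats | plsda`, and from Python via `run_pipeline(PipelineConfig(...))`.

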