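"""End-to-end pipeline driver.

Fixed stage order: QC -> formula assignment -> composites/ratios ->
group statistics -> multivariate -> set summaries.  Each stage logs its
input/output feature counts; identical config + seed reproduce the report
bundle byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .assign import AssignmentConfig, ElementBounds, assign_table
from .config import PipelineConfig
from .formula import DEFAULT_RULES
from .plsda import PLSDA, cross_validate
from .preprocess import preprocess_unknown
from .qc import blank_filter, internal_standard_cv, mass_normalize
from .stats import compare_ratio_groups, significant_feature_sets, upset_counts_frame
from .stoichiometry import composite_table
from .synthetic import make_design, sample_formula_library, simulate_feature_table
from .tables import FeatureTable, StudyDesign

log = logging.getLogger("soilstoich")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineReport:
    """Paths and key numbers from a completed run."""

    output_dir: Path
    feature_counts: dict[str, int] = field(default_factory=dict)
    is_cvs: dict[str, float] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full pipeline described by ``config``.

    When no feature table is configured, the synthetic stage generates one
    (with its truth sidecar) so the demo run is self-contained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash only the scientific parameters, not file locations, so reruns of
    # the same analysis into different directories share a provenance hash
    hashed = {
        k: v
        for k, v in config.to_dict().items()
        if k not in ("feature_table", "design_table", "library_table", "output_dir")
    }
    prov = {"config_hash": sio.config_hash(hashed), "seed": config.seed}
    report = PipelineReport(output_dir=out)

    def emit(df: pd.DataFrame, name: str) -> None:
        sio.write_csv(df, out / name, prov)
        report.files.append(name)

    # ---- inputs / synthetic stage -------------------------------------
    stage = "input"
    try:
        if config.feature_table:
            table = sio.read_feature_table(config.feature_table)
            design = sio.read_design(config.design_table)
        else:
            stage = "simulate"
            sseed = config.stage_seed("simulate")
            design = make_design(seed=sseed)
            library = sample_formula_library(
                config.n_synthetic_features,
                config.synthetic_mass_range,
                seed=config.stage_seed("library"),
            )
            # plant intensity effects: in every non-reference group a random
            # subset of features is shifted, so the downstream volcano and
            # set-intersection stages have structure to find in a demo run
            eff_rng = np.random.default_rng(config.stage_seed("effects"))
            m = len(library)
            effects = {}
            for g in design.groups():
                e = np.zeros(m)
                if g != design.reference_group and config.planted_fraction > 0:
                    k = int(round(config.planted_fraction * m))
                    chosen = eff_rng.choice(m, size=k, replace=False)
                    e[chosen] = config.planted_effect_log2 * eff_rng.choice(
                        [-1.0, 1.0], size=k
                    )
                effects[g] = e
            table, truth = simulate_feature_table(
                design,
                library,
                effects=effects,
                noise_sigma=config.noise_sigma,
                ppm_sigma=config.ppm_sigma,
                seed=sseed,
            )
            sio.write_feature_table(table, out / "feature_table.csv", prov)
            sio.write_design(design, out / "design.csv", prov)
            emit(truth.to_dataframe(), "synthetic_truth.csv")
            report.files.extend(["feature_table.csv", "design.csv"])
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - report the stage then fail
        raise StageError(stage, e) from e
    report.feature_counts["input"] = table.n_features
    log.info("input: %d features, %d samples", table.n_features, len(table.samples))

    # ---- QC -----------------------------------------------------------
    try:
        if config.apply_blank_filter:
            table = blank_filter(table, design, config.blank_ratio, config.blank_statistic)
        qc_rows = []
        for fid in design.internal_standard_ids:
            if fid in table.feature_ids:
                cv = internal_standard_cv(table, fid, design, config.is_cv_limit_percent)
                report.is_cvs[fid] = cv.cv_percent
                qc_rows.append(
                    {"feature_id": fid, "cv_percent": cv.cv_percent, "passed": cv.passed}
                )
        emit(pd.DataFrame(qc_rows, columns=["feature_id", "cv_percent", "passed"]),
             "qc_internal_standards.csv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", e) from e
    report.feature_counts["post_blank_filter"] = table.n_features
    log.info("qc: %d features retained", table.n_features)

    # ---- formula assignment ------------------------------------------
    try:
        acfg = AssignmentConfig(
            ppm_low=config.ppm_low,
            ppm_high=config.ppm_high,
            isotope_score_min=config.isotope_score_min,
            top_k=config.top_k,
        )
        # internal standards are identified compounds, not unknowns
        unknown = table.subset_features(
            [i for i, fid in enumerate(table.feature_ids)
             if fid not in design.internal_standard_ids]
        )
        candidates = assign_table(unknown, acfg)
        emit(candidates, "candidates.csv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("assignment", e) from e
    n_assigned = candidates["feature_id"].nunique()
    report.feature_counts["assigned"] = int(n_assigned)
    log.info("assignment: %d/%d features assigned", n_assigned, unknown.n_features)

    # ---- composites / ratios ------------------------------------------
    try:
        composites = composite_table(candidates, mode=config.composite_mode)
        emit(composites, "composites.csv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("stoichiometry", e) from e
    report.feature_counts["composites"] = len(composites)

    # ---- group statistics ---------------------------------------------
    try:
        groups = design.groups()
        sets = significant_feature_sets(
            unknown, design, alpha=config.alpha,
            min_abs_log2fc=config.min_abs_log2fc,
            correction=config.multiple_testing,
        )
        set_rows = [
            {"group": g, "feature_id": fid} for g, s in sets.items() for fid in sorted(s)
        ]
        emit(pd.DataFrame(set_rows, columns=["group", "feature_id"]),
             "significant_features.csv")
        emit(upset_counts_frame(sets), "upset_counts.csv")

        # ratio-level comparison: each feature's ratios are attributed to the
        # groups whose significant set contains it; features significant
        # nowhere form the reference group's baseline distribution
        ratio_cols = ["ratio_cn", "ratio_cp", "ratio_np"]
        by_feature = composites.set_index("feature_id")[ratio_cols]
        ratio_rows = []
        in_any = set().union(*sets.values()) if sets else set()
        for fid in by_feature.index:
            if fid not in in_any:
                ratio_rows.append({"group": design.reference_group, "feature_id": fid,
                                   **by_feature.loc[fid].to_dict()})
        for g, s in sets.items():
            for fid in sorted(s & set(by_feature.index)):
                ratio_rows.append({"group": g, "feature_id": fid,
                                   **by_feature.loc[fid].to_dict()})
        ratio_values = pd.DataFrame(
            ratio_rows, columns=["group", "feature_id", *ratio_cols]
        )
        stat_rows = []
        enough = (
            not ratio_values.empty
            and ratio_values["group"].nunique() >= 2
            and design.reference_group in set(ratio_values["group"])
        )
        if enough:
            try:
                for res in compare_ratio_groups(
                    ratio_values, reference=design.reference_group, alpha=config.alpha
                ):
                    for _, row in res.pairwise.iterrows():
                        stat_rows.append(
                            {"ratio": res.target, "kw_h": res.kw_h, "kw_p": res.kw_p,
                             "group": row["group"], "p_value": row["p_value"],
                             "cohens_d": row["cohens_d"],
                             "cliffs_delta": row["cliffs_delta"],
                             "label": row["label"]}
                        )
            except ValueError:
                log.info("ratio stats skipped: insufficient defined ratios per group")
        emit(pd.DataFrame(stat_rows, columns=["ratio", "kw_h", "kw_p", "group",
                                              "p_value", "cohens_d", "cliffs_delta",
                                              "label"]),
             "ratio_stats.csv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("statistics", e) from e

    # ---- multivariate ---------------------------------------------------
    try:
        cols = [table.sample_index(s) for s in design.non_blank_samples]
        labels = [design.sample_groups[s] for s in design.non_blank_samples]
        X_proc, keep = preprocess_unknown(
            unknown.intensities[:, cols], config.iqr_drop_fraction, unknown.feature_ids
        )
        X = X_proc.T  # samples x features
        n_comp = min(config.pls_components, X.shape[0] - 1, X.shape[1])
        results = PLSDA(X, labels, n_components=n_comp).fit()
        r2, q2 = cross_validate(
            X, labels, k=config.cv_folds, n_components=n_comp,
            seed=config.stage_seed("cv"),
        )
        kept_ids = [fid for fid, k in zip(unknown.feature_ids, keep) if k]
        vip_df = pd.DataFrame({"feature_id": kept_ids, "vip": results.vip()})
        emit(vip_df.sort_values("vip", ascending=False), "vip.csv")
        emit(results.scores_frame(3), "plsda_scores.csv")
        emit(
            pd.DataFrame([{"n_components": n_comp, "r2": r2, "q2": q2,
                           "folds": config.cv_folds}]),
            "plsda_summary.csv",
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("multivariate", e) from e
    log.info("multivariate: R2=%.3f Q2=%.3f", r2, q2)

    config.save(out / "config_used.yaml")
    report.files.append("config_used.yaml")
    return report
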