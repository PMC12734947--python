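"""Pipeline configuration: a flat, validated, YAML-round-trippable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, with documented ranges.

    Paths may be None when a stage is driven from synthetic data.  The master
    ``seed`` feeds every stochastic stage through derived per-stage seeds.
    """

    # inputs / outputs
    feature_table: str | None = None
    design_table: str | None = None
    library_table: str | None = None
    output_dir: str = "soilstoich_out"
    # synthetic-data stage (used when feature_table is absent)
    n_synthetic_features: int = 60
    synthetic_mass_range: tuple[float, float] = (85.0, 500.0)
    ppm_sigma: float = 0.5
    noise_sigma: float = 0.35
    planted_fraction: float = 0.15
    planted_effect_log2: float = 2.0
    # QC
    blank_ratio: float = 3.0
    blank_statistic: str = "mean"
    is_cv_limit_percent: float = 30.0
    apply_blank_filter: bool = True
    # formula assignment
    ppm_low: float = 2.0
    ppm_high: float = 5.0
    isotope_score_min: float = 30.0
    top_k: int = 3
    # stoichiometry
    composite_mode: str = "average-counts"
    # preprocessing / statistics
    iqr_drop_fraction: float = 0.25
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    multiple_testing: str = "bh"
    # multivariate
    pls_components: int = 2
    cv_folds: int = 5
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.blank_ratio >= 0, "blank_ratio must be >= 0"),
            (self.blank_statistic in ("mean", "max"), "blank_statistic must be mean|max"),
            (0 < self.is_cv_limit_percent <= 100, "is_cv_limit_percent in (0, 100]"),
            (0 < self.ppm_low <= self.ppm_high, "need 0 < ppm_low <= ppm_high"),
            (0 <= self.isotope_score_min <= 100, "isotope_score_min in [0, 100]"),
            (1 <= self.top_k <= 3, "top_k in {1, 2, 3}"),
            (self.composite_mode in ("average-counts", "average-ratios"),
             "composite_mode must be average-counts|average-ratios"),
            (0 <= self.iqr_drop_fraction < 1, "iqr_drop_fraction in [0, 1)"),
            (0 < self.alpha <= 1 or self.alpha == 0, "alpha in [0, 1]"),
            (self.min_abs_log2fc >= 0, "min_abs_log2fc must be >= 0"),
            (self.multiple_testing in ("bh", "none"), "multiple_testing must be bh|none"),
            (self.pls_components >= 1, "pls_components must be >= 1"),
            (self.cv_folds >= 2, "cv_folds must be >= 2"),
            (self.n_synthetic_features >= 1, "n_synthetic_features must be >= 1"),
            (0 <= self.planted_fraction <= 1, "planted_fraction in [0, 1]"),
            (self.ppm_sigma >= 0 and self.noise_sigma >= 0, "sigmas must be >= 0"),
            (0 <= self.seed < 2**31, "seed must fit in a signed 32-bit integer"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")
        self.synthetic_mass_range = tuple(float(v) for v in self.synthetic_mass_range)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic_mass_range"] = list(self.synthetic_mass_range)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        import hashlib

        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)
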