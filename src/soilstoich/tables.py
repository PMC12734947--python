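"""In-memory containers: the LC-MS feature table and the study design."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class FeatureTable:
    """An LC-MS feature table: m/z, retention time and per-sample intensities.

    ``intensities`` is a (features x samples) non-negative matrix in arbitrary
    instrument units; rows align with ``feature_ids``/``mz``/``rt_min`` and
    columns with ``samples``.
    """

    feature_ids: list[str]
    mz: np.ndarray
    rt_min: np.ndarray
    samples: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt_min = np.asarray(self.rt_min, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        nf, ns = len(self.feature_ids), len(self.samples)
        if self.intensities.shape != (nf, ns):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{nf} features x {ns} samples"
            )
        if self.mz.shape != (nf,) or self.rt_min.shape != (nf,):
            raise ValueError("mz and rt_min must have one entry per feature")
        if len(set(self.feature_ids)) != nf:
            dupes = sorted({f for f in self.feature_ids if self.feature_ids.count(f) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")
        if len(set(self.samples)) != ns:
            raise ValueError("duplicate sample ids")
        if (self.mz <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.rt_min < 0).any():
            raise ValueError("retention times must be non-negative")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, keep: np.ndarray | list) -> "FeatureTable":
        """New table restricted to the given boolean mask or index list (order kept)."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return FeatureTable(
            feature_ids=[self.feature_ids[i] for i in idx],
            mz=self.mz[idx],
            rt_min=self.rt_min[idx],
            samples=list(self.samples),
            intensities=self.intensities[idx],
        )

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"feature_id": self.feature_ids, "mz": self.mz, "rt_min": self.rt_min}
        )
        for j, s in enumerate(self.samples):
            df[s] = self.intensities[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        required = ["feature_id", "mz", "rt_min"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        samples = [c for c in df.columns if c not in required]
        return cls(
            feature_ids=[str(f) for f in df["feature_id"]],
            mz=df["mz"].to_numpy(dtype=float),
            rt_min=df["rt_min"].to_numpy(dtype=float),
            samples=samples,
            intensities=df[samples].to_numpy(dtype=float),
        )


@dataclass
class StudyDesign:
    """Sample metadata: group labels, blank flags, masses, injection order.

    The reference group (pasture in the motivating study) anchors all pairwise
    comparisons.  Sample masses (mg) are only needed for mass normalisation;
    internal-standard feature ids only for the IS CV check.
    """

    sample_groups: dict[str, str]  # sample id -> group label
    blanks: set[str] = field(default_factory=set)
    reference_group: str | None = None
    sample_mass_mg: dict[str, float] = field(default_factory=dict)
    injection_order: dict[str, int] = field(default_factory=dict)
    internal_standard_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown_blanks = self.blanks - set(self.sample_groups)
        if unknown_blanks:
            raise ValueError(f"blank samples not in design: {sorted(unknown_blanks)}")
        if self.reference_group is not None:
            nonblank_groups = {
                g for s, g in self.sample_groups.items() if s not in self.blanks
            }
            if self.reference_group not in nonblank_groups:
                raise ValueError(
                    f"reference group {self.reference_group!r} has no non-blank samples"
                )
        for s, m in self.sample_mass_mg.items():
            if m <= 0:
                raise ValueError(f"sample {s!r}: mass must be positive")

    @property
    def non_blank_samples(self) -> list[str]:
        return [s for s in self.sample_groups if s not in self.blanks]

    @property
    def blank_samples(self) -> list[str]:
        return [s for s in self.sample_groups if s in self.blanks]

    def groups(self) -> list[str]:
        """Distinct non-blank group labels, reference first if set."""
        seen: list[str] = []
        for s in self.non_blank_samples:
            g = self.sample_groups[s]
            if g not in seen:
                seen.append(g)
        if self.reference_group in seen:
            seen.remove(self.reference_group)
            seen.insert(0, self.reference_group)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.non_blank_samples if self.sample_groups[s] == group]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, g in self.sample_groups.items():
            rows.append(
                {
                    "sample_id": s,
                    "group": g,
                    "is_blank": s in self.blanks,
                    "mass_mg": self.sample_mass_mg.get(s, np.nan),
                    "injection_order": self.injection_order.get(s, np.nan),
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["reference_group"] = self.reference_group
        df.attrs["internal_standard_ids"] = list(self.internal_standard_ids)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        reference_group: str | None = None,
        internal_standard_ids: list[str] | None = None,
    ) -> "StudyDesign":
        if "sample_id" not in df.columns or "group" not in df.columns:
            raise ValueError("design table needs 'sample_id' and 'group' columns")
        ids = [str(s) for s in df["sample_id"]]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design table")
        blanks = set()
        if "is_blank" in df.columns:
            blanks = {
                str(s)
                for s, b in zip(ids, df["is_blank"])
                if str(b).strip().lower() in ("true", "1", "yes")
            }
        masses = {}
        if "mass_mg" in df.columns:
            for s, m in zip(ids, pd.to_numeric(df["mass_mg"], errors="coerce")):
                if np.isfinite(m):
                    masses[str(s)] = float(m)
        order = {}
        if "injection_order" in df.columns:
            for s, v in zip(ids, pd.to_numeric(df["injection_order"], errors="coerce")):
                if np.isfinite(v):
                    order[str(s)] = int(v)
        return cls(
            sample_groups=dict(zip(ids, (str(g) for g in df["group"]))),
            blanks=blanks,
            reference_group=reference_group
            if reference_group is not None
            else df.attrs.get("reference_group"),
            sample_mass_mg=masses,
            injection_order=order,
            internal_standard_ids=internal_standard_ids
            if internal_standard_ids is not None
            else list(df.attrs.get("internal_standard_ids", [])),
        )
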