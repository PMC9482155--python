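"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package;
conversions to and from 1-based file dialects happen only at I/O
boundaries (see :mod:`uromark.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = frozenset({"case", "control_healthy", "control_other_cancer"})
VALID_STAGES = frozenset({"Ta", "T1", "T2", "T3", "T4", "CIS"})
VALID_GRADES = frozenset({"low", "high"})

#: Fixed columns of a cohort table; remaining columns are marker values.
COHORT_FIXED_COLUMNS = ["sample_id", "group", "stage", "grade", "age"]


class ValidationError(ValueError):
    """An input violates a structural invariant."""


@dataclass
class MethylationCalls:
    """Per-CpG methylated/unmethylated counts for one sample.

    ``records`` has columns ``chrom`` (str), ``pos`` (0-based cytosine
    coordinate), ``n_meth`` and ``n_unmeth`` (non-negative counts with
    coverage >= 1), sorted by (chrom, pos) with no duplicate positions.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = ["chrom", "pos", "n_meth", "n_unmeth"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"records missing columns {missing}")
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise ValidationError("negative methylation counts")
        cov = df["n_meth"] + df["n_unmeth"]
        if (cov < 1).any():
            raise ValidationError("records with zero coverage are not allowed")
        key = df[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (chrom, pos) records")
        if not df.equals(df.sort_values(["chrom", "pos"]).reset_index(drop=True)):
            raise ValidationError("records must be sorted by (chrom, pos)")

    @classmethod
    def from_records(
        cls, sample_id: str, records: Sequence[tuple[str, int, int, int]]
    ) -> "MethylationCalls":
        """Build from (chrom, pos, n_meth, n_unmeth) tuples; sorts and
        merges duplicate positions by summing counts."""
        df = pd.DataFrame(records, columns=["chrom", "pos", "n_meth", "n_unmeth"])
        df = (
            df.groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_unmeth"]]
            .sum()
            .reset_index(drop=True)
        )
        return cls(sample_id, df)

    @property
    def coverage(self) -> np.ndarray:
        return (self.records["n_meth"] + self.records["n_unmeth"]).to_numpy()

    @property
    def beta(self) -> np.ndarray:
        """Per-CpG methylation fraction n_meth / (n_meth + n_unmeth)."""
        return self.records["n_meth"].to_numpy() / self.coverage

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TssAnnotation:
    """Strand-resolved transcription start sites.

    ``entries`` has columns ``chrom``, ``tss_pos`` (0-based), ``strand``
    ('+'/'-') and ``gene_id``.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "tss_pos", "strand", "gene_id"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValidationError(f"TSS entries missing columns {missing}")
        bad = ~self.entries["strand"].isin(["+", "-"])
        if bad.any():
            raise ValidationError("TSS entries with undefined strand")

    def positions_for(self, chrom: str) -> np.ndarray:
        sel = self.entries.loc[self.entries["chrom"] == chrom, "tss_pos"]
        return np.sort(sel.to_numpy())


@dataclass
class CohortTable:
    """Patient cohort with group labels, optional stage/grade/age and
    per-marker methylation concentrations.

    ``rows`` carries the fixed columns ``sample_id``, ``group``,
    ``stage``, ``grade``, ``age`` followed by one column per marker.
    Missing values are NaN/None, never silent zeros.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in COHORT_FIXED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns {missing}")
        problems = []
        bad_group = ~df["group"].isin(VALID_GROUPS)
        for idx in df.index[bad_group]:
            problems.append(f"row {idx}: unknown group {df.at[idx, 'group']!r}")
        has_stage = df["stage"].notna()
        bad_stage = has_stage & ~df["stage"].isin(VALID_STAGES)
        for idx in df.index[bad_stage]:
            problems.append(f"row {idx}: unknown stage {df.at[idx, 'stage']!r}")
        has_grade = df["grade"].notna()
        bad_grade = has_grade & ~df["grade"].isin(VALID_GRADES)
        for idx in df.index[bad_grade]:
            problems.append(f"row {idx}: unknown grade {df.at[idx, 'grade']!r}")
        noncase = df["group"] != "case"
        for idx in df.index[noncase & (has_stage | has_grade)]:
            problems.append(f"row {idx}: stage/grade on non-case sample")
        for m in self.marker_names:
            neg = df[m].notna() & (df[m] < 0)
            for idx in df.index[neg]:
                problems.append(f"row {idx}: negative value for marker {m}")
        if problems:
            raise ValidationError("invalid cohort rows:\n" + "\n".join(problems))

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.rows.columns if c not in COHORT_FIXED_COLUMNS]

    @property
    def is_case(self) -> pd.Series:
        return (self.rows["group"] == "case").set_axis(self.rows["sample_id"])

    def marker_values(self) -> pd.DataFrame:
        """Marker concentration matrix indexed by sample_id."""
        return self.rows.set_index("sample_id")[self.marker_names]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class WindowStat:
    """One scanned genomic window with per-sample mean methylation."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    sample_betas: dict[str, float]
    target_group_mean: float
    offtarget_group_mean: float

    @property
    def delta(self) -> float:
        return self.target_group_mean - self.offtarget_group_mean


@dataclass
class DmrCandidate:
    """A merged differentially methylated region; one biomarker candidate."""

    chrom: str
    start: int
    end: int
    source_windows: list[WindowStat] = field(default_factory=list)
    tss_distance: Optional[int] = None
    distal: Optional[bool] = None


@dataclass
class MarkerThreshold:
    """A calibrated per-marker decision threshold.

    ``threshold`` is in the units of the input concentrations; a sample
    is positive for the marker when its value is strictly greater.
    """

    marker_id: str
    threshold: float
    calibration_sensitivity: float
    calibration_specificity: float
    auc: float
    auc_p_value: float


class Outcome(str, enum.Enum):
    NEGATIVE = "NEGATIVE"
    INCONCLUSIVE = "INCONCLUSIVE"
    POSITIVE = "POSITIVE"


@dataclass
class PanelRule:
    """Three-state scoring rule: 0 methylated markers is negative,
    >= ``positive_cutoff_k`` is positive, anything between inconclusive."""

    n_markers: int = 8
    positive_cutoff_k: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.positive_cutoff_k <= self.n_markers:
            raise ValidationError(
                f"positive_cutoff_k must be in [1, {self.n_markers}]"
            )


@dataclass
class PanelCall:
    """A patient's binary marker calls and three-state panel outcome.

    ``marker_calls`` entries are True/False or None for a missing
    marker measurement.
    """

    sample_id: str
    marker_calls: list[Optional[bool]]
    n_methylated: int
    outcome: Outcome
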