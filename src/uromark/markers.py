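"""Per-marker ROC analysis and decision-threshold calibration.

Thresholds are chosen as the methylation concentration giving the
highest possible sensitivity subject to specificity strictly greater
than a floor (0.95 by default), calibrated against healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .types import MarkerThreshold


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationConfig:
    """Threshold calibration settings.

    ``specificity_floor`` is a strict lower bound ("> 95%"); a sample is
    positive when its value is strictly greater than the threshold, so
    ties at the threshold are negative.
    """

    specificity_floor: float = 0.95
    control_groups_used: frozenset[str] = frozenset({"control_healthy"})

    def __post_init__(self) -> None:
        if not 0.0 < self.specificity_floor < 1.0:
            raise CalibrationError("specificity_floor must lie in (0, 1)")


def roc_auc(
    case_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, float]:
    """AUC as the normalized Mann-Whitney U statistic, with the
    two-sided rank-sum p-value for AUC = 0.5.

    Ties between a case and a control count 0.5.  Degenerate input
    where every value is identical returns (0.5, 1.0).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("need at least one value per group")
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        return 0.5, 1.0
    res = stats.mannwhitneyu(case, control, alternative="two-sided")
    auc = float(res.statistic) / (len(case) * len(control))
    return auc, float(res.pvalue)


def calibrate_threshold(
    case_values: Sequence[float],
    control_values: Sequence[float],
    config: CalibrationConfig | None = None,
    marker_id: str = "",
) -> MarkerThreshold:
    """Pick the threshold maximizing sensitivity among all thresholds
    with specificity strictly above the floor.

    Candidate thresholds are the midpoints between consecutive distinct
    pooled values plus one candidate below the minimum and one above the
    maximum.  Ties in sensitivity break toward higher specificity, then
    toward the higher threshold.
    """
    config = config or CalibrationConfig()
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise CalibrationError("need at least one value per group")

    distinct = np.unique(np.concatenate([case, control]))
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    # positive rule: value > threshold (strict)
    sens = (case[None, :] > candidates[:, None]).mean(axis=1)
    spec = (control[None, :] <= candidates[:, None]).mean(axis=1)
    feasible = spec > config.specificity_floor
    if not feasible.any():
        raise CalibrationError(
            f"marker {marker_id!r}: no threshold attains specificity > "
            f"{config.specificity_floor} with {len(control)} controls"
        )
    order = np.lexsort(
        (candidates[feasible], spec[feasible], sens[feasible])
    )
    best = np.flatnonzero(feasible)[order[-1]]
    auc, pval = roc_auc(case, control)
    return MarkerThreshold(
        marker_id=marker_id,
        threshold=float(candidates[best]),
        calibration_sensitivity=float(sens[best]),
        calibration_specificity=float(spec[best]),
        auc=auc,
        auc_p_value=pval,
    )


def tissue_selection_filter(
    markers: Sequence[MarkerThreshold],
    min_sensitivity: float = 0.5,
    alpha: float = 0.05,
) -> list[MarkerThreshold]:
    """Keep markers with sensitivity strictly above ``min_sensitivity``
    and a significant AUC (p < alpha); the tissue-stage shortlist rule."""
    return [
        m
        for m in markers
        if m.calibration_sensitivity > min_sensitivity and m.auc_p_value < alpha
    ]
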