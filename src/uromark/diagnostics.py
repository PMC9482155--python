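"""Diagnostic-accuracy evaluation of three-state panel results.

Sensitivity, specificity and exact (Clopper-Pearson) 95% confidence
intervals are computed over conclusive test results only; predictive
values come from the Bayes formula at an assumed disease prevalence
(20% for gross-hematuria patients by default), never from cohort
column totals; the spared-cystoscopy fraction is the rate of true
negatives among all tested patients, inconclusive patients counting as
requiring cystoscopy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .types import Outcome, PanelCall, ValidationError


@dataclass
class PrevalenceConfig:
    prevalence: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must lie in (0, 1)")


@dataclass
class DiagnosticSummary:
    """Confusion counts on conclusive patients plus derived accuracy."""

    n_total: int
    n_conclusive: int
    tp: int
    fp: int
    tn: int
    fn: int
    n_inconclusive_cases: int
    n_inconclusive_controls: int
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity: Optional[float]
    specificity_ci: Optional[tuple[float, float]]
    conclusive_rate: float
    spared_fraction: float
    ppv: Optional[float] = None
    npv: Optional[float] = None
    prevalence: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_conclusive": self.n_conclusive,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_inconclusive_cases": self.n_inconclusive_cases,
            "n_inconclusive_controls": self.n_inconclusive_controls,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci) if self.sensitivity_ci else None,
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci) if self.specificity_ci else None,
            "conclusive_rate": self.conclusive_rate,
            "spared_fraction": self.spared_fraction,
            "ppv": self.ppv,
            "npv": self.npv,
            "prevalence": self.prevalence,
        }
        return d


def _exact_ci(count: int, nobs: int) -> Optional[tuple[float, float]]:
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return float(lo), float(hi)


def summarize(
    calls: Sequence[PanelCall],
    labels: Mapping[str, bool] | pd.Series,
    prevalence: PrevalenceConfig | float | None = None,
) -> DiagnosticSummary:
    """Summarize panel calls against case/control labels.

    ``labels`` maps sample id to True for cases.  Inconclusive samples
    are excluded from the confusion counts; an empty conclusive group
    leaves the corresponding accuracy undefined (None), never zero.
    """
    labels = dict(pd.Series(labels).items())
    missing = [c.sample_id for c in calls if c.sample_id not in labels]
    if missing:
        raise ValidationError(f"unlabeled samples: {missing[:5]}")
    tp = fp = tn = fn = inc_case = inc_ctrl = 0
    for c in calls:
        case = bool(labels[c.sample_id])
        if c.outcome is Outcome.INCONCLUSIVE:
            if case:
                inc_case += 1
            else:
                inc_ctrl += 1
        elif c.outcome is Outcome.POSITIVE:
            if case:
                tp += 1
            else:
                fp += 1
        else:
            if case:
                fn += 1
            else:
                tn += 1
    n_total = len(calls)
    n_conclusive = tp + fp + tn + fn
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    summary = DiagnosticSummary(
        n_total=n_total,
        n_conclusive=n_conclusive,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_inconclusive_cases=inc_case,
        n_inconclusive_controls=inc_ctrl,
        sensitivity=sens,
        sensitivity_ci=_exact_ci(tp, tp + fn),
        specificity=spec,
        specificity_ci=_exact_ci(tn, tn + fp),
        conclusive_rate=n_conclusive / n_total if n_total else 0.0,
        spared_fraction=tn / n_total if n_total else 0.0,
    )
    if prevalence is not None and sens is not None and spec is not None:
        cfg = (
            prevalence
            if isinstance(prevalence, PrevalenceConfig)
            else PrevalenceConfig(prevalence)
        )
        ppv, npv = predictive_values(sens, spec, cfg)
        summary.ppv, summary.npv = ppv, npv
        summary.prevalence = cfg.prevalence
    return summary


def predictive_values(
    sensitivity: float,
    specificity: float,
    config: PrevalenceConfig | float = PrevalenceConfig(),
) -> tuple[Optional[float], Optional[float]]:
    """PPV and NPV from sensitivity, specificity and prevalence via the
    Bayes formula; an undefined value (zero denominator) is None."""
    cfg = config if isinstance(config, PrevalenceConfig) else PrevalenceConfig(config)
    pi = cfg.prevalence
    for v in (sensitivity, specificity):
        if not 0.0 <= v <= 1.0:
            raise ValidationError("sensitivity/specificity must lie in [0, 1]")
    ppv_den = sensitivity * pi + (1.0 - specificity) * (1.0 - pi)
    npv_den = specificity * (1.0 - pi) + (1.0 - sensitivity) * pi
    ppv = sensitivity * pi / ppv_den if ppv_den > 0 else None
    npv = specificity * (1.0 - pi) / npv_den if npv_den > 0 else None
    return ppv, npv


def stratified_sensitivity(
    calls: Sequence[PanelCall],
    labels: Mapping[str, bool] | pd.Series,
    strata: Mapping[str, Optional[str]] | pd.Series,
) -> pd.DataFrame:
    """Per-stratum (tumor stage or grade) sensitivity among conclusive
    cases.

    Cases with a missing stratum label are excluded and counted in the
    ``n_missing_stratum`` attribute of the returned frame.  Strata with
    no conclusive cases get NaN sensitivity.
    """
    labels = dict(pd.Series(labels).items())
    strata = dict(pd.Series(strata).items())
    per: dict[str, dict[str, int]] = {}
    n_missing = 0
    for c in calls:
        if not labels.get(c.sample_id, False):
            continue
        stratum = strata.get(c.sample_id)
        if stratum is None or (isinstance(stratum, float) and np.isnan(stratum)):
            n_missing += 1
            continue
        rec = per.setdefault(str(stratum), {"tp": 0, "fn": 0, "inconclusive": 0})
        if c.outcome is Outcome.POSITIVE:
            rec["tp"] += 1
        elif c.outcome is Outcome.NEGATIVE:
            rec["fn"] += 1
        else:
            rec["inconclusive"] += 1
    rows = []
    for stratum in sorted(per):
        rec = per[stratum]
        n_conc = rec["tp"] + rec["fn"]
        sens = rec["tp"] / n_conc if n_conc else np.nan
        ci = _exact_ci(rec["tp"], n_conc)
        rows.append(
            {
                "stratum": stratum,
                "n_conclusive": n_conc,
                "tp": rec["tp"],
                "fn": rec["fn"],
                "n_inconclusive": rec["inconclusive"],
                "sensitivity": sens,
                "ci_low": ci[0] if ci else np.nan,
                "ci_high": ci[1] if ci else np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "n_conclusive",
            "tp",
            "fn",
            "n_inconclusive",
            "sensitivity",
            "ci_low",
            "ci_high",
        ],
    )
    table.attrs["n_missing_stratum"] = n_missing
    return table


class AgeSplitResult(NamedTuple):
    split_age: float
    p_values: Optional[dict[str, float]]
    n_lower: int
    n_upper: int
    underpowered: bool


def age_split_test(
    case_marker_values: pd.DataFrame, ages: Sequence[float]
) -> AgeSplitResult:
    """Test each marker for age-dependent methylation among cases.

    Cases are split at the median age into two equally sized groups
    (median ties go to the lower group) and compared per marker with a
    two-sided Wilcoxon rank-sum test.  Fewer than 4 cases is flagged
    underpowered and no p-values are reported.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(case_marker_values):
        raise ValidationError("ages and marker rows must align")
    if len(ages) < 2:
        raise ValidationError("need >= 2 cases with ages")
    order = np.argsort(ages, kind="stable")
    n_lower = int(np.ceil(len(ages) / 2))
    lower_idx = order[:n_lower]
    upper_idx = order[n_lower:]
    split_age = float(np.median(ages))
    if len(ages) < 4:
        return AgeSplitResult(split_age, None, n_lower, len(ages) - n_lower, True)
    p_values = {}
    for marker in case_marker_values.columns:
        x = case_marker_values[marker].to_numpy(dtype=float)[lower_idx]
        y = case_marker_values[marker].to_numpy(dtype=float)[upper_idx]
        if np.all(np.concatenate([x, y]) == x[0]):
            p_values[marker] = 1.0
        else:
            p_values[marker] = float(stats.ranksums(x, y).pvalue)
    return AgeSplitResult(split_age, p_values, n_lower, len(ages) - n_lower, False)
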