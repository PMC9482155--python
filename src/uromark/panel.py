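"""Three-state panel scoring: binary marker calls, methylated-marker
counts, negative/inconclusive/positive classification and positivity
cutoff search."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CohortTable,
    MarkerThreshold,
    Outcome,
    PanelCall,
    PanelRule,
    ValidationError,
)


def call_markers(
    values: Mapping[str, float] | pd.Series,
    thresholds: Sequence[MarkerThreshold],
) -> list[Optional[bool]]:
    """Binary per-marker calls: value strictly greater than the marker's
    threshold.  A missing (NaN/None) value yields a missing call.
    Marker ids in ``values`` must cover every threshold."""
    if isinstance(values, pd.Series):
        values = values.to_dict()
    missing_ids = [t.marker_id for t in thresholds if t.marker_id not in values]
    if missing_ids:
        raise ValidationError(f"marker ids missing from values: {missing_ids}")
    calls: list[Optional[bool]] = []
    for t in thresholds:
        v = values[t.marker_id]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            calls.append(None)
        else:
            calls.append(bool(v > t.threshold))
    return calls


def classify(
    calls: Sequence[Optional[bool]],
    rule: PanelRule | None = None,
    sample_id: str = "",
) -> PanelCall:
    """Classify a sample from its marker calls.

    With complete calls: 0 methylated markers is NEGATIVE, >= k is
    POSITIVE, in between INCONCLUSIVE.  With missing calls the rule is
    conservative: POSITIVE only if the observed positives already reach
    k; NEGATIVE is never assigned (a fully negative test must be
    certain before sparing cystoscopy); otherwise INCONCLUSIVE.
    """
    rule = rule or PanelRule()
    if len(calls) != rule.n_markers:
        raise ValidationError(
            f"expected {rule.n_markers} marker calls, got {len(calls)}"
        )
    n_pos = sum(1 for c in calls if c is True)
    n_missing = sum(1 for c in calls if c is None)
    if n_pos >= rule.positive_cutoff_k:
        outcome = Outcome.POSITIVE
    elif n_missing > 0:
        outcome = Outcome.INCONCLUSIVE
    elif n_pos == 0:
        outcome = Outcome.NEGATIVE
    else:
        outcome = Outcome.INCONCLUSIVE
    return PanelCall(
        sample_id=sample_id,
        marker_calls=list(calls),
        n_methylated=n_pos,
        outcome=outcome,
    )


def score_cohort(
    cohort: CohortTable,
    thresholds: Sequence[MarkerThreshold],
    rule: PanelRule | None = None,
) -> list[PanelCall]:
    """Call markers and classify every sample of a cohort."""
    rule = rule or PanelRule(n_markers=len(thresholds))
    out = []
    values = cohort.marker_values()
    for sample_id, row in values.iterrows():
        calls = call_markers(row, thresholds)
        out.append(classify(calls, rule, sample_id=str(sample_id)))
    return out


def cutoff_search(
    marker_calls: pd.DataFrame,
    is_case: Mapping[str, bool] | pd.Series,
    k_range: Sequence[int] | None = None,
    utility=None,
) -> tuple[pd.DataFrame, Optional[int]]:
    """Evaluate every positivity cutoff k.

    ``marker_calls`` is a boolean DataFrame (samples x markers, no
    missing values) indexed by sample id.  For each k the inconclusive
    band is counts in [1, k-1]; sensitivity and specificity are
    computed over conclusive samples only.  Returns the full table and
    the recommended k maximizing ``utility(sens, spec, conclusive_rate)``
    (default: Youden's J times the conclusive rate); rows where a
    metric is undefined are NaN and never recommended.
    """
    n_markers = marker_calls.shape[1]
    k_range = list(k_range) if k_range is not None else list(range(1, n_markers + 1))
    if utility is None:
        utility = lambda sens, spec, crate: (sens + spec - 1.0) * crate
    is_case = pd.Series(is_case).reindex(marker_calls.index)
    if is_case.isna().any():
        raise ValidationError("every sample needs a case/control label")
    counts = marker_calls.sum(axis=1).to_numpy()
    case = is_case.to_numpy(dtype=bool)
    rows = []
    for k in k_range:
        positive = counts >= k
        conclusive = positive | (counts == 0)
        tp = int((positive & case & conclusive).sum())
        fn = int((~positive & case & conclusive).sum())
        tn = int((~positive & ~case & conclusive).sum())
        fp = int((positive & ~case & conclusive).sum())
        sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        crate = conclusive.mean()
        rows.append(
            {
                "k": k,
                "sensitivity": sens,
                "specificity": spec,
                "conclusive_rate": crate,
                "n_conclusive": int(conclusive.sum()),
            }
        )
    table = pd.DataFrame(rows)
    util = [
        utility(r["sensitivity"], r["specificity"], r["conclusive_rate"])
        if not (np.isnan(r["sensitivity"]) or np.isnan(r["specificity"]))
        else -np.inf
        for r in rows
    ]
    best = int(table["k"].iloc[int(np.argmax(util))]) if np.isfinite(max(util)) else None
    return table, best
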