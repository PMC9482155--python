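"""Shared builders for diagnostic-accuracy fixtures."""

from uromark.panel import classify
from uromark.types import PanelRule


def make_calls(n, n_positive_markers, prefix, n_markers=8):
    """Panel calls with a fixed methylated-marker count each (scored
    under the standard >=2 rule)."""
    calls = []
    for i in range(n):
        marker_calls = [j < n_positive_markers for j in range(n_markers)]
        calls.append(
            classify(marker_calls, PanelRule(n_markers, 2), sample_id=f"{prefix}_{i}")
        )
    return calls


def confusion_fixture(tp, fn, inc_cases, fp, tn, inc_controls):
    """Panel calls + labels encoding the given confusion counts:
    positives carry 2 methylated markers, negatives 0, inconclusives 1."""
    calls = []
    labels = {}
    spec = [
        ("tp", tp, True, 2),
        ("fn", fn, True, 0),
        ("ic", inc_cases, True, 1),
        ("fp", fp, False, 2),
        ("tn", tn, False, 0),
        ("io", inc_controls, False, 1),
    ]
    for tag, n, is_case, k in spec:
        for c in make_calls(n, k, tag):
            calls.append(c)
            labels[c.sample_id] = is_case
    return calls, labels
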