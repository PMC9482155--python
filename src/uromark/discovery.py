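"""Sliding-window discovery of differentially methylated regions.

Methylation call tables are scanned with tiling windows at two scales
(200 bp and 1000 bp by default); windows hypermethylated in the target
group and unmethylated in the off-target group are retained, and
overlapping windows across both scales are merged into biomarker
candidates annotated with distance to the nearest TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .types import DmrCandidate, MethylationCalls, TssAnnotation, WindowStat


class ConfigurationError(ValueError):
    pass


@dataclass
class WindowConfig:
    """Window scan and filter parameters.

    A window is emitted only when every sample contributes at least
    ``min_cpgs_per_window`` CpGs with coverage >= ``min_coverage_per_cpg``.
    The filter keeps windows where at least ``min_target_fraction`` of
    target samples have window beta >= ``min_target_beta`` and at most
    ``max_offtarget_fraction`` of off-target samples exceed
    ``max_offtarget_beta``.
    """

    window_sizes: Sequence[int] = (200, 1000)
    steps: Mapping[int, int] | None = None  # default: step == window size
    min_cpgs_per_window: int = 4
    min_coverage_per_cpg: int = 10
    min_target_beta: float = 0.4
    max_offtarget_beta: float = 0.1
    min_target_fraction: float = 0.75
    max_offtarget_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.window_sizes):
            raise ConfigurationError("window sizes must be positive")
        for t in (
            self.min_target_beta,
            self.max_offtarget_beta,
            self.min_target_fraction,
            self.max_offtarget_fraction,
        ):
            if not 0.0 <= t <= 1.0:
                raise ConfigurationError("thresholds must lie in [0, 1]")

    def step_for(self, window_size: int) -> int:
        if self.steps and window_size in self.steps:
            return int(self.steps[window_size])
        return window_size


def scan_windows(
    samples: Sequence[MethylationCalls],
    groups: Mapping[str, str],
    config: WindowConfig | None = None,
) -> list[WindowStat]:
    """Tile every chromosome with windows at each configured scale and
    compute per-sample and per-group mean methylation.

    The per-sample window beta is the unweighted mean of per-CpG betas
    (coverage-filtered), so high-coverage CpGs do not dominate; group
    means are unweighted means over samples.
    """
    config = config or WindowConfig()
    for s in samples:
        if s.sample_id not in groups:
            raise ConfigurationError(f"sample {s.sample_id!r} missing from groups map")
    labels = {groups[s.sample_id] for s in samples}
    bad = labels - {"target", "offtarget"}
    if bad:
        raise ConfigurationError(f"unknown group labels {sorted(bad)}")
    target_ids = [s.sample_id for s in samples if groups[s.sample_id] == "target"]
    offtarget_ids = [s.sample_id for s in samples if groups[s.sample_id] == "offtarget"]
    if not target_ids or not offtarget_ids:
        raise ConfigurationError("both target and offtarget groups need >= 1 sample")

    # per-sample, per-chromosome coverage-filtered positions and beta cumsums
    chroms: set[str] = set()
    per_sample: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for s in samples:
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        keep = s.coverage >= config.min_coverage_per_cpg
        df = s.records.loc[keep]
        betas = s.beta[keep]
        for chrom, idx in df.groupby("chrom", sort=True).indices.items():
            pos = df["pos"].to_numpy()[idx]
            by_chrom[str(chrom)] = (pos, betas[idx])
            chroms.add(str(chrom))
        per_sample[s.sample_id] = by_chrom

    sample_ids = [s.sample_id for s in samples]
    out: list[WindowStat] = []
    for chrom in sorted(chroms):
        max_pos = max(
            (d[chrom][0][-1] for d in per_sample.values() if chrom in d and len(d[chrom][0])),
            default=-1,
        )
        if max_pos < 0:
            continue
        for w in config.window_sizes:
            step = config.step_for(w)
            starts = np.arange(0, max_pos + 1, step, dtype=np.int64)
            counts = np.empty((len(sample_ids), len(starts)), dtype=np.int64)
            sums = np.empty((len(sample_ids), len(starts)))
            for i, sid in enumerate(sample_ids):
                pos, beta = per_sample[sid].get(chrom, (np.array([], dtype=np.int64), np.array([])))
                cb = np.concatenate([[0.0], np.cumsum(beta)])
                lo = np.searchsorted(pos, starts, side="left")
                hi = np.searchsorted(pos, starts + w, side="left")
                counts[i] = hi - lo
                sums[i] = cb[hi] - cb[lo]
            ok = (counts >= config.min_cpgs_per_window).all(axis=0)
            for j in np.flatnonzero(ok):
                betas_j = sums[:, j] / counts[:, j]
                sample_betas = dict(zip(sample_ids, betas_j.tolist()))
                tmean = float(np.mean([sample_betas[sid] for sid in target_ids]))
                omean = float(np.mean([sample_betas[sid] for sid in offtarget_ids]))
                out.append(
                    WindowStat(
                        chrom=chrom,
                        start=int(starts[j]),
                        end=int(starts[j] + w),
                        n_cpgs=int(counts[:, j].min()),
                        sample_betas=sample_betas,
                        target_group_mean=tmean,
                        offtarget_group_mean=omean,
                    )
                )
    return out


def filter_windows(
    windows: Sequence[WindowStat],
    groups: Mapping[str, str],
    config: WindowConfig | None = None,
) -> list[WindowStat]:
    """Keep windows methylated in the target group and unmethylated in
    the off-target group, per the configured fractions."""
    config = config or WindowConfig()
    kept = []
    for win in windows:
        t_betas = [b for sid, b in win.sample_betas.items() if groups[sid] == "target"]
        o_betas = [b for sid, b in win.sample_betas.items() if groups[sid] == "offtarget"]
        frac_t = np.mean([b >= config.min_target_beta for b in t_betas])
        frac_o = np.mean([b > config.max_offtarget_beta for b in o_betas])
        if frac_t >= config.min_target_fraction and frac_o <= config.max_offtarget_fraction:
            kept.append(win)
    return kept


def merge_candidates(windows: Sequence[WindowStat]) -> list[DmrCandidate]:
    """Merge overlapping windows (>= 1 bp, same chromosome, across all
    scales) into single candidates; abutting half-open intervals do not
    merge.  Output is sorted by (chrom, start) and idempotent under
    input shuffling."""
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start, w.end))
    out: list[DmrCandidate] = []
    for win in ordered:
        if out and out[-1].chrom == win.chrom and win.start < out[-1].end:
            cur = out[-1]
            cur.end = max(cur.end, win.end)
            cur.source_windows.append(win)
        else:
            out.append(
                DmrCandidate(
                    chrom=win.chrom,
                    start=win.start,
                    end=win.end,
                    source_windows=[win],
                )
            )
    return out


def annotate_tss(
    candidates: Sequence[DmrCandidate],
    tss: TssAnnotation,
    distal_cutoff: int = 1500,
) -> list[DmrCandidate]:
    """Annotate each candidate with the distance to the nearest TSS.

    Distance is 0 when a TSS falls inside the half-open interval,
    otherwise the gap to the nearest interval edge; a candidate is
    distal when the distance is strictly greater than ``distal_cutoff``
    (1500 bp by default).  Candidates on chromosomes absent from the
    annotation get a missing distance and undefined distal flag.
    """
    out = []
    for c in candidates:
        positions = tss.positions_for(c.chrom)
        if len(positions) == 0:
            out.append(
                DmrCandidate(c.chrom, c.start, c.end, list(c.source_windows), None, None)
            )
            continue
        inside = (positions >= c.start) & (positions < c.end)
        if inside.any():
            dist = 0
        else:
            left = positions[positions < c.start]
            right = positions[positions >= c.end]
            gaps = []
            if len(left):
                gaps.append(c.start - left.max())
            if len(right):
                gaps.append(right.min() - c.end)
            dist = int(min(gaps))
        out.append(
            DmrCandidate(
                c.chrom,
                c.start,
                c.end,
                list(c.source_windows),
                int(dist),
                bool(dist > distal_cutoff),
            )
        )
    return out


class QcSummary(NamedTuple):
    mean_coverage: float
    mean_beta: float
    n_cpgs: int


def sample_qc_summary(sample: MethylationCalls) -> QcSummary:
    """Mean coverage, unweighted mean per-CpG beta and CpG count."""
    if len(sample) == 0:
        raise ValueError(f"sample {sample.sample_id!r} has no records")
    return QcSummary(
        mean_coverage=float(sample.coverage.mean()),
        mean_beta=float(sample.beta.mean()),
        n_cpgs=len(sample),
    )
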