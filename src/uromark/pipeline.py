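"""End-to-end seeded pipeline: simulate -> discover -> calibrate ->
score -> evaluate, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as uio
from .diagnostics import PrevalenceConfig, summarize
from .discovery import (
    WindowConfig,
    annotate_tss,
    filter_windows,
    merge_candidates,
    scan_windows,
)
from .markers import CalibrationConfig, calibrate_threshold
from .panel import PanelRule, cutoff_search, score_cohort
from .simulate import (
    RrbsSimConfig,
    UrineSimConfig,
    default_rrbs_config,
    discovery_preset,
    hematuria_preset,
    simulate_rrbs,
    simulate_tss,
    simulate_urine_cohort,
)
from .types import MarkerThreshold

log = logging.getLogger("uromark")


@dataclass
class PipelineConfig:
    """One declarative config for a full seeded run."""

    seed: int = 0
    output_dir: str = "uromark_run"
    rrbs: RrbsSimConfig = field(default_factory=RrbsSimConfig)
    n_planted_dmrs: int = 6
    discovery_cohort: Optional[UrineSimConfig] = None
    hematuria_cohort: Optional[UrineSimConfig] = None
    windows: WindowConfig = field(default_factory=WindowConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    panel_rule: PanelRule = field(default_factory=PanelRule)
    prevalence: PrevalenceConfig = field(default_factory=PrevalenceConfig)
    log_level: str = "INFO"

    def resolved(self) -> "PipelineConfig":
        """Fill seed-derived stage configs; called once at run start."""
        cfg = dataclasses.replace(self)
        if not cfg.rrbs.planted_dmrs:
            cfg.rrbs = default_rrbs_config(
                seed=cfg.seed, n_dmrs=cfg.n_planted_dmrs,
                **{f.name: getattr(cfg.rrbs, f.name)
                   for f in dataclasses.fields(RrbsSimConfig)
                   if f.name not in ("planted_dmrs", "seed")},
            )
        else:
            cfg.rrbs = dataclasses.replace(cfg.rrbs, seed=cfg.seed)
        if cfg.discovery_cohort is None:
            cfg.discovery_cohort = discovery_preset(seed=cfg.seed + 1)
        if cfg.hematuria_cohort is None:
            cfg.hematuria_cohort = hematuria_preset(seed=cfg.seed + 2)
        return cfg

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    def config_hash(self) -> str:
        """Hash of the scientific parameters; output location and log
        level do not affect it."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        canonical = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _as_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all artifacts under ``config.output_dir``
    and return the manifest (also written as manifest.json)."""
    config = config.resolved()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    logging.basicConfig(level=config.log_level)
    manifest: dict = {"seed": config.seed, "config_hash": cfg_hash, "stages": {}, "files": {}}

    # --- stage 1: cell-line methylomes + DMR discovery
    log.info("simulating %d cell-line methylomes", config.rrbs.n_target_lines + config.rrbs.n_offtarget_lines)
    samples, truth_dmrs = simulate_rrbs(config.rrbs)
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    groups = {}
    for s in samples:
        uio.write_coverage_file(s, covdir / f"{s.sample_id}.cov")
        groups[s.sample_id] = s.sample_id.rsplit("_", 1)[0]
    pd.Series(groups, name="group").rename_axis("sample_id").to_csv(
        outdir / "groups.tsv", sep="\t"
    )
    (outdir / "planted_dmrs.json").write_text(
        json.dumps([dataclasses.asdict(d) for d in truth_dmrs], indent=2)
    )
    genome_span = int(config.rrbs.n_cpgs * config.rrbs.mean_gap)
    tss = simulate_tss(genome_span=genome_span, chrom=config.rrbs.chrom, seed=config.seed + 3)

    windows = scan_windows(samples, groups, config.windows)
    kept = filter_windows(windows, groups, config.windows)
    candidates = annotate_tss(merge_candidates(kept), tss)
    uio.write_candidates_bed(candidates, outdir / "candidates.bed")
    manifest["stages"]["discovery"] = {
        "n_samples": len(samples),
        "n_windows_scanned": len(windows),
        "n_windows_kept": len(kept),
        "n_candidates": len(candidates),
        "n_planted": len(truth_dmrs),
    }

    # --- stage 2: discovery urine cohort + threshold calibration
    disc_cohort, disc_truth = simulate_urine_cohort(config.discovery_cohort)
    uio.write_cohort(disc_cohort, outdir / "cohort_discovery.tsv")
    thresholds = calibrate_panel(disc_cohort, config.calibration)
    (outdir / "thresholds.json").write_text(
        json.dumps([dataclasses.asdict(t) for t in thresholds], indent=2)
    )

    values = disc_cohort.marker_values()
    marker_calls = pd.DataFrame(
        {t.marker_id: values[t.marker_id] > t.threshold for t in thresholds}
    )
    table, best_k = cutoff_search(marker_calls, disc_cohort.is_case)
    table.to_csv(outdir / "cutoff_search.tsv", sep="\t", index=False)
    manifest["stages"]["calibration"] = {
        "n_markers": len(thresholds),
        "recommended_k": best_k,
    }

    # --- stage 3: score and evaluate both cohorts
    reports = {}
    for name, cohort in (
        ("discovery", disc_cohort),
        ("hematuria", simulate_urine_cohort(config.hematuria_cohort)[0]),
    ):
        calls = score_cohort(cohort, thresholds, config.panel_rule)
        summary = summarize(calls, cohort.is_case, config.prevalence)
        report = {"config_hash": cfg_hash, "cohort": name, **summary.to_dict()}
        uio.write_report(report, outdir / f"report_{name}.json")
        reports[name] = report
        manifest["stages"][f"evaluate_{name}"] = {
            "n_samples": summary.n_total,
            "n_conclusive": summary.n_conclusive,
        }

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["reports"] = reports
    return manifest


def calibrate_panel(
    cohort, config: CalibrationConfig | None = None
) -> list[MarkerThreshold]:
    """Calibrate one threshold per marker on a cohort, cases versus the
    configured calibration control groups (healthy controls only by
    default)."""
    config = config or CalibrationConfig()
    controls = cohort.rows["group"].isin(config.control_groups_used)
    cases = cohort.rows["group"] == "case"
    out = []
    for m in cohort.marker_names:
        out.append(
            calibrate_threshold(
                cohort.rows.loc[cases, m].dropna(),
                cohort.rows.loc[controls, m].dropna(),
                config,
                marker_id=m,
            )
        )
    return out
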