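"""Seeded synthetic data with the statistical structure the pipeline
assumes.

Two generators are provided.  ``simulate_rrbs`` emulates a panel of
urological cancer cell-line methylomes (8 target-cancer and 8
off-target-cancer lines by default) as per-CpG count tables with
beta-binomial noise, negative-binomial coverage and planted
ground-truth DMRs.  ``simulate_urine_cohort`` emulates urine ddPCR
marker concentrations for patient cohorts: each case carries a latent
log-normal tumor-shedding factor that scales the positivity odds of
all markers jointly, which is what makes an 8-marker panel far more
sensitive than any single marker while keeping per-marker marginal
sensitivities at their configured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import CohortTable, MethylationCalls, TssAnnotation

DEFAULT_MARKERS = ("m1", "m2", "m3", "m4", "m5", "m6", "m7", "m8")

#: Healthy-control marker operating points (sensitivity 54-73%,
#: specificity 95-96%) matching the urine discovery-series behaviour.
DEFAULT_SENSITIVITIES = (0.54, 0.58, 0.62, 0.65, 0.68, 0.70, 0.72, 0.73)
DEFAULT_SPECIFICITIES = (0.95, 0.955, 0.96, 0.95, 0.955, 0.96, 0.95, 0.96)


class SimConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# RRBS cell-line simulation


@dataclass(frozen=True)
class PlantedDmr:
    """A ground-truth differentially methylated region."""

    chrom: str
    start: int
    span: int
    n_cpgs: int
    target_beta: float
    offtarget_beta: float

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class RrbsSimConfig:
    """Cell-line methylome simulation parameters.

    Coverage follows a negative binomial with the study-scale mean of
    111.6x; background per-CpG methylation is a two-mode Beta mixture
    whose mean matches the observed genome-wide 37.2%.  ``n_cpgs`` is a
    desk-scale default; real RRBS profiles are orders of magnitude
    larger but statistically equivalent per window.
    """

    n_target_lines: int = 8
    n_offtarget_lines: int = 8
    n_cpgs: int = 20_000
    chrom: str = "chr1"
    mean_gap: float = 150.0
    clustering: float = 0.6  # fraction of gaps drawn from the short (CpG-island) mode
    short_gap_mean: float = 20.0
    coverage_mean: float = 111.6
    coverage_dispersion: float = 5.0
    beta_low: tuple[float, float] = (1.5, 15.0)  # Beta params, unmethylated mode
    beta_high: tuple[float, float] = (12.0, 3.0)  # Beta params, methylated mode
    high_mode_weight: float = 0.4
    bb_precision: float = 30.0  # beta-binomial concentration for sample noise
    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        regions = sorted(self.planted_dmrs, key=lambda r: (r.chrom, r.start))
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise SimConfigError(
                    f"planted regions overlap: {a.start}-{a.end} and {b.start}-{b.end}"
                )
        for r in regions:
            if not (0.0 <= r.target_beta <= 1.0 and 0.0 <= r.offtarget_beta <= 1.0):
                raise SimConfigError("planted betas must lie in [0, 1]")


def default_planted_dmrs(
    n_dmrs: int = 6,
    genome_span: int | None = None,
    config: RrbsSimConfig | None = None,
    target_beta: float = 0.85,
    offtarget_beta: float = 0.03,
) -> list[PlantedDmr]:
    """Evenly spaced planted regions (600-1000 bp, one CpG per ~40 bp)
    across the expected genome span of ``config``."""
    cfg = config or RrbsSimConfig()
    if genome_span is None:
        genome_span = int(cfg.n_cpgs * cfg.mean_gap)
    spans = [600 + 100 * (i % 5) for i in range(n_dmrs)]
    out = []
    for i, span in enumerate(spans):
        start = int(genome_span * (i + 1) / (n_dmrs + 1))
        out.append(
            PlantedDmr(
                chrom=cfg.chrom,
                start=start,
                span=span,
                n_cpgs=span // 40,
                target_beta=target_beta,
                offtarget_beta=offtarget_beta,
            )
        )
    return out


def default_rrbs_config(seed: int = 0, n_dmrs: int = 6, **overrides) -> RrbsSimConfig:
    cfg = RrbsSimConfig(seed=seed, **overrides)
    return replace(cfg, planted_dmrs=default_planted_dmrs(n_dmrs=n_dmrs, config=cfg))


def _draw_gaps(rng: np.random.Generator, cfg: RrbsSimConfig, n: int) -> np.ndarray:
    short = cfg.clustering
    long_mean = max(
        2.0, (cfg.mean_gap - short * cfg.short_gap_mean) / max(1e-9, 1.0 - short)
    )
    is_short = rng.random(n) < short
    gaps = np.where(
        is_short,
        rng.exponential(cfg.short_gap_mean, n),
        rng.exponential(long_mean, n),
    )
    return np.maximum(2, gaps.astype(np.int64))


def simulate_rrbs(
    config: RrbsSimConfig,
) -> tuple[list[MethylationCalls], list[PlantedDmr]]:
    """Simulate one methylation call table per cell line plus the
    planted ground truth.  The seed fully determines the output."""
    rng = np.random.default_rng(config.seed)

    positions = 1000 + np.cumsum(_draw_gaps(rng, config, config.n_cpgs))
    # carve out planted regions from the background and lay down their CpGs
    keep = np.ones(len(positions), dtype=bool)
    planted_pos: list[np.ndarray] = []
    for region in config.planted_dmrs:
        keep &= (positions < region.start) | (positions >= region.end)
        planted_pos.append(
            np.linspace(
                region.start + 5, region.end - 5, region.n_cpgs, dtype=np.int64
            )
        )
    background = positions[keep]

    n_bg = len(background)
    is_high = rng.random(n_bg) < config.high_mode_weight
    bg_beta = np.where(
        is_high,
        rng.beta(*config.beta_high, n_bg),
        rng.beta(*config.beta_low, n_bg),
    )

    all_pos = [background]
    target_beta = [bg_beta]
    offtarget_beta = [bg_beta]
    for region, ppos in zip(config.planted_dmrs, planted_pos):
        all_pos.append(ppos)
        target_beta.append(np.full(len(ppos), region.target_beta))
        offtarget_beta.append(np.full(len(ppos), region.offtarget_beta))
    pos = np.concatenate(all_pos)
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    beta_by_group = {
        "target": np.concatenate(target_beta)[order],
        "offtarget": np.concatenate(offtarget_beta)[order],
    }
    # de-duplicate any collisions between background and planted grids
    uniq = np.concatenate([[True], np.diff(pos) > 0])
    pos = pos[uniq]
    beta_by_group = {g: b[uniq] for g, b in beta_by_group.items()}

    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    samples: list[MethylationCalls] = []
    groups = [("target", config.n_target_lines), ("offtarget", config.n_offtarget_lines)]
    for group, n_lines in groups:
        beta = np.clip(beta_by_group[group], 1e-9, 1.0 - 1e-9)
        a = beta * config.bb_precision
        b = (1.0 - beta) * config.bb_precision
        for i in range(n_lines):
            cov = rng.negative_binomial(config.coverage_dispersion, p_nb, len(pos))
            p = rng.beta(a, b)
            n_meth = rng.binomial(cov, p)
            ok = cov >= 1
            df = pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "pos": pos[ok],
                    "n_meth": n_meth[ok],
                    "n_unmeth": (cov - n_meth)[ok],
                }
            )
            samples.append(MethylationCalls(f"{group}_{i + 1:02d}", df))
    return samples, list(config.planted_dmrs)


def simulate_tss(
    n_genes: int = 200,
    genome_span: int = 3_000_000,
    chrom: str = "chr1",
    seed: int = 0,
) -> TssAnnotation:
    """Random strand-resolved TSS annotation for a synthetic genome."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.integers(0, genome_span, n_genes))
    strand = rng.choice(["+", "-"], n_genes)
    entries = pd.DataFrame(
        {
            "chrom": chrom,
            "tss_pos": pos,
            "strand": strand,
            "gene_id": [f"gene_{i + 1:04d}" for i in range(n_genes)],
        }
    )
    return TssAnnotation(entries)


# ---------------------------------------------------------------------------
# Urine cohort simulation

_GH_NODES, _GH_WEIGHTS = hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _shedding_intercept(sensitivity: float, sigma: float) -> float:
    """Intercept b such that E_z[sigmoid(b + sigma z)] equals the target
    marginal sensitivity, z standard normal (Gauss-Hermite quadrature)."""
    if sensitivity >= 1.0:
        return math.inf
    if sigma == 0.0:
        return float(logit(sensitivity))
    f = lambda b: float((_GH_WEIGHTS * expit(b + sigma * _GH_NODES)).sum()) - sensitivity
    return brentq(f, -40.0, 40.0)


@dataclass
class UrineSimConfig:
    """Urine cohort simulation parameters.

    Marker generation is a two-part model: a positivity draw (the
    latent shedding factor scales all within-case marker odds jointly;
    control false positives are independent assay noise) followed by a
    concentration draw (log-normal for positive markers, zero-inflated
    trace background for negative ones).  Concentrations are in
    methylated copies per reaction, arbitrary but consistent units.
    """

    n_cases: int = 93
    n_controls_healthy: int = 180
    n_controls_other: int = 0
    prevalence_target: float = 0.20
    marker_names: Sequence[str] = DEFAULT_MARKERS
    per_marker_sensitivity: Sequence[float] = DEFAULT_SENSITIVITIES
    per_marker_specificity: Sequence[float] = DEFAULT_SPECIFICITIES
    shedding_sigma: float = 2.0  # sd of the latent shedding factor, logit scale
    stage_shedding_delta: float = 0.0  # optional stage-rank shift of shedding
    other_cancer_fp_odds: float = 1.5  # FP odds multiplier for other-cancer controls
    conc_pos_mu: float = math.log(300.0)
    conc_pos_sigma: float = 0.8
    conc_shed_coef: float = 0.8  # concentration boost per shedding sd
    conc_fp_mu: float = math.log(15.0)
    conc_fp_sigma: float = 0.8
    background_zero_prob: float = 0.7
    conc_bg_mu: float = math.log(1.5)
    conc_bg_sigma: float = 0.7
    stage_distribution: Optional[dict[str, float]] = None
    grade_distribution: Optional[dict[Optional[str], float]] = None
    age_mean: float = 69.0
    age_sd: float = 10.0
    age_range: tuple[int, int] = (40, 95)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.marker_names)
        if len(self.per_marker_sensitivity) != k or len(self.per_marker_specificity) != k:
            raise SimConfigError("per-marker rates must match marker_names length")
        for v in list(self.per_marker_sensitivity) + list(self.per_marker_specificity):
            if not 0.0 < v <= 1.0:
                raise SimConfigError(
                    f"marker sensitivities/specificities must lie in (0, 1]; got {v}"
                )
        if self.shedding_sigma < 0:
            raise SimConfigError("shedding_sigma must be >= 0")


_STAGE_RANK = {"Ta": 0, "CIS": 0, "T1": 1, "T2": 2, "T3": 3, "T4": 4}


def discovery_preset(seed: int = 0) -> UrineSimConfig:
    """Urine discovery series composition: 26 bladder cancers, 56
    healthy controls, 30 other urological cancers (n = 112)."""
    return UrineSimConfig(
        n_cases=26,
        n_controls_healthy=56,
        n_controls_other=30,
        stage_distribution={"Ta": 12 / 26, "T2": 4 / 26, "T3": 4 / 26, "T4": 1 / 26, "CIS": 5 / 26},
        grade_distribution={"low": 8 / 26, "high": 18 / 26},
        age_mean=75.0,
        age_range=(49, 93),
        seed=seed,
    )


def hematuria_preset(seed: int = 0) -> UrineSimConfig:
    """Gross-hematuria series composition: 273 patients, 93 with a
    confirmed bladder tumor (case fraction 34.1%); assumed clinical
    prevalence for predictive values is 20%."""
    return UrineSimConfig(
        n_cases=93,
        n_controls_healthy=180,
        n_controls_other=0,
        prevalence_target=0.20,
        stage_distribution={
            "Ta": 43 / 93,
            "T1": 31 / 93,
            "T2": 9 / 93,
            "T3": 1 / 93,
            "T4": 2 / 93,
            "CIS": 7 / 93,
        },
        grade_distribution={"low": 29 / 93, "high": 61 / 93, None: 3 / 93},
        age_mean=69.0,
        age_range=(48, 91),
        seed=seed,
    )


def simulate_urine_cohort(
    config: UrineSimConfig,
) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a urine cohort table plus the per-patient latent truth.

    Returns (cohort, truth); ``truth`` has one row per sample with the
    shedding factor (cases only) and the true per-marker states.
    """
    rng = np.random.default_rng(config.seed)
    markers = list(config.marker_names)
    k = len(markers)
    sens = np.asarray(config.per_marker_sensitivity, dtype=float)
    spec = np.asarray(config.per_marker_specificity, dtype=float)
    intercepts = np.array(
        [_shedding_intercept(s, config.shedding_sigma) for s in sens]
    )

    stage_dist = config.stage_distribution or {"Ta": 0.45, "T1": 0.3, "T2": 0.1, "T3": 0.02, "T4": 0.03, "CIS": 0.1}
    grade_dist = config.grade_distribution or {"low": 0.32, "high": 0.68}

    rows = []
    truth_rows = []

    def _age() -> int:
        a = rng.normal(config.age_mean, config.age_sd)
        return int(np.clip(round(a), *config.age_range))

    def _concentrations(states: np.ndarray, z: float, is_case: bool) -> np.ndarray:
        conc = np.zeros(k)
        for j in range(k):
            if states[j]:
                if is_case:
                    mu = config.conc_pos_mu + config.conc_shed_coef * z
                    conc[j] = math.exp(rng.normal(mu, config.conc_pos_sigma))
                else:
                    conc[j] = math.exp(rng.normal(config.conc_fp_mu, config.conc_fp_sigma))
            elif rng.random() >= config.background_zero_prob:
                conc[j] = math.exp(rng.normal(config.conc_bg_mu, config.conc_bg_sigma))
        return np.round(conc, 3)

    stage_labels = list(stage_dist)
    stage_p = np.asarray(list(stage_dist.values()), dtype=float)
    stage_p = stage_p / stage_p.sum()
    grade_labels = list(grade_dist)
    grade_p = np.asarray(list(grade_dist.values()), dtype=float)
    grade_p = grade_p / grade_p.sum()

    for i in range(config.n_cases):
        stage = stage_labels[rng.choice(len(stage_labels), p=stage_p)]
        grade = grade_labels[rng.choice(len(grade_labels), p=grade_p)]
        z = rng.normal()
        if config.stage_shedding_delta:
            z = z + config.stage_shedding_delta * _STAGE_RANK.get(stage, 0)
        with np.errstate(over="ignore"):
            p_pos = expit(intercepts + config.shedding_sigma * z)
        states = rng.random(k) < p_pos
        conc = _concentrations(states, z, is_case=True)
        sid = f"case_{i + 1:03d}"
        rows.append([sid, "case", stage, grade, _age(), *conc])
        truth_rows.append([sid, True, z, *states])

    control_specs = [
        ("healthy", "control_healthy", config.n_controls_healthy, 1.0),
        ("other", "control_other_cancer", config.n_controls_other, config.other_cancer_fp_odds),
    ]
    for prefix, group, n, odds_mult in control_specs:
        fp_odds = (1.0 - spec) / spec * odds_mult
        fp_prob = fp_odds / (1.0 + fp_odds)
        for i in range(n):
            states = rng.random(k) < fp_prob
            conc = _concentrations(states, 0.0, is_case=False)
            sid = f"{prefix}_{i + 1:03d}"
            rows.append([sid, group, None, None, _age(), *conc])
            truth_rows.append([sid, False, np.nan, *states])

    cohort = CohortTable(
        pd.DataFrame(
            rows, columns=["sample_id", "group", "stage", "grade", "age", *markers]
        )
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "is_case", "shedding", *[f"true_{m}" for m in markers]],
    )
    return cohort, truth
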