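"""End-to-end orchestration: discovery -> training -> scoring -> evaluation.

The stages mirror how the method is applied to a real cohort:

1. per-sample region statistics over the candidate panel;
2. read-proportion DMR calling in two contrasts (tumor vs adjacent
   normal, tumor vs noncancer urine), intersected for cancer specificity,
   ranked by differential value, top-n selected;
3. per-read classifier trained on sequence+methylation encodings of reads
   in the selected regions (tumor-tissue aberrant-side reads as
   positives);
4. every urine sample scored: S = fraction of reads called tumor-derived;
5. ROC evaluation with the Youden cutoff frozen on the training cohort.

One master seed deterministically derives per-stage seeds by hashing the
stage name, so stages can be rerun independently and reproducibly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigError, MethylRead, Region, assign_reads_to_regions
from .model import (
    ModelSpec,
    ReadClassifier,
    build_training_set,
    score_reads,
    train_read_classifier,
)
from .regions import (
    DMRCall,
    call_dmrs,
    filter_specific,
    region_statistics,
    select_top_n,
)
from .scoring import CohortEvaluation, evaluate_holdout, sample_score
from .simulate import SimConfig, SimulatedStudy, simulate_study

__all__ = [
    "AnalysisConfig",
    "PipelineResult",
    "stage_seed",
    "study_region_stats",
    "discover_markers",
    "train_from_study",
    "score_cohort",
    "run_end_to_end",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class AnalysisConfig:
    """All analysis-stage parameters in one place.

    Thresholds: alpha_lo/alpha_hi bound the hypo/hyper read calls,
    min_cpgs_per_read and min_reads_per_region gate low-information reads
    and cells, q_threshold and min_abs_delta gate DMR calls, top_n fixes
    the marker count, tau is the read-level tumor-call threshold inside S.
    """

    alpha_lo: float = 0.2
    alpha_hi: float = 0.8
    min_cpgs_per_read: int = 3
    min_reads_per_region: int = 5
    q_threshold: float = 0.05
    min_abs_delta: float = 0.2
    top_n: int = 20
    direction: str = "hypo"
    tau: float = 0.5
    min_reads_for_score: int = 20
    score_method: str = "fraction"
    fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.1)
    model: ModelSpec = field(default_factory=ModelSpec)

    def validate(self) -> "AnalysisConfig":
        if not 0.0 <= self.alpha_lo < self.alpha_hi <= 1.0:
            raise ConfigError("need 0 <= alpha_lo < alpha_hi <= 1")
        if self.direction not in ("hypo", "hyper"):
            raise ConfigError("direction must be 'hypo' or 'hyper'")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        self.model.validate()
        return self

    @property
    def statistic(self) -> str:
        return "p_hypo" if self.direction == "hypo" else "p_hyper"


def study_region_stats(
    study: SimulatedStudy, cfg: AnalysisConfig
) -> tuple[pd.DataFrame, dict[str, list[MethylRead]]]:
    """Pool all sample reads, assign to the candidate panel, summarize."""
    all_reads = [r for reads in study.reads.values() for r in reads]
    by_region = assign_reads_to_regions(all_reads, study.candidate_regions())
    stats = region_statistics(
        by_region,
        alpha_lo=cfg.alpha_lo,
        alpha_hi=cfg.alpha_hi,
        min_cpgs=cfg.min_cpgs_per_read,
        min_reads=cfg.min_reads_per_region,
        samples=study.manifest["sample_id"].tolist(),
    )
    return stats, by_region


def discover_markers(
    stats: pd.DataFrame,
    manifest: pd.DataFrame,
    regions: list[Region],
    cfg: AnalysisConfig,
    case: str = "tumor_tissue",
    tissue_control: str = "normal_tissue",
    urine_control: str = "noncancer_urine",
) -> tuple[list[DMRCall], list[Region]]:
    """Call cancer-specific pDMRs and select the top-n marker regions."""
    kwargs = dict(
        statistic=cfg.statistic,
        regions=regions,
        min_abs_delta=cfg.min_abs_delta,
        q_threshold=cfg.q_threshold,
    )
    vs_tissue = call_dmrs(stats, manifest, case, tissue_control, **kwargs)
    vs_urine = call_dmrs(stats, manifest, case, urine_control, **kwargs)
    specific = filter_specific(vs_tissue, vs_urine)
    selected = select_top_n(specific, cfg.direction, cfg.top_n)
    return specific, selected


def train_from_study(
    by_region: dict[str, list[MethylRead]],
    selected: list[Region],
    manifest: pd.DataFrame,
    cfg: AnalysisConfig,
    seed: int,
    positive_group: str = "tumor_tissue",
    negative_groups: tuple[str, ...] = ("normal_tissue", "noncancer_urine"),
) -> tuple[ReadClassifier, pd.DataFrame, int]:
    """Assemble the labeled read set and train the classifier.

    Returns the model, the per-epoch training log, and the number of reads
    in the balanced training set.
    """
    train_set = build_training_set(
        by_region,
        selected,
        manifest,
        positive_group=positive_group,
        negative_groups=negative_groups,
        alpha_lo=cfg.alpha_lo,
        alpha_hi=cfg.alpha_hi,
        min_cpgs=cfg.min_cpgs_per_read,
        L=cfg.model.window_length,
        seed=stage_seed(seed, "balance"),
    )
    spec = ModelSpec(**{**cfg.model.__dict__, "seed": stage_seed(seed, "train")})
    model, log = train_read_classifier(train_set, spec)
    return model, log, int(train_set.X.shape[0])


def score_cohort(
    model: ReadClassifier,
    study: SimulatedStudy,
    selected: list[Region],
    cfg: AnalysisConfig,
    groups: tuple[str, ...] = ("pca_urine", "noncancer_urine"),
    case_group: str = "pca_urine",
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Score every sample of the chosen groups.

    Returns the per-sample table (sample_id, s, n_reads_scored, label,
    theta, reason) and the raw per-read score vectors keyed by sample
    (used downstream by the downsampling analysis).
    """
    manifest = study.manifest
    wanted = manifest.loc[manifest["group"].isin(groups)]
    rows = []
    read_scores: dict[str, np.ndarray] = {}
    for sid, group in zip(wanted["sample_id"], wanted["group"]):
        result = score_reads(
            model, study.reads[sid], selected, min_cpgs=cfg.min_cpgs_per_read
        )
        read_scores[sid] = result.scores
        ss = sample_score(
            result.scores,
            tau=cfg.tau,
            min_reads_for_score=cfg.min_reads_for_score,
            sample_id=sid,
            method=cfg.score_method,
        )
        rows.append(
            dict(
                sample_id=sid,
                s=ss.s,
                n_reads_scored=ss.n_reads_scored,
                label=int(group == case_group),
                theta=study.truth.get(sid, np.nan),
                reason=result.reason or "",
            )
        )
    return pd.DataFrame(rows), read_scores


@dataclass
class PipelineResult:
    """Everything an end-to-end run produces."""

    train_study: SimulatedStudy
    val_study: SimulatedStudy
    stats: pd.DataFrame
    calls: list[DMRCall]
    selected: list[Region]
    model: ReadClassifier
    training_log: pd.DataFrame
    n_training_reads: int
    train_scores: pd.DataFrame
    val_scores: pd.DataFrame
    train_read_scores: dict[str, np.ndarray]
    val_read_scores: dict[str, np.ndarray]
    evaluations: dict[str, CohortEvaluation]


def run_end_to_end(
    sim_config: SimConfig | None = None,
    analysis: AnalysisConfig | None = None,
    master_seed: int = 0,
) -> PipelineResult:
    """Run simulate -> call-dmrs -> train -> score -> evaluate.

    The training study carries tissue and urine cohorts; an independent
    validation urine cohort is drawn over the same region panel under a
    different derived seed.  The Youden cutoff is learned on the training
    cohort and frozen for validation.
    """
    sim_config = (sim_config or SimConfig()).validate()
    cfg = (analysis or AnalysisConfig()).validate()

    train_study = simulate_study(
        sim_config, seed=stage_seed(master_seed, "simulate-train")
    )
    val_study = simulate_study(
        sim_config,
        seed=stage_seed(master_seed, "simulate-val"),
        cohorts=("urine",),
        regions=train_study.regions,
    )

    stats, by_region = study_region_stats(train_study, cfg)
    calls, selected = discover_markers(
        stats, train_study.manifest, train_study.candidate_regions(), cfg
    )
    if not selected:
        raise ConfigError("no marker regions selected; nothing to train on")

    model, log, n_training_reads = train_from_study(
        by_region, selected, train_study.manifest, cfg, master_seed
    )

    train_scores, train_read_scores = score_cohort(model, train_study, selected, cfg)
    val_scores, val_read_scores = score_cohort(model, val_study, selected, cfg)
    evaluations = evaluate_holdout(
        {"training": train_scores, "validation": val_scores}
    )
    return PipelineResult(
        train_study=train_study,
        val_study=val_study,
        stats=stats,
        calls=calls,
        selected=selected,
        model=model,
        training_log=log,
        n_training_reads=n_training_reads,
        train_scores=train_scores,
        val_scores=val_scores,
        train_read_scores=train_read_scores,
        val_read_scores=val_read_scores,
        evaluations=evaluations,
    )
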