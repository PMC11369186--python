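"""Sample-level tumor-fraction scores and biomarker evaluation.

The sample score S is the estimated fraction of tumor-derived reads: the
share of a sample's scored reads whose classifier probability d exceeds a
read-call threshold tau (default 0.5).  A mean-probability aggregation
(S = mean d) is available behind a flag; the thresholded fraction is the
default because it reads most literally as a ratio of tumor-called reads.

Classification cutoffs on S are chosen by the Youden index
(J = sensitivity + specificity - 1) on the training cohort and frozen for
any validation cohort — the only leakage-free protocol.  The module also
provides generic biomarker ROC comparison, a marker-count threshold
sweep, and depth-downsampling robustness via read subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .io import ConfigError, DataError

__all__ = [
    "SampleScore",
    "RocResult",
    "CohortEvaluation",
    "sample_score",
    "roc_curve",
    "evaluate_holdout",
    "compare_biomarkers",
    "threshold_sweep",
    "downsample_robustness",
]


@dataclass
class SampleScore:
    """Estimated tumor-read ratio of one sample."""

    sample_id: str
    s: float  # NaN when n_reads_scored < min_reads_for_score
    n_reads_scored: int
    tau: float

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.s)


def sample_score(
    read_scores: np.ndarray,
    tau: float = 0.5,
    min_reads_for_score: int = 20,
    sample_id: str = "",
    method: str = "fraction",
) -> SampleScore:
    """Aggregate per-read tumor probabilities into the sample score.

    ``fraction`` (default): S = #(d > tau) / n.  ``mean``: S = mean(d).
    The score is missing (NaN) when fewer than ``min_reads_for_score``
    reads were scored — too few reads make the ratio meaningless.
    """
    if not 0.0 < tau < 1.0:
        raise ConfigError(f"tau must be in (0,1), got {tau}")
    if method not in ("fraction", "mean"):
        raise ConfigError(f"method must be 'fraction' or 'mean', got {method!r}")
    d = np.asarray(read_scores, dtype=float)
    n = int(d.size)
    if n < min_reads_for_score:
        return SampleScore(sample_id, float("nan"), n, tau)
    s = float(np.mean(d > tau)) if method == "fraction" else float(np.mean(d))
    return SampleScore(sample_id, s, n, tau)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC curve with the Youden-index operating point.

    A sample is called positive when its score is >= the cutoff.  Youden
    ties break toward the lowest cutoff (maximal sensitivity at equal J).
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    youden_cutoff: float
    j: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    n_case: int
    n_control: int

    def confusion_at(self, cutoff: float, scores, labels) -> tuple[int, int, int, int]:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        pred = scores >= cutoff
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        tn = int(np.sum(~pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        return tp, fp, tn, fn


def roc_curve(scores, labels) -> RocResult:
    """ROC analysis of sample scores against binary labels.

    AUC is the trapezoidal area, identical to the tie-corrected
    Mann–Whitney statistic.  The Youden cutoff is the lowest threshold
    maximizing sensitivity + specificity - 1; accuracy and the confusion
    counts are evaluated there with the >=-cutoff positive rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size or scores.size == 0:
        raise ConfigError("scores and labels must be equal-length and non-empty")
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite (drop missing samples first)")
    classes = np.unique(labels)
    if classes.size != 2 or set(classes) != {0, 1}:
        raise DataError(f"labels must contain both classes 0 and 1, got {classes}")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    auc = float(skm.auc(fpr, tpr))
    j_curve = tpr - fpr
    jmax = j_curve.max()
    # thresholds are decreasing; the last argmax is the lowest cutoff
    best = int(np.flatnonzero(np.isclose(j_curve, jmax))[-1])
    cutoff = float(thr[best])
    if np.isinf(cutoff):  # sklearn's sentinel above the top score
        cutoff = float(scores.max()) + 1.0
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return RocResult(
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
        youden_cutoff=cutoff,
        j=float(jmax),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / scores.size,
        n_case=int(np.sum(labels == 1)),
        n_control=int(np.sum(labels == 0)),
    )


@dataclass
class CohortEvaluation:
    """One cohort's performance at a (possibly frozen) cutoff."""

    cohort: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_case: int
    n_control: int
    excluded: list[str] = field(default_factory=list)  # samples with missing S


def evaluate_holdout(
    score_tables: Mapping[str, pd.DataFrame],
    train_cohort: str = "training",
) -> dict[str, CohortEvaluation]:
    """Evaluate cohorts with the cutoff frozen on the training cohort.

    Each table needs columns ``sample_id``, ``s`` and ``label`` (1 = case).
    Samples with a missing score are excluded and listed per cohort.  AUC
    is computed per cohort on its own scores; sensitivity, specificity and
    accuracy everywhere use the training Youden cutoff.
    """
    if train_cohort not in score_tables:
        raise ConfigError(f"no cohort named {train_cohort!r} in score tables")
    prepared: dict[str, tuple[pd.DataFrame, list[str]]] = {}
    for name, table in score_tables.items():
        missing = table.loc[~np.isfinite(table["s"]), "sample_id"].tolist()
        kept = table.loc[np.isfinite(table["s"])]
        for cls in (0, 1):
            if not (kept["label"] == cls).any():
                raise DataError(
                    f"cohort {name!r}: class {cls} empty after exclusions"
                )
        prepared[name] = (kept, missing)
    train_kept, _ = prepared[train_cohort]
    train_roc = roc_curve(train_kept["s"], train_kept["label"])
    cutoff = train_roc.youden_cutoff
    out: dict[str, CohortEvaluation] = {}
    for name, (kept, missing) in prepared.items():
        roc = roc_curve(kept["s"], kept["label"])
        tp, fp, tn, fn = roc.confusion_at(cutoff, kept["s"], kept["label"])
        out[name] = CohortEvaluation(
            cohort=name,
            auc=roc.auc,
            cutoff=cutoff,
            sensitivity=tp / (tp + fn),
            specificity=tn / (tn + fp),
            accuracy=(tp + tn) / len(kept),
            n_case=roc.n_case,
            n_control=roc.n_control,
            excluded=missing,
        )
    return out


# ---------------------------------------------------------------------------
# biomarker comparison
# ---------------------------------------------------------------------------

def compare_biomarkers(
    table: pd.DataFrame,
    columns: Sequence[str],
    label_col: str = "label",
    directions: Mapping[str, str] | None = None,
) -> dict[str, RocResult]:
    """ROC per numeric biomarker column on the row-complete sample set.

    ``directions`` maps a column to ``'higher'`` (default, higher value
    means case) or ``'lower'`` (inverse markers, e.g. free-to-total PSA
    ratio); lower-is-case columns are negated before the ROC so AUCs are
    directly comparable.
    """
    directions = dict(directions or {})
    for col in columns:
        if col not in table.columns:
            raise ConfigError(f"column {col!r} not in table")
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise DataError(f"column {col!r} is not numeric")
        if directions.setdefault(col, "higher") not in ("higher", "lower"):
            raise ConfigError(f"direction for {col!r} must be 'higher' or 'lower'")
    complete = table.dropna(subset=[*columns, label_col])
    out = {}
    for col in columns:
        vals = complete[col].to_numpy(dtype=float)
        if directions[col] == "lower":
            vals = -vals
        out[col] = roc_curve(vals, complete[label_col])
    return out


# ---------------------------------------------------------------------------
# marker-count threshold sweep
# ---------------------------------------------------------------------------

def threshold_sweep(
    n_grid: Sequence[int],
    n_available: int,
    run_fn: Callable[[int], tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Sweep the number of selected marker regions.

    ``run_fn(n)`` must rerun selection -> training -> scoring with the top
    ``n`` regions under the pipeline's master seed and return (scores,
    labels) for the evaluation cohort.  Duplicate grid values are computed
    once; values above ``n_available`` are clamped with a warning.  Returns
    a table (n_requested, n_used, auc, accuracy, youden_cutoff).
    """
    if any(n < 1 for n in n_grid):
        raise ConfigError("all grid values must be >= 1")
    rows = []
    cache: dict[int, RocResult] = {}
    for n in n_grid:
        n_used = min(int(n), n_available)
        if n_used < n:
            warnings.warn(
                f"grid point {n} exceeds available calls ({n_available}); "
                f"evaluating at {n_used}",
                stacklevel=2,
            )
        if n_used not in cache:
            scores, labels = run_fn(n_used)
            cache[n_used] = roc_curve(scores, labels)
        roc = cache[n_used]
        rows.append(
            dict(
                n_requested=int(n),
                n_used=n_used,
                auc=roc.auc,
                accuracy=roc.accuracy,
                youden_cutoff=roc.youden_cutoff,
            )
        )
    return pd.DataFrame(rows).drop_duplicates(subset="n_requested").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# downsampling robustness
# ---------------------------------------------------------------------------

def downsample_robustness(
    read_scores_by_sample: Mapping[str, np.ndarray],
    fractions: Sequence[float],
    tau: float = 0.5,
    min_reads_for_score: int = 20,
    seed: int = 0,
    method: str = "fraction",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute S after subsampling each sample's reads.

    Because S depends on a read only through its classifier probability,
    subsampling reads is equivalent to subsampling the per-read score
    vector, which avoids re-encoding.  Sampling is without replacement,
    ``floor(fraction * n)`` reads per cell, independently per (sample,
    fraction) under ``seed``.  Cells falling below ``min_reads_for_score``
    are missing; the Pearson correlation matrix between fractions is
    computed on pairwise-complete samples.
    """
    fracs = list(dict.fromkeys(float(f) for f in fractions))
    if any(not 0.0 < f <= 1.0 for f in fracs):
        raise ConfigError(f"fractions must be in (0,1], got {fractions}")
    rng = np.random.default_rng(seed)
    rows = {}
    for sid, d in read_scores_by_sample.items():
        d = np.asarray(d, dtype=float)
        row = {}
        for f in fracs:
            if f == 1.0:
                sub = d
            else:
                k = int(np.floor(f * d.size))
                sub = d[rng.choice(d.size, k, replace=False)] if k else d[:0]
            row[f] = sample_score(
                sub, tau=tau, min_reads_for_score=min_reads_for_score,
                sample_id=sid, method=method,
            ).s
        rows[sid] = row
    scores = pd.DataFrame.from_dict(rows, orient="index")[fracs]
    scores.index.name = "sample_id"
    corr = scores.corr(method="pearson", min_periods=2)
    return scores, corr
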