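"""Read-level alpha values, region statistics, and DMR calling.

The central quantity is the per-read alpha value — the fraction of a
read's covered CpGs that are methylated.  Two kinds of region statistic
are derived from it per sample:

* ``mean_meth`` (M): CpG-call-weighted mean methylation of a region, the
  basis for mean-level DMRs (mDMRs);
* ``p_hypo`` / ``p_hyper`` (P): the proportion of reads whose alpha is at
  or below ``alpha_lo`` / at or above ``alpha_hi``, the basis for
  read-proportion DMRs (pDMRs).  Tumor signal in a dilute mixture lives in
  the aberrant read subpopulation, which the proportion statistic sees and
  the mean dilutes away — this is the reason pDMRs outperform mDMRs at low
  tumor fractions.

Group differences are tested per region with a two-sided Wilcoxon
rank-sum test across per-sample statistics and Benjamini–Hochberg
corrected across regions; calls additionally require a minimum absolute
difference of group means.  Cancer-specific calls must replicate, with
the same direction, against both the adjacent-normal and the
noncancer-urine contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, DataError, MethylRead, Region

__all__ = [
    "ReadAlpha",
    "DMRCall",
    "compute_alpha",
    "region_statistics",
    "call_dmrs",
    "filter_specific",
    "select_top_n",
    "region_auc",
    "cluster_samples",
    "write_dmr_calls",
    "read_dmr_calls",
    "STAT_COLUMNS",
]

#: statistics testable by call_dmrs / region_auc
STAT_COLUMNS = ("mean_meth", "p_hypo", "p_hyper")


@dataclass(frozen=True)
class ReadAlpha:
    """Per-read methylation summary: alpha = methylated / covered CpGs."""

    read: MethylRead
    alpha: float
    n_cpgs: int


@dataclass
class DMRCall:
    """One region's differential-methylation test result."""

    region: Region
    kind: str  # 'mDMR' | 'pDMR'
    statistic: str
    direction: str  # 'hypo' | 'hyper'
    delta: float  # mean(case) - mean(control)
    p_value: float
    q_value: float
    called: bool
    specific: bool = False


def compute_alpha(read: MethylRead, min_cpgs: int = 3) -> ReadAlpha | None:
    """Alpha value of one read, or None if it covers fewer than min_cpgs CpGs.

    Exclusion (not zero-filling) keeps low-information reads out of the
    proportion statistics.
    """
    n = len(read.cpg_states)
    if n < min_cpgs:
        return None
    return ReadAlpha(read, sum(read.cpg_states) / n, n)


def region_statistics(
    reads_by_region: dict[str, list[MethylRead]],
    alpha_lo: float = 0.2,
    alpha_hi: float = 0.8,
    min_cpgs: int = 3,
    min_reads: int = 5,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region, per-sample summary statistics.

    Returns a tidy DataFrame with one row per (region_id, sample_id) and
    columns ``n_reads`` (alpha-qualifying reads), ``n_cpg_calls``,
    ``mean_meth``, ``p_hypo``, ``p_hyper``.  ``mean_meth`` weights every
    CpG call equally over all of a region's reads; the proportions are over
    alpha-qualifying reads only.  Statistics of a (region, sample) cell
    with fewer than ``min_reads`` qualifying reads are set missing (NaN).
    When ``samples`` is given, zero-read cells are materialized as missing
    rows so downstream pivots see every sample.
    """
    if not 0.0 <= alpha_lo < alpha_hi <= 1.0:
        raise ConfigError(
            f"need 0 <= alpha_lo < alpha_hi <= 1, got {alpha_lo}, {alpha_hi}"
        )
    rows = []
    for region_id, reads in reads_by_region.items():
        per_sample: dict[str, list] = {}
        for read in reads:
            per_sample.setdefault(read.sample_id, []).append(read)
        sample_ids = samples if samples is not None else sorted(per_sample)
        for sid in sample_ids:
            sreads = per_sample.get(sid, [])
            meth_calls = sum(sum(r.cpg_states) for r in sreads)
            total_calls = sum(len(r.cpg_states) for r in sreads)
            alphas = np.array(
                [
                    a.alpha
                    for r in sreads
                    if (a := compute_alpha(r, min_cpgs)) is not None
                ]
            )
            n = alphas.size
            if n >= min_reads:
                row = dict(
                    region_id=region_id,
                    sample_id=sid,
                    n_reads=n,
                    n_cpg_calls=total_calls,
                    mean_meth=meth_calls / total_calls if total_calls else np.nan,
                    p_hypo=float(np.mean(alphas <= alpha_lo)),
                    p_hyper=float(np.mean(alphas >= alpha_hi)),
                )
            else:
                row = dict(
                    region_id=region_id,
                    sample_id=sid,
                    n_reads=n,
                    n_cpg_calls=total_calls,
                    mean_meth=np.nan,
                    p_hypo=np.nan,
                    p_hyper=np.nan,
                )
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "sample_id",
            "n_reads",
            "n_cpg_calls",
            "mean_meth",
            "p_hypo",
            "p_hyper",
        ],
    )


def _group_samples(manifest: pd.DataFrame, label: str, label_col: str) -> list[str]:
    if label_col not in manifest.columns:
        raise ConfigError(f"manifest has no column {label_col!r}")
    ids = manifest.loc[manifest[label_col] == label, "sample_id"].tolist()
    if not ids:
        raise ConfigError(f"no samples with {label_col} == {label!r} in manifest")
    return ids


def _direction(statistic: str, delta: float) -> str:
    """Map the sign of delta (case - control) to hypo/hyper."""
    if statistic == "p_hypo":
        return "hypo" if delta > 0 else "hyper"
    if statistic == "p_hyper":
        return "hyper" if delta > 0 else "hypo"
    return "hyper" if delta > 0 else "hypo"  # mean_meth


def call_dmrs(
    stats: pd.DataFrame,
    manifest: pd.DataFrame,
    case: str,
    control: str,
    statistic: str = "p_hypo",
    regions: dict[str, Region] | list[Region] | None = None,
    label_col: str = "group",
    min_abs_delta: float = 0.2,
    q_threshold: float = 0.05,
    min_samples: int = 2,
) -> list[DMRCall]:
    """Call DMRs on a chosen per-sample statistic.

    Per region, case and control per-sample values are compared with a
    two-sided Wilcoxon rank-sum test; samples with a missing statistic are
    dropped from that region's test only, and regions with fewer than
    ``min_samples`` non-missing values in either group are not tested.
    Benjamini–Hochberg correction runs across all tested regions.  A region
    is called when ``q <= q_threshold`` and ``|delta| >= min_abs_delta``,
    with ``delta = mean(case) - mean(control)`` and direction from the sign
    of delta.
    """
    if statistic not in STAT_COLUMNS:
        raise ConfigError(f"statistic must be one of {STAT_COLUMNS}")
    case_ids = set(_group_samples(manifest, case, label_col))
    control_ids = set(_group_samples(manifest, control, label_col))
    region_map = _region_map(regions, stats)

    wide = stats.pivot(index="region_id", columns="sample_id", values=statistic)
    tested: list[tuple[str, float, float]] = []
    for region_id, row in wide.iterrows():
        x = row[row.index.isin(case_ids)].dropna().to_numpy()
        y = row[row.index.isin(control_ids)].dropna().to_numpy()
        if x.size < min_samples or y.size < min_samples:
            continue
        delta = float(x.mean() - y.mean())
        if np.ptp(np.concatenate([x, y])) == 0.0:
            p = 1.0  # all values tied: no evidence either way
        else:
            p = float(
                sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
            )
        tested.append((region_id, delta, p))
    if not tested:
        return []
    pvals = np.array([t[2] for t in tested])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    kind = "mDMR" if statistic == "mean_meth" else "pDMR"
    calls = []
    for (region_id, delta, p), q in zip(tested, qvals):
        calls.append(
            DMRCall(
                region=region_map[region_id],
                kind=kind,
                statistic=statistic,
                direction=_direction(statistic, delta),
                delta=delta,
                p_value=p,
                q_value=float(q),
                called=bool(q <= q_threshold and abs(delta) >= min_abs_delta),
            )
        )
    return calls


def _region_map(
    regions: dict[str, Region] | list[Region] | None, stats: pd.DataFrame
) -> dict[str, Region]:
    if isinstance(regions, dict):
        return regions
    if regions is not None:
        return {r.id: r for r in regions}
    # placeholder Regions carrying only ids; coordinates unknown from stats
    return {
        rid: Region("?", 0, 1, rid) for rid in stats["region_id"].unique()
    }


def filter_specific(
    calls_vs_normal: list[DMRCall], calls_vs_noncancer: list[DMRCall]
) -> list[DMRCall]:
    """Keep regions called with the same direction in both contrasts.

    The surviving call carries the smaller-magnitude delta of the two
    (conservative) and the larger q.  Both call sets must cover the same
    region universe.
    """
    a = {c.region.id: c for c in calls_vs_normal}
    b = {c.region.id: c for c in calls_vs_noncancer}
    if set(a) != set(b):
        raise DataError(
            "region universes differ between the two contrasts "
            f"({len(set(a) ^ set(b))} regions mismatch)"
        )
    out = []
    for rid, ca in a.items():
        cb = b[rid]
        if ca.called and cb.called and ca.direction == cb.direction:
            keep = ca if abs(ca.delta) <= abs(cb.delta) else cb
            out.append(
                DMRCall(
                    region=ca.region,
                    kind=ca.kind,
                    statistic=ca.statistic,
                    direction=ca.direction,
                    delta=keep.delta,
                    p_value=max(ca.p_value, cb.p_value),
                    q_value=max(ca.q_value, cb.q_value),
                    called=True,
                    specific=True,
                )
            )
    return out


def select_top_n(
    calls: list[DMRCall], direction: str, n: int, require_specific: bool = True
) -> list[Region]:
    """Top-n regions of one direction, ranked by |delta| descending.

    Ties break by q ascending, then (chrom, start).  A warning is raised
    when fewer than n qualifying calls exist; the available ones are
    returned.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    pool = [
        c
        for c in calls
        if c.called
        and c.direction == direction
        and (c.specific or not require_specific)
    ]
    pool.sort(key=lambda c: (-abs(c.delta), c.q_value, c.region.chrom, c.region.start))
    if len(pool) < n:
        warnings.warn(
            f"requested top {n} {direction} calls but only {len(pool)} available",
            stacklevel=2,
        )
    out = []
    for c in pool[:n]:
        region = Region(
            c.region.chrom, c.region.start, c.region.end, c.region.id, c.direction
        )
        region.stats = {"delta": c.delta, "q_value": c.q_value}
        out.append(region)
    return out


def region_auc(
    stats: pd.DataFrame,
    manifest: pd.DataFrame,
    case: str,
    control: str,
    statistic: str = "p_hypo",
    label_col: str = "group",
) -> pd.Series:
    """Per-region AUC of the statistic as a case-vs-control ranking.

    AUC = Mann–Whitney U / (n_case * n_control), ties counting one half.
    Regions where either group has no non-missing sample get NaN.
    """
    if statistic not in STAT_COLUMNS:
        raise ConfigError(f"statistic must be one of {STAT_COLUMNS}")
    case_ids = set(_group_samples(manifest, case, label_col))
    control_ids = set(_group_samples(manifest, control, label_col))
    wide = stats.pivot(index="region_id", columns="sample_id", values=statistic)
    out = {}
    for region_id, row in wide.iterrows():
        x = row[row.index.isin(case_ids)].dropna().to_numpy()
        y = row[row.index.isin(control_ids)].dropna().to_numpy()
        if x.size == 0 or y.size == 0:
            out[region_id] = np.nan
            continue
        u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
        out[region_id] = float(u / (x.size * y.size))
    return pd.Series(out, name=f"auc_{statistic}").sort_index()


def write_dmr_calls(calls: list[DMRCall], path) -> None:
    """Write calls as BED6+ (score = |delta| scaled to 0-1000)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tid\tscore\tstrand\tkind\tstatistic\t"
            "direction\tdelta\tp_value\tq_value\tcalled\tspecific\n"
        )
        for c in sorted(calls, key=lambda c: (c.region.chrom, c.region.start)):
            score = int(round(min(abs(c.delta), 1.0) * 1000))
            fh.write(
                f"{c.region.chrom}\t{c.region.start}\t{c.region.end}\t"
                f"{c.region.id}\t{score}\t.\t{c.kind}\t{c.statistic}\t"
                f"{c.direction}\t{c.delta:.6g}\t{c.p_value:.6g}\t"
                f"{c.q_value:.6g}\t{int(c.called)}\t{int(c.specific)}\n"
            )


def read_dmr_calls(path) -> list[DMRCall]:
    """Read calls written by :func:`write_dmr_calls`."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"#chrom": "chrom"})
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            DMRCall(
                region=Region(row.chrom, int(row.start), int(row.end), row.id),
                kind=row.kind,
                statistic=row.statistic,
                direction=row.direction,
                delta=float(row.delta),
                p_value=float(row.p_value),
                q_value=float(row.q_value),
                called=bool(row.called),
                specific=bool(row.specific),
            )
        )
    return calls


def cluster_samples(
    matrix: pd.DataFrame,
    deltas: pd.Series | None = None,
    top_fraction: float = 0.1,
) -> tuple[np.ndarray, pd.Series]:
    """Ward hierarchical clustering of samples on region statistics.

    ``matrix`` is samples x regions (e.g. a pivot of ``p_hypo``); when
    ``deltas`` (per-region differential values) is given, clustering is
    restricted to the ``top_fraction`` of regions by |delta|.  Missing
    entries are imputed with the region (column) mean.  Returns the scipy
    linkage matrix and flat labels at k=2, deterministic for a given row
    order up to Ward's distance-tie handling.
    """
    if matrix.shape[0] < 2:
        raise DataError("need at least 2 samples to cluster")
    if not 0.0 < top_fraction <= 1.0:
        raise ConfigError(f"top_fraction must be in (0,1], got {top_fraction}")
    sub = matrix
    if deltas is not None:
        k = max(1, int(round(top_fraction * len(deltas))))
        keep = deltas.abs().sort_values(ascending=False).index[:k]
        sub = matrix.loc[:, matrix.columns.intersection(keep)]
    filled = sub.apply(lambda col: col.fillna(col.mean()), axis=0)
    filled = filled.dropna(axis=1, how="all")
    if filled.shape[1] == 0:
        raise DataError("no usable regions after imputation")
    Z = hierarchy.linkage(filled.to_numpy(), method="ward")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(labels, index=matrix.index, name="cluster")
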