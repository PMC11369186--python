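"""Synthetic bisulfite-read generator.

Emulates the data regime the scoring method targets: a panel of candidate
regions with region-structured CpG methylation, tumor and normal tissue
read sets, and urine samples that are two-component mixtures of a small
tumor-read fraction ``theta`` in a noncancer background.

The generative model per read is Beta-Bernoulli: a read drawn from origin
``o`` in a region with mean methylation ``p_o`` first draws a read-level
methylation propensity ``mu ~ Beta(p_o * kappa, (1 - p_o) * kappa)``, then
methylates each covered CpG independently ``Bernoulli(mu)``.  The Beta
concentration ``kappa`` controls within-read concordance — the empirical
pattern that methylation states tend to be shared along a DNA fragment —
without changing the region mean.  Smaller ``kappa`` means more bimodal,
more concordant reads.

Only reads overlapping the candidate regions are simulated; background
genome, sequencing error and fragment-length variation are out of scope
(a single uniform state-flip rate is available for non-conversion-style
noise, default 0).  All reads are reported on the plus strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ConfigError, MethylRead, Region, write_bed, write_read_records, write_manifest

__all__ = [
    "SimRegion",
    "SimConfig",
    "SimulatedStudy",
    "simulate_reference",
    "simulate_reads",
    "simulate_sample",
    "simulate_urine_sample",
    "simulate_study",
    "write_study",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimRegion:
    """A simulated candidate region with its group methylation profile."""

    chrom: str
    start: int
    end: int
    region_id: str
    sequence: str
    cpg_offsets: np.ndarray  # position of the C of each CpG, region-relative
    p_meth_tumor: float
    p_meth_normal: float
    concordance_kappa: float
    motif: str | None = None
    informative: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ConfigError(f"{self.region_id}: start >= end")
        offs = np.asarray(self.cpg_offsets, dtype=np.int64)
        if np.any(np.diff(offs) < 2):
            raise ConfigError(f"{self.region_id}: CpG offsets closer than 2 bp")
        if offs.size and (offs[0] < 0 or offs[-1] > self.end - self.start - 2):
            raise ConfigError(f"{self.region_id}: CpG offset outside region")
        for p in (self.p_meth_tumor, self.p_meth_normal):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{self.region_id}: p_meth {p} outside [0,1]")
        if self.concordance_kappa <= 0:
            raise ConfigError(f"{self.region_id}: kappa must be > 0")
        self.cpg_offsets = offs

    def p_meth(self, origin: str) -> float:
        if origin == "tumor":
            return self.p_meth_tumor
        if origin == "normal":
            return self.p_meth_normal
        raise ConfigError(f"unknown origin {origin!r}")

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end, self.region_id)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults are the desk-scale analog of the targeted WGBS regime: a panel
    of 200 candidate regions of which 20 are informative (tumor-hypo with a
    methylation difference of 0.8), tissue samples at 10X region coverage,
    urine mixtures at 20X, and a tumor-fraction grid spanning 0–0.3 with
    five samples per level.
    """

    n_regions: int = 200
    n_informative: int = 20
    region_length: int = 240
    cpgs_per_region: int = 12
    read_length: int = 100
    reads_per_region_per_x: int = 2
    # methylation profile
    p_meth_tumor: float = 0.1
    p_meth_normal: float = 0.9
    p_background: float = 0.8
    informative_direction: Literal["hypo", "hyper"] = "hypo"
    concordance_kappa: float = 15.0
    flip_rate: float = 0.0
    motif: str | None = None
    # cohort design
    tissue_depth_x: float = 10.0
    urine_depth_x: float = 20.0
    n_tumor_tissue: int = 10
    n_normal_tissue: int = 10
    n_noncancer_urine: int = 25
    theta_grid: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.3)
    samples_per_theta: int = 5
    seed: int = 0

    def validate(self) -> "SimConfig":
        counts = dict(
            n_regions=self.n_regions,
            region_length=self.region_length,
            cpgs_per_region=self.cpgs_per_region,
            read_length=self.read_length,
            reads_per_region_per_x=self.reads_per_region_per_x,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if not 0 <= self.n_informative <= self.n_regions:
            raise ConfigError("n_informative must be in [0, n_regions]")
        # each CpG needs 2 bp and pads 1 bp at each end
        if self.region_length < 2 * self.cpgs_per_region + 2:
            raise ConfigError(
                f"region_length={self.region_length} too small to host "
                f"{self.cpgs_per_region} CpGs"
            )
        if self.read_length > self.region_length:
            raise ConfigError("read_length must not exceed region_length")
        for p in (self.p_meth_tumor, self.p_meth_normal, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"methylation probability {p} outside [0,1]")
        if self.concordance_kappa <= 0:
            raise ConfigError("concordance_kappa must be > 0")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ConfigError("flip_rate must be in [0,1]")
        if any(not 0.0 <= t <= 1.0 for t in self.theta_grid):
            raise ConfigError("theta_grid values must be in [0,1]")
        if self.informative_direction not in ("hypo", "hyper"):
            raise ConfigError("informative_direction must be 'hypo' or 'hyper'")
        return self


@dataclass
class SimulatedStudy:
    """A full synthetic study: regions, per-sample reads, manifest, truth."""

    config: SimConfig
    regions: list[SimRegion]
    fasta: str
    reads: dict[str, list[MethylRead]]
    manifest: pd.DataFrame
    truth: dict[str, float]  # sample_id -> true tumor fraction (urine only)

    @property
    def informative_ids(self) -> list[str]:
        return [r.region_id for r in self.regions if r.informative]

    def candidate_regions(self) -> list[Region]:
        return [r.as_region() for r in self.regions]


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _random_cg_free_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random base array of length n containing no CG dinucleotide."""
    seq = rng.integers(0, 4, size=n)  # 0=A 1=C 2=G 3=T
    # destroy CG pairs by rewriting the G; C followed by A/C/T never forms CG
    while True:
        cg = np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2))
        if cg.size == 0:
            return seq
        seq[cg + 1] = rng.choice([0, 1, 3], size=cg.size)


def _place_cpg_offsets(
    region_length: int, n_cpgs: int, rng: np.random.Generator
) -> np.ndarray:
    """Roughly even CpG placement with jitter; gaps >= 2 bp guaranteed."""
    lo, hi = 1, region_length - 3  # keep 1 bp clear of both ends
    slots = np.linspace(lo, hi, n_cpgs)
    gap = (hi - lo) / max(n_cpgs - 1, 1)
    jitter = rng.uniform(-0.3 * gap, 0.3 * gap, size=n_cpgs) if n_cpgs > 1 else np.zeros(1)
    offs = np.sort(np.round(slots + jitter).astype(np.int64))
    offs = np.clip(offs, lo, hi)
    # enforce minimum spacing of 2
    for i in range(1, len(offs)):
        if offs[i] < offs[i - 1] + 2:
            offs[i] = offs[i - 1] + 2
    if offs.size and offs[-1] > hi:
        raise ConfigError(
            f"cannot place {n_cpgs} CpGs with 2 bp spacing in {region_length} bp"
        )
    return offs


def simulate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[SimRegion], str]:
    """Generate the candidate-region panel and its FASTA text.

    Every region's sequence contains ``CG`` exactly at the recorded CpG
    offsets and nowhere else, so CpG bookkeeping is exact by construction.
    Which regions are informative is drawn without replacement under the
    config seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    informative = np.zeros(config.n_regions, dtype=bool)
    informative[
        rng.choice(config.n_regions, size=config.n_informative, replace=False)
    ] = True
    if config.informative_direction == "hypo":
        p_tum, p_norm = config.p_meth_tumor, config.p_meth_normal
    else:
        p_tum, p_norm = config.p_meth_normal, config.p_meth_tumor
    gap = 100  # bp between consecutive regions on the synthetic chromosome
    regions: list[SimRegion] = []
    fasta_parts: list[str] = []
    for i in range(config.n_regions):
        offs = _place_cpg_offsets(config.region_length, config.cpgs_per_region, rng)
        seq = _random_cg_free_sequence(config.region_length, rng)
        seq[offs] = 1  # C
        seq[offs + 1] = 2  # G
        sequence = _BASES[seq].tobytes().decode()
        start = i * (config.region_length + gap)
        region = SimRegion(
            chrom="chrSim",
            start=start,
            end=start + config.region_length,
            region_id=f"region_{i:04d}",
            sequence=sequence,
            cpg_offsets=offs,
            p_meth_tumor=p_tum if informative[i] else config.p_background,
            p_meth_normal=p_norm if informative[i] else config.p_background,
            concordance_kappa=config.concordance_kappa,
            motif=config.motif,
            informative=bool(informative[i]),
        )
        regions.append(region)
        fasta_parts.append(f">{region.region_id} {region.chrom}:{region.start}-{region.end}\n{sequence}\n")
    return regions, "".join(fasta_parts)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _draw_mu(p: float, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Read-level methylation propensities; degenerate p handled exactly."""
    if p <= 0.0:
        return np.zeros(n)
    if p >= 1.0:
        return np.ones(n)
    return rng.beta(p * kappa, (1.0 - p) * kappa, size=n)


def simulate_reads(
    region: SimRegion,
    n_reads: int,
    origin: Literal["tumor", "normal"],
    rng: np.random.Generator | int,
    read_length: int = 100,
    flip_rate: float = 0.0,
    sample_id: str = "",
) -> list[MethylRead]:
    """Draw reads of one origin uniformly within a region.

    Each read's methylation propensity is Beta-distributed around the
    origin's region mean; covered CpGs are then independent Bernoulli
    draws.  ``flip_rate`` flips each state independently (conversion-noise
    stand-in, default off).  The origin is recorded as the ground-truth
    label on every read.
    """
    if n_reads < 0:
        raise ConfigError(f"n_reads must be >= 0, got {n_reads}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    L = region.end - region.start
    if read_length > L:
        raise ConfigError(
            f"read_length {read_length} exceeds region length {L}"
        )
    if n_reads == 0:
        return []
    p = region.p_meth(origin)
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    mus = _draw_mu(p, region.concordance_kappa, n_reads, rng)
    offs = region.cpg_offsets
    seq = region.sequence
    motif = region.motif if origin == "tumor" else None
    reads: list[MethylRead] = []
    for k in range(n_reads):
        s = int(starts[k])
        lo = np.searchsorted(offs, s, side="left")
        hi = np.searchsorted(offs, s + read_length - 2, side="right")
        covered = offs[lo:hi]
        states = (rng.random(covered.size) < mus[k]).astype(np.int64)
        if flip_rate > 0.0 and covered.size:
            flips = rng.random(covered.size) < flip_rate
            states[flips] = 1 - states[flips]
        read_seq = seq[s : s + read_length]
        if motif:
            read_seq = _embed_motif(read_seq, covered - s, motif)
        reads.append(
            MethylRead(
                chrom=region.chrom,
                start=region.start + s,
                strand="+",
                sequence=read_seq,
                cpg_offsets=(covered - s).tolist(),
                cpg_states=states.tolist(),
                sample_id=sample_id,
                origin_label=origin,
            )
        )
    return reads


def _embed_motif(seq: str, cpg_offsets: np.ndarray, motif: str) -> str:
    """Overwrite the read start with a motif, preserving CpG bookkeeping."""
    m = len(motif)
    if m > len(seq):
        return seq
    protected = set()
    for o in cpg_offsets:
        protected.update((int(o), int(o) + 1))
    bases = list(seq)
    for i, ch in enumerate(motif):
        if i not in protected:
            bases[i] = ch
    # a motif C just before a CpG-free G could mint a spurious CG; accept it —
    # the sequence channel only needs learnable signal, not CG-free purity
    return "".join(bases)


def simulate_sample(
    regions: Sequence[SimRegion],
    origin: Literal["tumor", "normal"],
    depth_x: float,
    rng: np.random.Generator | int,
    config: SimConfig,
    sample_id: str = "",
) -> list[MethylRead]:
    """Simulate one pure-origin (tissue) sample across all regions.

    Read counts per region are Poisson with mean
    ``depth_x * reads_per_region_per_x``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lam = depth_x * config.reads_per_region_per_x
    reads: list[MethylRead] = []
    counts = rng.poisson(lam, size=len(regions))
    for region, n in zip(regions, counts):
        reads.extend(
            simulate_reads(
                region, int(n), origin, rng,
                read_length=config.read_length,
                flip_rate=config.flip_rate,
                sample_id=sample_id,
            )
        )
    return reads


def simulate_urine_sample(
    regions: Sequence[SimRegion],
    theta: float,
    depth_x: float,
    rng: np.random.Generator | int,
    config: SimConfig,
    sample_id: str = "",
) -> tuple[list[MethylRead], float]:
    """Simulate a urine sample: a mixture of tumor reads at fraction theta.

    Every read is independently tumor-origin with probability ``theta`` and
    normal-origin otherwise; the realized origin of each read is retained as
    its ground-truth label, and the nominal ``theta`` is returned for
    parameter-recovery checks.
    """
    if not 0.0 <= theta <= 1.0:
        raise ConfigError(f"theta must be in [0,1], got {theta}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lam = depth_x * config.reads_per_region_per_x
    reads: list[MethylRead] = []
    counts = rng.poisson(lam, size=len(regions))
    for region, n in zip(regions, counts):
        n = int(n)
        k = int(rng.binomial(n, theta)) if n else 0
        reads.extend(
            simulate_reads(
                region, k, "tumor", rng,
                read_length=config.read_length,
                flip_rate=config.flip_rate,
                sample_id=sample_id,
            )
        )
        reads.extend(
            simulate_reads(
                region, n - k, "normal", rng,
                read_length=config.read_length,
                flip_rate=config.flip_rate,
                sample_id=sample_id,
            )
        )
    return reads, theta


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimConfig,
    seed: int | None = None,
    cohorts: Sequence[str] = ("tissue", "urine"),
    regions: list[SimRegion] | None = None,
) -> SimulatedStudy:
    """Simulate a full study under one seed.

    The tissue cohort holds ``n_tumor_tissue`` tumor and ``n_normal_tissue``
    adjacent-normal samples.  The urine cohort holds
    ``samples_per_theta`` case samples per positive theta in ``theta_grid``
    (group ``pca_urine``) plus ``n_noncancer_urine`` controls at theta 0
    (group ``noncancer_urine``).  True thetas are retained in ``truth``.
    Passing ``regions`` reuses an existing panel (e.g. to draw an
    independent validation cohort over the same reference).
    """
    config.validate()
    master = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(master)
    if regions is None:
        regions, fasta = simulate_reference(config, rng)
    else:
        regions = list(regions)
        fasta = "".join(
            f">{r.region_id} {r.chrom}:{r.start}-{r.end}\n{r.sequence}\n"
            for r in regions
        )
    reads: dict[str, list[MethylRead]] = {}
    rows: list[dict] = []
    truth: dict[str, float] = {}

    if "tissue" in cohorts:
        for i in range(config.n_tumor_tissue):
            sid = f"tumor_tissue_{i:02d}"
            reads[sid] = simulate_sample(
                regions, "tumor", config.tissue_depth_x, rng, config, sid
            )
            rows.append({"sample_id": sid, "group": "tumor_tissue"})
        for i in range(config.n_normal_tissue):
            sid = f"normal_tissue_{i:02d}"
            reads[sid] = simulate_sample(
                regions, "normal", config.tissue_depth_x, rng, config, sid
            )
            rows.append({"sample_id": sid, "group": "normal_tissue"})

    if "urine" in cohorts:
        for theta in config.theta_grid:
            if theta <= 0:
                continue
            for j in range(config.samples_per_theta):
                sid = f"pca_urine_t{theta:g}_{j:02d}".replace(".", "p")
                reads[sid], _ = simulate_urine_sample(
                    regions, theta, config.urine_depth_x, rng, config, sid
                )
                truth[sid] = theta
                rows.append({"sample_id": sid, "group": "pca_urine"})
        for i in range(config.n_noncancer_urine):
            sid = f"noncancer_urine_{i:02d}"
            reads[sid], _ = simulate_urine_sample(
                regions, 0.0, config.urine_depth_x, rng, config, sid
            )
            truth[sid] = 0.0
            rows.append({"sample_id": sid, "group": "noncancer_urine"})

    manifest = pd.DataFrame(rows, columns=["sample_id", "group"])
    return SimulatedStudy(config, regions, fasta, reads, manifest, truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write a simulated study as a dataset directory.

    Layout: ``regions.fa``, ``regions.bed``, ``manifest.tsv``,
    ``truth.json`` and one read-record TSV per sample under ``reads/``.
    The manifest's ``reads_path`` column points at each sample's TSV,
    relative to the dataset root.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    (outdir / "regions.fa").write_text(study.fasta)
    write_bed(study.candidate_regions(), outdir / "regions.bed")
    manifest = study.manifest.copy()
    manifest["reads_path"] = [
        f"reads/{sid}.tsv" for sid in manifest["sample_id"]
    ]
    write_manifest(manifest, outdir / "manifest.tsv")
    truth = {
        "seed": study.config.seed,
        "informative_regions": study.informative_ids,
        "theta": study.truth,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(study.config).items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    for sid, sample_reads in study.reads.items():
        write_read_records(sample_reads, outdir / "reads" / f"{sid}.tsv")
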