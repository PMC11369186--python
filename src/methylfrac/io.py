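"""On-disk formats and canonical in-memory containers.

Everything downstream operates on :class:`MethylRead` (one sequenced
bisulfite fragment with per-CpG methylation states) and :class:`Region`
(a candidate or called differentially methylated region).  All genomic
coordinates are 0-based half-open on the plus strand; a CpG is anchored
at the position of its C on the plus strand.  Minus-strand reads are
normalized to this frame at ingest (sequence reverse-complemented,
offsets remapped), so no later stage needs to reason about strand.

Supported formats:

* read-record TSV — the reference interchange format for per-read
  methylation calls (columns: sample_id, chrom, start, strand, sequence,
  cpg_offsets, cpg_states, origin_label);
* BED (3+ columns) for region coordinates, BED6+ for DMR calls;
* Bismark-style cytosine report TSV for per-CpG count summaries;
* sample-manifest TSV (sample_id, group and/or grade, reads_path,
  optional numeric biomarker columns);
* optionally, Bismark alignments in SAM/BAM via the XM tag (requires
  pysam; the TSV path is the tested reference implementation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConfigError",
    "DataError",
    "MethylRead",
    "Region",
    "VALID_GROUPS",
    "VALID_GRADES",
    "read_read_records",
    "write_read_records",
    "read_bed",
    "write_bed",
    "read_cpg_report",
    "read_manifest",
    "assign_reads_to_regions",
    "read_bismark_alignments",
]


class FormatError(ValueError):
    """Malformed on-disk input; the message names the offending row."""


class ConfigError(ValueError):
    """Invalid parameter or configuration value."""


class DataError(ValueError):
    """Structurally valid input that violates a data-level contract."""


VALID_GROUPS = frozenset(
    {"tumor_tissue", "normal_tissue", "pca_urine", "noncancer_urine"}
)
VALID_GRADES = frozenset({"HGS", "LGS", "none"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

READ_RECORD_COLUMNS = (
    "sample_id",
    "chrom",
    "start",
    "strand",
    "sequence",
    "cpg_offsets",
    "cpg_states",
    "origin_label",
)

_STATE_CODE = {"M": 1, "U": 0}
_CODE_STATE = {1: "M", 0: "U"}


class MethylRead:
    """One sequenced fragment with its base sequence and CpG methylation states.

    Parameters
    ----------
    chrom, start
        Genomic placement; ``start`` is the 0-based leftmost aligned base.
    strand
        ``'+'`` or ``'-'``.  Construction with ``'-'`` is allowed for raw
        ingest; :meth:`normalized` maps the read to the plus-strand frame.
    sequence
        Read bases over ``ACGTN``, 5'->3' on ``strand``.
    cpg_offsets
        Strictly increasing offsets into ``sequence`` pointing at the C of
        each covered CpG (``sequence[o:o+2] == "CG"``).
    cpg_states
        Per-CpG methylation calls, 1 = methylated, 0 = unmethylated.
    """

    __slots__ = (
        "chrom",
        "start",
        "strand",
        "sequence",
        "cpg_offsets",
        "cpg_states",
        "sample_id",
        "origin_label",
    )

    def __init__(
        self,
        chrom: str,
        start: int,
        strand: str,
        sequence: str,
        cpg_offsets: Sequence[int],
        cpg_states: Sequence[int],
        sample_id: str = "",
        origin_label: str = "unknown",
    ):
        self.chrom = chrom
        self.start = int(start)
        self.strand = strand
        self.sequence = sequence
        self.cpg_offsets = tuple(int(o) for o in cpg_offsets)
        self.cpg_states = tuple(int(s) for s in cpg_states)
        self.sample_id = sample_id
        self.origin_label = origin_label

    # -- contracts ---------------------------------------------------------
    def validate(self) -> "MethylRead":
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise DataError(f"negative start {self.start}")
        if set(self.sequence) - set("ACGTN"):
            raise DataError(f"sequence has non-ACGTN characters: {self.sequence!r}")
        if len(self.cpg_offsets) != len(self.cpg_states):
            raise DataError(
                f"{len(self.cpg_offsets)} offsets but {len(self.cpg_states)} states"
            )
        if any(b < a for a, b in zip(self.cpg_offsets, self.cpg_offsets[1:])):
            raise DataError(f"cpg_offsets not strictly increasing: {self.cpg_offsets}")
        if any(s not in (0, 1) for s in self.cpg_states):
            raise DataError(f"cpg_states must be 0/1, got {self.cpg_states}")
        for o in self.cpg_offsets:
            if self.sequence[o : o + 2] != "CG":
                raise DataError(
                    f"offset {o} does not point at a CG dinucleotide "
                    f"(found {self.sequence[o:o + 2]!r})"
                )
        return self

    def normalized(self) -> "MethylRead":
        """Return the plus-strand view of this read.

        For a minus-strand read the stored sequence reads 5'->3' on the minus
        strand; the CpG dinucleotide is palindromic, so each offset maps to
        ``len(seq) - 2 - offset`` after reverse-complementing.
        """
        if self.strand == "+":
            return self
        seq = self.sequence.translate(_COMPLEMENT)[::-1]
        n = len(seq)
        pairs = sorted(
            (n - 2 - o, s) for o, s in zip(self.cpg_offsets, self.cpg_states)
        )
        return MethylRead(
            self.chrom,
            self.start,
            "+",
            seq,
            [p for p, _ in pairs],
            [s for _, s in pairs],
            self.sample_id,
            self.origin_label,
        )

    # -- derived views -----------------------------------------------------
    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    def cpg_positions(self) -> np.ndarray:
        """Genomic positions (plus-strand C) of the covered CpGs."""
        return self.start + np.asarray(self.cpg_offsets, dtype=np.int64)

    def __eq__(self, other):
        if not isinstance(other, MethylRead):
            return NotImplemented
        return all(
            getattr(self, f) == getattr(other, f) for f in MethylRead.__slots__
        )

    def __hash__(self):
        return hash((self.chrom, self.start, self.sequence, self.cpg_offsets))

    def __repr__(self):
        return (
            f"MethylRead({self.chrom}:{self.start}{self.strand}, "
            f"{len(self.sequence)} bp, {len(self.cpg_offsets)} CpGs, "
            f"sample={self.sample_id!r}, origin={self.origin_label!r})"
        )


@dataclass
class Region:
    """A genomic interval that is a candidate or called DMR."""

    chrom: str
    start: int
    end: int
    id: str
    direction: str | None = None  # 'hypo' | 'hyper' once called
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start >= self.end:
            raise DataError(
                f"region {self.id or '?'}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# read-record TSV
# ---------------------------------------------------------------------------

def write_read_records(reads: Iterable[MethylRead], path: str | Path) -> None:
    """Write reads as the canonical read-record TSV (byte-stable)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(READ_RECORD_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                "\t".join(
                    (
                        r.sample_id,
                        r.chrom,
                        str(r.start),
                        r.strand,
                        r.sequence,
                        ",".join(str(o) for o in r.cpg_offsets),
                        ",".join(_CODE_STATE[s] for s in r.cpg_states),
                        r.origin_label,
                    )
                )
                + "\n"
            )


def read_read_records(path: str | Path, normalize: bool = True) -> list[MethylRead]:
    """Parse a read-record TSV into validated :class:`MethylRead` objects.

    Invalid rows raise :class:`FormatError` naming the 1-based line number.
    With ``normalize=True`` (default) minus-strand reads are mapped to the
    plus-strand frame.
    """
    path = Path(path)
    reads: list[MethylRead] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file (missing header)")
        if tuple(header) != READ_RECORD_COLUMNS:
            raise FormatError(
                f"{path}: bad header {header!r}; expected {list(READ_RECORD_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(READ_RECORD_COLUMNS):
                raise FormatError(
                    f"{path} line {lineno}: expected {len(READ_RECORD_COLUMNS)} "
                    f"columns, found {len(row)}"
                )
            sample_id, chrom, start, strand, seq, offs, states, origin = row
            try:
                offsets = [int(x) for x in offs.split(",")] if offs else []
                state_codes = (
                    [_STATE_CODE[x] for x in states.split(",")] if states else []
                )
                read = MethylRead(
                    chrom, int(start), strand, seq, offsets, state_codes,
                    sample_id=sample_id, origin_label=origin,
                ).validate()
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            reads.append(read.normalized() if normalize else read)
    return reads


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Region]:
    """Read a 3+ column BED file (0-based half-open) into Regions.

    The optional 4th column becomes the region id; otherwise ids are
    ``chrom:start-end``.
    """
    path = Path(path)
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            rid = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            regions.append(Region(chrom, start, end, rid))
    ids = [r.id for r in regions]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate region ids")
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


# ---------------------------------------------------------------------------
# Bismark-style cytosine report
# ---------------------------------------------------------------------------

def read_cpg_report(path: str | Path) -> pd.DataFrame:
    """Read a Bismark-style CpG cytosine report into per-CpG counts.

    Expects tab-separated columns chrom, position (1-based), strand,
    count_methylated, count_unmethylated (trailing context columns are
    ignored).  Records on the two strands of one CpG are collapsed onto the
    plus-strand C with summed counts.  Returns a DataFrame with columns
    ``chrom, pos, meth_count, unmeth_count`` where ``pos`` is the 0-based
    plus-strand position of the C.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3, 4],
            names=["chrom", "pos", "strand", "meth_count", "unmeth_count"],
            dtype={"chrom": str, "strand": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a cytosine report ({exc})") from exc
    for col in ("pos", "meth_count", "unmeth_count"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise FormatError(f"{path}: column {col} is not integer")
    if (df[["meth_count", "unmeth_count"]] < 0).any().any():
        bad = (df[["meth_count", "unmeth_count"]] < 0).any(axis=1).idxmax()
        raise FormatError(f"{path} row {bad + 1}: negative count")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"{path} row {int(bad_strand.idxmax()) + 1}: "
            f"strand {df['strand'][bad_strand.idxmax()]!r}"
        )
    # 1-based report position -> 0-based plus-strand C: the minus-strand C of
    # a CpG sits one base right of the plus-strand C.
    df["pos"] = np.where(df["strand"] == "+", df["pos"] - 1, df["pos"] - 2)
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: position underflow after strand collapsing")
    out = (
        df.groupby(["chrom", "pos"], as_index=False)[["meth_count", "unmeth_count"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# sample manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV.

    Requires a ``sample_id`` column plus at least one of ``group`` /
    ``grade``; any other columns (e.g. ``reads_path`` or numeric biomarker
    columns) pass through untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if "group" not in df.columns and "grade" not in df.columns:
        raise FormatError(f"{path}: need at least one of 'group'/'grade' columns")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    if "group" in df.columns:
        bad = ~df["group"].isin(VALID_GROUPS)
        if bad.any():
            raise FormatError(
                f"{path}: unknown group {df['group'][bad].iloc[0]!r}; "
                f"allowed: {sorted(VALID_GROUPS)}"
            )
    if "grade" in df.columns:
        df["grade"] = df["grade"].fillna("none")
        bad = ~df["grade"].isin(VALID_GRADES)
        if bad.any():
            raise FormatError(
                f"{path}: unknown grade {df['grade'][bad].iloc[0]!r}; "
                f"allowed: {sorted(VALID_GRADES)}"
            )
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read -> region assignment
# ---------------------------------------------------------------------------

def assign_reads_to_regions(
    reads: Sequence[MethylRead], regions: Sequence[Region]
) -> dict[str, list[MethylRead]]:
    """Map each region id to the reads whose CpGs fall inside it.

    A read is assigned to a region iff at least one of its CpG positions
    (plus-strand C) lies in ``[start, end)``.  Regions must be
    non-overlapping per chromosome (merge upstream otherwise); a read whose
    CpGs span two regions is counted in each.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    bounds: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, regs in by_chrom.items():
        regs.sort(key=lambda r: r.start)
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise DataError(
                    f"overlapping regions {a.id} and {b.id} on {chrom}; merge first"
                )
        bounds[chrom] = (
            np.array([r.start for r in regs], dtype=np.int64),
            np.array([r.end for r in regs], dtype=np.int64),
            [r.id for r in regs],
        )
    out: dict[str, list[MethylRead]] = {r.id: [] for r in regions}
    for read in reads:
        entry = bounds.get(read.chrom)
        if entry is None or not read.cpg_offsets:
            continue
        starts, ends, ids = entry
        pos = read.cpg_positions()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        for i in np.unique(idx[ok]):
            out[ids[i]].append(read)
    return out


# ---------------------------------------------------------------------------
# optional: Bismark SAM/BAM ingestion
# ---------------------------------------------------------------------------

def read_bismark_alignments(
    path: str | Path,
    sample_id: str = "",
    min_mapq: int = 0,
) -> list[MethylRead]:
    """Ingest Bismark alignments (SAM/BAM) via the XM methylation-call tag.

    Only CpG calls (XM characters ``Z`` methylated / ``z`` unmethylated) are
    retained.  Reads with indels, without an XM tag, or below ``min_mapq``
    are skipped.  No mapping-quality filter is applied by default.  Because
    bisulfite conversion turns unmethylated C into T in the read, the base
    pair at each called CpG is restored to ``CG`` in the emitted sequence so
    the canonical read contract holds.  Requires pysam.
    """
    import pysam  # optional dependency; TSV is the reference path

    reads: list[MethylRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if not aln.has_tag("XM"):
                continue
            cigar = aln.cigartuples or []
            if any(op not in (0, 7, 8) for op, _ in cigar):  # M/=/X only
                continue
            xm = aln.get_tag("XM")
            seq = aln.query_sequence
            if seq is None or len(xm) != len(seq):
                continue
            strand = "-" if aln.is_reverse else "+"
            offsets, states = [], []
            for i, ch in enumerate(xm):
                if ch == "Z":
                    offsets.append(i), states.append(1)
                elif ch == "z":
                    offsets.append(i), states.append(0)
            # Bismark reports the read in reference orientation; on the minus
            # strand the CpG call sits on the G of the plus-strand CG.
            if strand == "-":
                offsets = [o - 1 for o in offsets]
            if any(o < 0 or o + 1 >= len(seq) for o in offsets):
                continue
            bases = list(seq)
            for o in offsets:  # undo bisulfite conversion at called CpGs
                bases[o], bases[o + 1] = "C", "G"
            reads.append(
                MethylRead(
                    aln.reference_name,
                    aln.reference_start,
                    "+",
                    "".join(bases),
                    offsets,
                    states,
                    sample_id=sample_id,
                ).validate()
            )
    return reads
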