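"""Target regions, read counting and the raw coverage matrix.

Depth of coverage is defined per (region, sample) as the number of reads
passing the filter whose aligned reference span overlaps the region by at
least one base; a read overlapping several regions counts once in each.
The counting module is replaceable: a precomputed coverage matrix can be
supplied as a TSV instead of BAM files.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_REGION_ID_RE = re.compile(r"^(?P<chrom>.+):(?P<start>\d+)-(?P<end>\d+)$")


class CoverageError(ValueError):
    """Raised for malformed coverage inputs (BED, TSV, BAM)."""


@dataclass(frozen=True)
class TargetRegion:
    """A capture interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CoverageError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and end > self.start


def make_region(chrom: str, start: int, end: int) -> TargetRegion:
    return TargetRegion(chrom, start, end, f"{chrom}:{start}-{end}")


def region_from_id(region_id: str) -> TargetRegion:
    """Parse a "chrom:start-end" identifier back into a region."""
    m = _REGION_ID_RE.match(region_id)
    if m is None:
        raise CoverageError(f"cannot parse region id {region_id!r}")
    return TargetRegion(
        m.group("chrom"), int(m.group("start")), int(m.group("end")), region_id
    )


@dataclass(frozen=True)
class ReadFilter:
    """Which alignments contribute to coverage.

    Secondary and supplementary alignments are controlled together by
    ``include_secondary``. Unmapped reads are always excluded.
    """

    min_mapq: int = 20
    include_duplicates: bool = False
    include_secondary: bool = False
    include_qcfail: bool = False

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def passes(self, read: "pysam.AlignedSegment") -> bool:
        if read.is_unmapped:
            return False
        if (read.is_secondary or read.is_supplementary) and not self.include_secondary:
            return False
        if read.is_duplicate and not self.include_duplicates:
            return False
        if read.is_qcfail and not self.include_qcfail:
            return False
        return read.mapping_quality >= self.min_mapq


class CoverageMatrix:
    """Integer read counts, regions in rows, samples in columns."""

    def __init__(
        self,
        counts: np.ndarray,
        region_ids: Sequence[str],
        sample_ids: Sequence[str],
    ):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise CoverageError("counts must be a 2-D matrix")
        if counts.shape[0] == 0:
            raise CoverageError("no regions")
        if counts.shape[1] == 0:
            raise CoverageError("no samples")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise CoverageError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise CoverageError("counts must be non-negative")
        region_ids = list(region_ids)
        sample_ids = list(sample_ids)
        if counts.shape != (len(region_ids), len(sample_ids)):
            raise CoverageError("counts shape does not match id lists")
        if len(set(region_ids)) != len(region_ids):
            raise CoverageError("duplicated region ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise CoverageError("duplicated sample ids")
        self.counts = counts.astype(np.int64)
        self.region_ids = region_ids
        self.sample_ids = sample_ids

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_regions(self, indices: Sequence[int]) -> "CoverageMatrix":
        idx = list(indices)
        return CoverageMatrix(
            self.counts[idx, :],
            [self.region_ids[i] for i in idx],
            self.sample_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.region_ids, columns=self.sample_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageMatrix):
            return NotImplemented
        return (
            self.region_ids == other.region_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


def load_targets(bed_path: str | os.PathLike) -> list[TargetRegion]:
    """Load target regions from a BED3+ file (tab-separated, 0-based half-open).

    Regions are sorted by (chrom, start, end); exact duplicates are dropped
    with a warning.
    """
    regions: list[TargetRegion] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise CoverageError(
                    f"{bed_path}: line {lineno}: expected >= 3 BED columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CoverageError(
                    f"{bed_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise CoverageError(
                    f"{bed_path}: line {lineno}: invalid interval "
                    f"{chrom}:{start}-{end} (need 0 <= start < end)"
                )
            regions.append(make_region(chrom, start, end))
    seen: set[tuple[str, int, int]] = set()
    unique: list[TargetRegion] = []
    n_dup = 0
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        key = (r.chrom, r.start, r.end)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        unique.append(r)
    if n_dup:
        logger.warning("%s: dropped %d duplicate target region(s)", bed_path, n_dup)
    return unique


def count_region_coverage(
    bam_path: str | os.PathLike,
    regions: Sequence[TargetRegion],
    read_filter: ReadFilter | None = None,
) -> np.ndarray:
    """Count filter-passing reads overlapping each region by >= 1 bp."""
    read_filter = read_filter or ReadFilter()
    counts = np.zeros(len(regions), dtype=np.int64)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        try:
            has_index = bam.check_index()
        except (ValueError, AttributeError):
            has_index = False
        if not has_index:
            raise CoverageError(
                f"{bam_path} has no index; run 'samtools index' first"
            )
        references = set(bam.references)
        missing: set[str] = set()
        for i, region in enumerate(regions):
            if region.chrom not in references:
                missing.add(region.chrom)
                continue
            counts[i] = sum(
                1
                for read in bam.fetch(region.chrom, region.start, region.end)
                if read_filter.passes(read)
            )
        if missing:
            logger.warning(
                "%s: chromosome(s) %s absent from BAM header; counts set to 0",
                bam_path,
                ",".join(sorted(missing)),
            )
    return counts


def build_coverage_matrix(
    bam_paths: Sequence[str | os.PathLike],
    regions: Sequence[TargetRegion],
    read_filter: ReadFilter | None = None,
) -> CoverageMatrix:
    """Count every BAM against the targets; one column per BAM."""
    if not bam_paths:
        raise CoverageError("need at least one BAM file")
    columns = []
    for path in bam_paths:
        try:
            columns.append(count_region_coverage(path, regions, read_filter))
        except (OSError, ValueError) as exc:
            raise CoverageError(f"cannot read BAM {path}: {exc}") from exc
    sample_ids: list[str] = []
    for ordinal, path in enumerate(bam_paths):
        base = os.path.basename(str(path))
        if base.endswith(".bam"):
            base = base[: -len(".bam")]
        if base in sample_ids:
            base = f"{base}.{ordinal}"
        sample_ids.append(base)
    return CoverageMatrix(
        np.stack(columns, axis=1), [r.region_id for r in regions], sample_ids
    )


def write_coverage_tsv(matrix: CoverageMatrix, path: str | os.PathLike) -> None:
    df = matrix.to_frame()
    df.index.name = "region_id"
    df.to_csv(path, sep="\t")


def read_coverage_tsv(path: str | os.PathLike) -> CoverageMatrix:
    """Read a coverage TSV (header of sample ids, first column region ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise CoverageError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if df.shape[0] == 0:
        raise CoverageError(f"{path}: no regions")
    if df.shape[1] == 0:
        raise CoverageError(f"{path}: no samples")
    raw = df.to_numpy()
    try:
        # fast path: every cell is a plain integer literal
        return CoverageMatrix(
            raw.astype(np.int64), list(df.index), list(df.columns)
        )
    except (TypeError, ValueError):
        pass
    values = np.empty(df.shape, dtype=np.int64)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                values[i, j] = int(cell)
            except (TypeError, ValueError) as exc:
                raise CoverageError(
                    f"{path}: non-integer cell {cell!r} at region "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                ) from exc
    return CoverageMatrix(values, list(df.index), list(df.columns))
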