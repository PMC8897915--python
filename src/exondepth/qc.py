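"""Region annotation and quality control.

Regions are annotated with GC fraction, mappability, length and median
depth, then filtered with boundary-inclusive thresholds: a region is
removed only when it falls strictly outside [gc_min, gc_max],
[median_depth_min, median_depth_max] or [length_min, length_max], or
strictly below mappability_min.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io_coverage import CoverageMatrix, TargetRegion

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "gc",
    "mappability",
    "length",
    "median_depth",
]


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    gc_min: float = 0.20
    gc_max: float = 0.80
    mappability_min: float = 0.9
    median_depth_min: float = 20.0
    median_depth_max: float = 4000.0
    length_min: int = 20
    length_max: int = 2000

    def __post_init__(self) -> None:
        if not (
            self.gc_min < self.gc_max
            and self.median_depth_min < self.median_depth_max
            and self.length_min < self.length_max
        ):
            raise ValueError("each QC min must be below its max")


@dataclass
class QCResult:
    kept_indices: list[int]
    removed: list[tuple[str, list[str]]]
    summary: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def annotate_gc(
    regions: Sequence[TargetRegion], fasta_path: str | os.PathLike
) -> np.ndarray:
    """GC fraction over non-N reference bases; NaN for all-N regions."""
    gc = np.empty(len(regions))
    with pysam.FastaFile(str(fasta_path)) as fasta:
        present = set(fasta.references)
        for i, region in enumerate(regions):
            if region.chrom not in present:
                raise QCError(
                    f"chromosome {region.chrom!r} missing from {fasta_path}"
                )
            seq = fasta.fetch(region.chrom, region.start, region.end).upper()
            non_n = len(seq) - seq.count("N")
            if non_n == 0:
                gc[i] = np.nan
            else:
                gc[i] = (seq.count("G") + seq.count("C")) / non_n
    return gc


def load_mappability(
    path: str | os.PathLike | None, regions: Sequence[TargetRegion]
) -> np.ndarray:
    """Per-region mappability from a region_id->value TSV; default 1.0."""
    values = np.ones(len(regions))
    if path is None:
        logger.info("no mappability file supplied; all regions set to 1.0")
        return values
    table = pd.read_csv(
        path, sep="\t", header=None, names=["region_id", "mappability"], dtype=str
    )
    mapping: dict[str, float] = {}
    for _, row in table.iterrows():
        if row["region_id"] == "region_id":  # tolerate a header row
            continue
        val = float(row["mappability"])
        if not 0.0 <= val <= 1.0:
            raise QCError(
                f"mappability {val} for {row['region_id']} outside [0, 1]"
            )
        mapping[row["region_id"]] = val
    n_missing = 0
    for i, region in enumerate(regions):
        if region.region_id in mapping:
            values[i] = mapping[region.region_id]
        else:
            n_missing += 1
    if n_missing:
        logger.warning(
            "%d region(s) missing from mappability file; defaulted to 1.0",
            n_missing,
        )
    return values


def build_annotations(
    matrix: CoverageMatrix,
    regions: Sequence[TargetRegion],
    gc: np.ndarray,
    mappability: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-region annotation table aligned with matrix rows."""
    if [r.region_id for r in regions] != matrix.region_ids:
        raise QCError("regions do not align with coverage matrix rows")
    if mappability is None:
        mappability = np.ones(len(regions))
    return pd.DataFrame(
        {
            "region_id": matrix.region_ids,
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "gc": np.asarray(gc, dtype=float),
            "mappability": np.asarray(mappability, dtype=float),
            "length": [r.length for r in regions],
            "median_depth": np.median(matrix.counts, axis=1),
        }
    )


def _failed_filters(row: pd.Series, t: QCThresholds) -> list[str]:
    reasons = []
    gc = row["gc"]
    if np.isnan(gc) or gc < t.gc_min or gc > t.gc_max:
        reasons.append("gc")
    if row["mappability"] < t.mappability_min:
        reasons.append("mappability")
    if not (t.median_depth_min <= row["median_depth"] <= t.median_depth_max):
        reasons.append("median_depth")
    if not (t.length_min <= row["length"] <= t.length_max):
        reasons.append("length")
    return reasons


def apply_qc(
    matrix: CoverageMatrix,
    annotations: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[CoverageMatrix, pd.DataFrame, QCResult]:
    """Drop regions failing any of the four filters; keep boundary values."""
    thresholds = thresholds or QCThresholds()
    if list(annotations["region_id"]) != matrix.region_ids:
        raise QCError("annotations do not align with coverage matrix rows")
    kept: list[int] = []
    removed: list[tuple[str, list[str]]] = []
    summary = {"gc": 0, "mappability": 0, "median_depth": 0, "length": 0}
    for i, (_, row) in enumerate(annotations.iterrows()):
        reasons = _failed_filters(row, thresholds)
        if reasons:
            removed.append((row["region_id"], reasons))
            for reason in reasons:
                summary[reason] += 1
        else:
            kept.append(i)
    if not kept:
        raise QCError("empty matrix after QC: every region failed a filter")
    result = QCResult(kept_indices=kept, removed=removed, summary=summary)
    filtered = matrix.subset_regions(kept)
    filtered_annotations = annotations.iloc[kept].reset_index(drop=True)
    return filtered, filtered_annotations, result


def qc_report(
    annotations: pd.DataFrame,
    result: QCResult | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-region QC report: annotation columns + kept flag + reasons."""
    thresholds = thresholds or QCThresholds()
    report = annotations.copy()
    kept = []
    reasons_col = []
    for _, row in annotations.iterrows():
        reasons = _failed_filters(row, thresholds)
        kept.append(0 if reasons else 1)
        reasons_col.append(",".join(reasons))
    report["kept"] = kept
    report["reasons"] = reasons_col
    return report


def flag_anomalous_samples(matrix: CoverageMatrix, n_mads: float = 3.0) -> list[str]:
    """Flag (never remove) samples whose total coverage deviates from the
    cohort median by more than ``n_mads`` median absolute deviations."""
    totals = matrix.counts.sum(axis=0).astype(float)
    med = np.median(totals)
    mad = np.median(np.abs(totals - med))
    if mad == 0:
        return []
    flagged = [
        sid
        for sid, tot in zip(matrix.sample_ids, totals)
        if abs(tot - med) > n_mads * mad
    ]
    if flagged:
        logger.warning("anomalous total coverage in sample(s): %s", ",".join(flagged))
    return flagged


def write_annotations_tsv(annotations: pd.DataFrame, path: str | os.PathLike) -> None:
    annotations.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotations_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("region_id", "gc") if c not in df.columns]
    if missing:
        raise QCError(f"{path}: missing column(s) {missing}")
    return df
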