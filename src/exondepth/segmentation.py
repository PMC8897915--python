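"""Ratio tracks, circular binary segmentation and CNV calling.

Per sample, the ratio of raw to expected coverage is segmented on the
log2 scale with CBS: the circular arc maximizing a t-like contrast
between in-arc and out-of-arc means is accepted as a split when its
permutation p-value falls below alpha, recursively. Segments with a
rounded copy number different from 2 become DEL/DUP calls; nearby calls
of the same type are merged.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_coverage import TargetRegion

CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "type",
    "copy_number",
    "n_exons",
    "raw_sum",
    "norm_sum",
    "ratio",
    "lratio",
]


@dataclass
class RatioTrack:
    sample_id: str
    raw: np.ndarray  # (n,) raw counts
    norm: np.ndarray  # (n,) expected coverage, > 0
    ratio: np.ndarray  # (raw + c) / (norm + c)
    log2_ratio: np.ndarray
    regions: list[TargetRegion]
    pseudocount: float


@dataclass
class Segment:
    sample_id: str
    chrom: str
    first: int  # inclusive region index into the track
    last: int  # inclusive
    start: int
    end: int
    n_exons: int
    raw_sum: float
    norm_sum: float
    mean_log2_ratio: float


@dataclass
class CNVCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    type: str  # DEL or DUP
    copy_number: int
    n_exons: int
    raw_sum: float
    norm_sum: float
    ratio: float
    lratio: float
    exon_ranges: tuple[tuple[int, int], ...] = field(default=())  # inclusive index ranges


def compute_ratio_track(
    raw_col: np.ndarray,
    norm_col: np.ndarray,
    regions: Sequence[TargetRegion],
    pseudocount: float = 0.5,
    sample_id: str = "sample",
) -> RatioTrack:
    raw_col = np.asarray(raw_col, dtype=float)
    norm_col = np.asarray(norm_col, dtype=float)
    if raw_col.shape != norm_col.shape or raw_col.shape[0] != len(regions):
        raise ValueError("raw, normalized and region lists must align")
    if np.any(norm_col <= 0):
        raise ValueError("normalized coverage must be strictly positive")
    order = sorted(
        range(len(regions)), key=lambda i: (regions[i].chrom, regions[i].start, regions[i].end)
    )
    raw_s = raw_col[order]
    norm_s = norm_col[order]
    ratio = (raw_s + pseudocount) / (norm_s + pseudocount)
    return RatioTrack(
        sample_id=sample_id,
        raw=raw_s,
        norm=norm_s,
        ratio=ratio,
        log2_ratio=np.log2(ratio),
        regions=[regions[i] for i in order],
        pseudocount=pseudocount,
    )


def _best_arc(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t-like| circular-arc contrast on a contiguous signal.

    Returns (stat, i, j) for the arc x[i:j]; the complement arc is
    equivalent by symmetry, so contiguous windows suffice. The pooled
    scale is the overall SD, which is permutation-invariant.
    """
    n = x.shape[0]
    total = float(x.sum())
    sd = float(x.std())
    if sd == 0 or n < 2:
        return 0.0, 0, n
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    best_stat, best_i, best_j = 0.0, 0, n
    for w in range(max(min_width, 1), n - max(min_width, 1) + 1):
        if w == n:
            continue
        sums = prefix[w:] - prefix[:-w]
        mean_in = sums / w
        mean_out = (total - sums) / (n - w)
        stat = np.abs(mean_in - mean_out) / (sd * math.sqrt(1.0 / w + 1.0 / (n - w)))
        pos = int(np.argmax(stat))
        if stat[pos] > best_stat:
            best_stat = float(stat[pos])
            best_i, best_j = pos, pos + w
    return best_stat, best_i, best_j


def _max_stats_batch(perms: np.ndarray, min_width: int) -> np.ndarray:
    """Max arc statistic for each row of a (B, n) permutation batch."""
    b, n = perms.shape
    total = perms.sum(axis=1)
    sd = perms.std(axis=1)
    sd = np.where(sd == 0, np.inf, sd)
    prefix = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1)
    best = np.zeros(b)
    for w in range(max(min_width, 1), n - max(min_width, 1) + 1):
        if w == n:
            continue
        sums = prefix[:, w:] - prefix[:, :-w]
        mean_in = sums / w
        mean_out = (total[:, None] - sums) / (n - w)
        stat = np.abs(mean_in - mean_out) / (
            sd[:, None] * math.sqrt(1.0 / w + 1.0 / (n - w))
        )
        np.maximum(best, stat.max(axis=1), out=best)
    return best


def _split_significant(
    x: np.ndarray,
    stat: float,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test with early stopping once significance is impossible."""
    if stat <= 0:
        return False
    needed = math.ceil(alpha * (n_perm + 1))  # exceedances that force p >= alpha
    exceed = 0
    done = 0
    batch = 64
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.empty((b, x.shape[0]))
        for r in range(b):
            perms[r] = rng.permutation(x)
        stats = _max_stats_batch(perms, min_width)
        exceed += int(np.sum(stats >= stat - 1e-12))
        done += b
        if exceed >= needed:
            return False
    p = (1.0 + exceed) / (1.0 + n_perm)
    return p < alpha


def cbs_segment(
    track: RatioTrack,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 1,
    seed: int = 7,
) -> list[Segment]:
    """Segment the log2 ratio per chromosome; segments partition each one."""
    segments: list[Segment] = []
    chroms: list[str] = []
    for r in track.regions:
        if not chroms or chroms[-1] != r.chrom:
            chroms.append(r.chrom)
    for chrom in chroms:
        idx = [i for i, r in enumerate(track.regions) if r.chrom == chrom]
        lo, hi = idx[0], idx[-1] + 1
        bounds: list[tuple[int, int]] = []

        def recurse(a: int, b: int) -> None:
            x = track.log2_ratio[a:b]
            if b - a < 2 * max(min_width, 1) or b - a < 2:
                bounds.append((a, b))
                return
            stat, i, j = _best_arc(x, min_width)
            rng = np.random.default_rng([seed, a, b])
            if stat > 0 and _split_significant(x, stat, alpha, n_perm, min_width, rng):
                for piece in ((a, a + i), (a + i, a + j), (a + j, b)):
                    if piece[1] > piece[0]:
                        recurse(*piece)
            else:
                bounds.append((a, b))

        recurse(lo, hi)
        bounds.sort()
        for a, b in bounds:
            raw_sum = float(track.raw[a:b].sum())
            norm_sum = float(track.norm[a:b].sum())
            segments.append(
                Segment(
                    sample_id=track.sample_id,
                    chrom=chrom,
                    first=a,
                    last=b - 1,
                    start=track.regions[a].start,
                    end=track.regions[b - 1].end,
                    n_exons=b - a,
                    raw_sum=raw_sum,
                    norm_sum=norm_sum,
                    mean_log2_ratio=float(track.log2_ratio[a:b].mean()),
                )
            )
    return segments


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _poisson_lratio(
    raw: np.ndarray, norm: np.ndarray, cn: int, pseudocount: float
) -> float:
    """Log-likelihood ratio of copy number ``cn`` against CN=2."""
    scale = cn / 2.0
    mu_alt = np.maximum(scale * norm, pseudocount)
    mu_null = norm
    with np.errstate(divide="ignore"):
        ll_alt = float(np.sum(raw * np.log(mu_alt) - mu_alt))
        ll_null = float(np.sum(raw * np.log(mu_null) - mu_null))
    return ll_alt - ll_null


def call_segments(
    segments: Sequence[Segment],
    raw_col: np.ndarray,
    norm_col: np.ndarray,
    pseudocount: float = 0.5,
) -> list[CNVCall]:
    """Round 2*ratio to an integer copy number; emit calls where CN != 2.

    ``raw_col``/``norm_col`` must be in the same (track) order the
    segments index into.
    """
    raw_col = np.asarray(raw_col, dtype=float)
    norm_col = np.asarray(norm_col, dtype=float)
    calls: list[CNVCall] = []
    for seg in segments:
        ratio = seg.raw_sum / seg.norm_sum
        cn = _round_half_up(2.0 * ratio)
        if cn == 2:
            continue
        sl = slice(seg.first, seg.last + 1)
        lratio = _poisson_lratio(raw_col[sl], norm_col[sl], cn, pseudocount)
        calls.append(
            CNVCall(
                sample_id=seg.sample_id,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                type="DEL" if cn < 2 else "DUP",
                copy_number=cn,
                n_exons=seg.n_exons,
                raw_sum=seg.raw_sum,
                norm_sum=seg.norm_sum,
                ratio=ratio,
                lratio=lratio,
                exon_ranges=((seg.first, seg.last),),
            )
        )
    return calls


def merge_calls(
    calls: Sequence[CNVCall],
    raw_col: np.ndarray | None = None,
    norm_col: np.ndarray | None = None,
    max_gap_bp: int = 50_000,
    pseudocount: float = 0.5,
) -> list[CNVCall]:
    """Merge same-type adjacent calls whose genomic gap is <= max_gap_bp.

    Applied left-to-right per (sample, chrom). Sums, copy number and the
    likelihood ratio are recomputed over the union of the calls' exons
    (intervening CN=2 exons are not included).
    """
    grouped: dict[tuple[str, str], list[CNVCall]] = {}
    for call in sorted(calls, key=lambda c: (c.sample_id, c.chrom, c.start, c.end)):
        grouped.setdefault((call.sample_id, call.chrom), []).append(call)
    merged: list[CNVCall] = []
    for group in grouped.values():
        current = group[0]
        for nxt in group[1:]:
            gap = nxt.start - current.end
            if nxt.type == current.type and gap <= max_gap_bp:
                current = _merge_pair(current, nxt, raw_col, norm_col, pseudocount)
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return merged


def _merge_pair(
    a: CNVCall,
    b: CNVCall,
    raw_col: np.ndarray | None,
    norm_col: np.ndarray | None,
    pseudocount: float,
) -> CNVCall:
    raw_sum = a.raw_sum + b.raw_sum
    norm_sum = a.norm_sum + b.norm_sum
    ratio = raw_sum / norm_sum
    cn = _round_half_up(2.0 * ratio)
    ranges = tuple(sorted(a.exon_ranges + b.exon_ranges))
    if raw_col is not None and norm_col is not None:
        idx = np.concatenate(
            [np.arange(f, l + 1) for f, l in ranges]
        )
        lratio = _poisson_lratio(
            np.asarray(raw_col, dtype=float)[idx],
            np.asarray(norm_col, dtype=float)[idx],
            cn,
            pseudocount,
        )
    else:
        lratio = a.lratio + b.lratio
    return CNVCall(
        sample_id=a.sample_id,
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        type="DEL" if cn < 2 else "DUP",
        copy_number=cn,
        n_exons=a.n_exons + b.n_exons,
        raw_sum=raw_sum,
        norm_sum=norm_sum,
        ratio=ratio,
        lratio=lratio,
        exon_ranges=ranges,
    )


def call_sample(
    raw_col: np.ndarray,
    norm_col: np.ndarray,
    regions: Sequence[TargetRegion],
    sample_id: str = "sample",
    pseudocount: float = 0.5,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 1,
    seed: int = 7,
    max_gap_bp: int = 50_000,
) -> list[CNVCall]:
    """Ratio track -> CBS -> calls -> merge, for one sample."""
    track = compute_ratio_track(raw_col, norm_col, regions, pseudocount, sample_id)
    segments = cbs_segment(track, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=seed)
    calls = call_segments(segments, track.raw, track.norm, pseudocount)
    return merge_calls(calls, track.raw, track.norm, max_gap_bp, pseudocount)


def calls_to_frame(calls: Sequence[CNVCall]) -> pd.DataFrame:
    rows = [
        {col: getattr(c, col) for col in CALL_COLUMNS}
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls_tsv(calls: Sequence[CNVCall], path: str | os.PathLike) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls_bed(calls: Sequence[CNVCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample_id)):
            name = f"{c.sample_id}|{c.type}|{c.copy_number}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\n")
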